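"""Configuration loading: nuclide, phantom, species, limits, fixtures.

Defaults ship as YAML/CSV package data; every loader also accepts an
explicit path so users can override any constant.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .dose import Nuclide, Phantom
from .errors import ConfigError
from .planning import DoseLimits, SpeciesParams


def _data_path(name: str):
    return resources.files("radplan").joinpath("data", name)


def _load_yaml(path: str | Path | None, default_name: str) -> dict:
    if path is not None:
        text = Path(path).read_text()
    else:
        text = _data_path(default_name).read_text()
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ConfigError(f"expected a mapping in {path or default_name}")
    return out


def load_nuclide(path: str | Path | None = None) -> Nuclide:
    cfg = _load_yaml(path, "nuclide.yaml")
    try:
        return Nuclide(
            name=str(cfg["name"]),
            physical_half_life_h=float(cfg["half_life_h"]),
            mean_energy_per_decay_mev=float(cfg["mean_energy_mev"]),
        )
    except KeyError as exc:
        raise ConfigError(f"nuclide config missing key {exc}") from exc


def load_phantom(path: str | Path | None = None) -> Phantom:
    cfg = _load_yaml(path, "phantom.yaml")
    try:
        return Phantom(
            organ_masses_g={k: float(v) for k, v in cfg["organ_masses_g"].items()},
            total_body_mass_g=float(cfg["total_body_mass_g"]),
            name=str(cfg.get("name", "adult_male")),
        )
    except KeyError as exc:
        raise ConfigError(f"phantom config missing key {exc}") from exc


def load_species(path: str | Path | None = None) -> SpeciesParams:
    cfg = _load_yaml(path, "species.yaml")
    try:
        return SpeciesParams(
            km={k: float(v) for k, v in cfg["km"].items()},
            reference_weight_kg={k: float(v) for k, v in cfg["reference_weight_kg"].items()},
            human_bsa_m2=float(cfg["human_bsa_m2"]),
        )
    except KeyError as exc:
        raise ConfigError(f"species config missing key {exc}") from exc


def load_limits(path: str | Path | None = None) -> DoseLimits:
    cfg = _load_yaml(path, "limits.yaml")
    try:
        return DoseLimits(
            red_marrow_mgy=float(cfg["red_marrow_mgy"]),
            other_organ_mgy=float(cfg["other_organ_mgy"]),
            overrides={k: float(v) for k, v in cfg.get("overrides", {}).items()},
        )
    except KeyError as exc:
        raise ConfigError(f"limits config missing key {exc}") from exc


def load_fixture(name: str) -> pd.DataFrame:
    """Read a packaged CSV fixture (printed summary tables)."""
    p = _data_path(f"fixtures/{name}")
    with resources.as_file(p) as fp:
        return pd.read_csv(fp)


def human_dose_table(antibody_dose_mg_per_m2: float) -> dict[str, float]:
    """Per-organ absorbed doses (mGy/MBq) at one antibody dose level,
    from the packaged human dose-estimate fixture."""
    df = load_fixture("human_dose_table.csv")
    sel = df[df["antibody_dose_mg_per_m2"] == antibody_dose_mg_per_m2]
    if sel.empty:
        raise ConfigError(
            f"no dose column for {antibody_dose_mg_per_m2} mg/m2; "
            f"available: {sorted(df['antibody_dose_mg_per_m2'].unique())}"
        )
    return dict(zip(sel["organ"], sel["mgy_per_mbq"].astype(float)))
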