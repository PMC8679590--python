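"""Simplified absorbed-dose engine for pure β-emitters.

For a β-only nuclide the self-irradiation S-value reduces to the local
energy-deposition approximation (absorbed fraction 1): all emitted energy
is absorbed in the source organ.  Cross-organ dose is carried only by the
uniformly-distributed remainder of body; bremsstrahlung and photon
cross-dose are neglected.  This deliberately does not reproduce a full
phantom Monte Carlo code — it supplies self-consistent per-organ doses
for planning arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError, InvalidInputError

#: J per MeV
_J_PER_MEV = 1.602e-13
#: decays per MBq·h
_DECAYS_PER_MBQ_H = 3.6e9

#: default mapping of source region -> dosimetric target organ
DEFAULT_SOURCE_TARGET_MAP = {"heart_contents": "heart_wall"}


@dataclass(frozen=True)
class Nuclide:
    name: str
    physical_half_life_h: float
    mean_energy_per_decay_mev: float  # mean β energy

    def __post_init__(self) -> None:
        if self.physical_half_life_h <= 0:
            raise InvalidInputError("half-life must be > 0")
        if self.mean_energy_per_decay_mev < 0:
            raise InvalidInputError("mean energy must be >= 0")

    @property
    def delta_mgy_g_per_mbq_h(self) -> float:
        """Energy emitted per unit TIAC, as mGy·g / (MBq·h)."""
        # MeV/decay x J/MeV x decays/(MBq h) = J/(MBq h) = Gy·kg/(MBq h)
        return self.mean_energy_per_decay_mev * _J_PER_MEV * _DECAYS_PER_MBQ_H * 1e6


@dataclass(frozen=True)
class Phantom:
    """Reference phantom: organ masses plus total body mass (g)."""

    organ_masses_g: Mapping[str, float]
    total_body_mass_g: float = 73_700.0
    name: str = "adult_male"

    def __post_init__(self) -> None:
        for organ, m in self.organ_masses_g.items():
            if m <= 0:
                raise InvalidInputError(f"organ mass must be > 0 ({organ})")
        if sum(self.organ_masses_g.values()) >= self.total_body_mass_g:
            raise InvalidInputError("organ masses must sum below total body mass")

    def mass(self, organ: str) -> float:
        try:
            return self.organ_masses_g[organ]
        except KeyError:
            raise ConfigError(f"no phantom mass for organ {organ!r}") from None


@dataclass(frozen=True)
class DoseTable:
    """Absorbed dose per unit administered activity (mGy/MBq) per target organ."""

    doses_mgy_per_mbq: Mapping[str, float]
    antibody_dose_label: str = ""

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses_mgy_per_mbq.values()):
            raise InvalidInputError("doses must be >= 0")

    def items(self):
        return self.doses_mgy_per_mbq.items()

    def __getitem__(self, organ: str) -> float:
        return self.doses_mgy_per_mbq[organ]


def self_dose_s_value(nuclide: Nuclide, mass_g: float) -> float:
    """Self-irradiation S-value, mGy/(MBq·h), local-deposition approximation."""
    if mass_g <= 0:
        raise InvalidInputError("mass must be > 0")
    return nuclide.delta_mgy_g_per_mbq_h / mass_g


def absorbed_dose(
    tiacs: Mapping[str, float],
    phantom: Phantom,
    nuclide: Nuclide,
    source_target_map: Mapping[str, str] | None = None,
    antibody_dose_label: str = "",
) -> DoseTable:
    """Absorbed dose per administered MBq for each target organ.

    D(target) = TIAC(source) x S_self(target mass)
              + TIAC(remainder) x Delta / total body mass.

    ``tiacs`` keys are source regions; ``heart_contents`` maps to the
    ``heart_wall`` target by default.  ``whole_body`` is not itself a
    source; a ``total_body`` row is emitted as the mass-weighted mean of
    organ and remainder doses.
    """
    if source_target_map is None:
        source_target_map = DEFAULT_SOURCE_TARGET_MAP

    uniform = tiacs.get("remainder", 0.0) * nuclide.delta_mgy_g_per_mbq_h / phantom.total_body_mass_g

    doses: dict[str, float] = {}
    for source, tiac in tiacs.items():
        if source in ("remainder", "whole_body"):
            continue
        if tiac < 0:
            raise InvalidInputError(f"negative TIAC for {source}")
        target = source_target_map.get(source, source)
        doses[target] = tiac * self_dose_s_value(nuclide, phantom.mass(target)) + uniform

    organ_mass = sum(phantom.mass(t) for t in doses)
    weighted = sum(doses[t] * phantom.mass(t) for t in doses)
    weighted += (phantom.total_body_mass_g - organ_mass) * uniform
    doses["total_body"] = weighted / phantom.total_body_mass_g

    return DoseTable(doses_mgy_per_mbq=doses, antibody_dose_label=antibody_dose_label)
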