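"""Dose planning: limiting organ, maximum activity, interspecies conversions.

Maximum administrable activity is the organ-wise minimum of
dose limit / absorbed dose per MBq.  Antibody doses are converted
between species on a body-surface-area basis with FDA-style km factors
(mg/kg x km = mg/m²); activities scale the same way and are projected to
a whole human via a reference adult-male BSA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from .dose import DoseTable
from .errors import ConfigError, InvalidInputError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style half-up rounding (1666.5 -> 1667, 0.125 -> 0.13)."""
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class DoseLimits:
    """Organ absorbed-dose ceilings in mGy."""

    red_marrow_mgy: float = 3_000.0
    other_organ_mgy: float = 20_000.0
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.red_marrow_mgy <= 0 or self.other_organ_mgy <= 0:
            raise InvalidInputError("dose limits must be > 0")
        if any(v <= 0 for v in self.overrides.values()):
            raise InvalidInputError("dose-limit overrides must be > 0")

    def for_organ(self, organ: str) -> float:
        if organ in self.overrides:
            return self.overrides[organ]
        return self.red_marrow_mgy if organ == "red_marrow" else self.other_organ_mgy


@dataclass(frozen=True)
class SpeciesParams:
    """Interspecies body-surface-area scaling constants.

    km converts mg/kg to mg/m² (multiply).  Two human size constants
    co-exist deliberately: the 60 kg / km=37 pair governs antibody mg/kg
    conversions, while the 1.89 m² reference-male BSA governs whole-body
    activity extrapolation.
    """

    km: Mapping[str, float] = field(
        default_factory=lambda: {"mouse": 3.0, "cynomolgus": 12.0, "human": 37.0}
    )
    reference_weight_kg: Mapping[str, float] = field(
        default_factory=lambda: {"mouse": 0.025, "human": 60.0}
    )
    human_bsa_m2: float = 1.89

    def km_for(self, species: str) -> float:
        try:
            return self.km[species]
        except KeyError:
            raise ConfigError(f"no km factor for species {species!r}") from None

    def weight_for(self, species: str) -> float:
        try:
            return self.reference_weight_kg[species]
        except KeyError:
            raise ConfigError(f"no reference weight for species {species!r}") from None


@dataclass(frozen=True)
class PlanningResult:
    """Outcome of a maximum-activity search over a dose table."""

    antibody_dose_label: str
    limiting_organ: str
    max_activity_mbq: float  # unrounded
    max_activity_mbq_rounded: int
    per_organ_max_mbq: Mapping[str, float]
    limits_used: Mapping[str, float]


def max_activity(
    dose_table: DoseTable | Mapping[str, float],
    limits: DoseLimits = DoseLimits(),
    exclude: tuple[str, ...] = (),
) -> PlanningResult:
    """Dose-limiting organ and maximum administrable activity.

    Per organ, max MBq = limit / (mGy per MBq); the limiting organ is the
    argmin.  Zero-dose organs are skipped with a warning.  ``exclude``
    removes rows (e.g. ``("total_body",)``) from the search; by default
    every row participates under its applicable limit.
    """
    if isinstance(dose_table, DoseTable):
        label = dose_table.antibody_dose_label
        rows = dict(dose_table.items())
    else:
        label = ""
        rows = dict(dose_table)
    rows = {o: d for o, d in rows.items() if o not in exclude}
    if not rows:
        raise InvalidInputError("empty dose table")

    per_organ: dict[str, float] = {}
    limits_used: dict[str, float] = {}
    for organ, d in rows.items():
        if d <= 0:
            warnings.warn(f"skipping organ {organ!r} with non-positive dose", stacklevel=2)
            continue
        lim = limits.for_organ(organ)
        per_organ[organ] = lim / d
        limits_used[organ] = lim
    if not per_organ:
        raise InvalidInputError("no organ with positive dose")

    limiting = min(per_organ, key=per_organ.__getitem__)
    amax = per_organ[limiting]
    return PlanningResult(
        antibody_dose_label=label, limiting_organ=limiting,
        max_activity_mbq=amax, max_activity_mbq_rounded=int(round_half_up(amax)),
        per_organ_max_mbq=per_organ, limits_used=limits_used,
    )


def mg_per_kg_to_mg_per_m2(dose_mg_per_kg: float, species: str,
                           params: SpeciesParams = SpeciesParams()) -> float:
    """Body-weight dose to body-surface-area dose: dose x km."""
    if dose_mg_per_kg < 0:
        raise InvalidInputError("dose must be >= 0")
    return dose_mg_per_kg * params.km_for(species)


def mg_per_m2_to_mg_per_kg(dose_mg_per_m2: float, species: str,
                           params: SpeciesParams = SpeciesParams()) -> float:
    """Inverse of :func:`mg_per_kg_to_mg_per_m2`."""
    if dose_mg_per_m2 < 0:
        raise InvalidInputError("dose must be >= 0")
    return dose_mg_per_m2 / params.km_for(species)


def mg_per_m2_to_mouse_ug_per_animal(dose_mg_per_m2: float,
                                     params: SpeciesParams = SpeciesParams()) -> float:
    """BSA dose to per-animal dose for a reference (25 g) mouse, in μg."""
    if dose_mg_per_m2 < 0:
        raise InvalidInputError("dose must be >= 0")
    mg_per_kg = dose_mg_per_m2 / params.km_for("mouse")
    return mg_per_kg * params.weight_for("mouse") * 1000.0


def mouse_activity_to_human(mbq_per_animal: float,
                            params: SpeciesParams = SpeciesParams()) -> tuple[float, float]:
    """Extrapolate a per-mouse activity to (MBq/m², MBq/human).

    MBq/m² = (MBq / mouse weight kg) x mouse km;
    MBq/human = MBq/m² x reference adult-male BSA.
    """
    if mbq_per_animal < 0:
        raise InvalidInputError("activity must be >= 0")
    per_m2 = mbq_per_animal / params.weight_for("mouse") * params.km_for("mouse")
    return per_m2, per_m2 * params.human_bsa_m2


def safety_margin(max_activity_mbq: float, therapeutic_mbq: float,
                  adequate_threshold: float = 1.0) -> tuple[float, bool]:
    """Ratio of the administrable maximum to the therapeutic requirement.

    Returns (ratio, adequate); a ratio below the threshold is inadequate.
    """
    if therapeutic_mbq <= 0:
        raise InvalidInputError("therapeutic activity must be > 0")
    ratio = float(max_activity_mbq) / float(therapeutic_mbq)
    return ratio, bool(ratio >= adequate_threshold)
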