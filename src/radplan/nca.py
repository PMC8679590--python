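"""Noncompartmental analysis and time-integrated activity coefficients.

The NCA follows the conventional bolus-IV recipe: observed Cmax/Tmax,
trapezoidal AUC to the last sample, a log-linear terminal fit with
automatic tail selection (best adjusted R², ties toward more points,
Tmax excluded), Clast/λz extrapolation, and the derived CL, MRT and Vss.

TIAC helpers impose physical decay on biologically-scaled curves,
humanize monkey blood kinetics to a reference adult male, and derive
the red-marrow coefficient from blood via the extracellular-fluid
method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .curves import TimeActivityCurve
from .errors import (
    CannotFitTerminalError,
    DegenerateCurveError,
    InconsistentTiacsError,
    InsufficientDataError,
    InvalidInputError,
)

LN2 = math.log(2.0)

#: adjusted-R² window within which a longer tail is preferred
_TIE_TOL = 1e-4


@dataclass(frozen=True)
class NCAResult:
    """Noncompartmental parameters for one curve.

    ``cl`` and ``vss`` are expressed against the nominal dose passed to
    :func:`nca` (100 %ID by default), so a %ID/g curve yields CL in g/h
    and Vss in g; a %ID/mL curve yields mL/h and mL.
    """

    cmax: float
    tmax: float
    auc_last: float
    auc_inf: float
    aumc_inf: float
    lambda_z: float
    t_half: float
    cl: float
    vss: float
    mrt: float
    n_tail_points: int
    r2_adj: float
    extrapolated_fraction: float


@dataclass(frozen=True)
class HumanizationParams:
    """Constants for translating monkey blood FIA/mL to a reference man."""

    monkey_body_mass_g: float
    reference_body_mass_g: float = 73_700.0
    reference_blood_volume_ml: float = 5_300.0
    y90_half_life_h: float = 64.0

    def __post_init__(self) -> None:
        for f in (
            self.monkey_body_mass_g, self.reference_body_mass_g,
            self.reference_blood_volume_ml, self.y90_half_life_h,
        ):
            if f <= 0:
                raise InvalidInputError("humanization parameters must be > 0")


@dataclass(frozen=True)
class RedMarrowParams:
    """Blood-based red-marrow activity model constants."""

    reference_red_marrow_mass_g: float = 1_120.0
    rmecff: float = 0.19  # marrow extracellular fluid fraction
    hct: float = 0.47  # hematocrit

    def __post_init__(self) -> None:
        if not (0.0 < self.rmecff < 1.0):
            raise InvalidInputError("rmecff must be in (0, 1)")
        if not (0.0 < self.hct < 1.0):
            raise InvalidInputError("hct must be in (0, 1)")
        if self.reference_red_marrow_mass_g <= 0:
            raise InvalidInputError("marrow mass must be > 0")


def _auc_segments(t: np.ndarray, y: np.ndarray, rule: str) -> tuple[float, float]:
    """AUC and AUMC over the observed span.

    ``rule`` is ``"linear"`` (default trapezoid throughout) or
    ``"linuplogdown"`` (log trapezoid on strictly decreasing positive
    segments).
    """
    auc = aumc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        y1, y2 = y[i], y[i + 1]
        if rule == "linuplogdown" and y1 > y2 > 0:
            k = math.log(y1 / y2) / dt
            auc += (y1 - y2) / k
            # closed form of the log-linear moment integral
            aumc += (t[i] * y1 - t[i + 1] * y2) / k + (y1 - y2) / k**2
        else:
            auc += 0.5 * (y1 + y2) * dt
            aumc += 0.5 * (t[i] * y1 + t[i + 1] * y2) * dt
    return auc, aumc


def _fit_lambda_z(t: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Automatic terminal-slope selection.

    Candidate tails start strictly after Tmax and contain >= 3 positive
    samples.  Each is fit by log-linear least squares; the tail with the
    best adjusted R² wins, with ties (within 1e-4) broken toward more
    points — mirroring the common commercial default.

    Returns (lambda_z, n_points, adjusted_r2).
    """
    tmax_idx = int(np.argmax(y))
    n = len(t)
    candidates = []
    for start in range(tmax_idx + 1, n - 2):
        yy = y[start:]
        if np.any(yy <= 0):
            continue
        res = stats.linregress(t[start:], np.log(yy))
        lam = -res.slope
        if lam <= 0:
            continue
        m = n - start
        r2 = res.rvalue**2
        r2_adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        candidates.append((lam, m, r2_adj))
    if not candidates:
        raise CannotFitTerminalError(
            "no valid terminal phase (need >=3 positive points after Tmax "
            "with negative log-linear slope)"
        )
    best_adj = max(c[2] for c in candidates)
    eligible = [c for c in candidates if c[2] >= best_adj - _TIE_TOL]
    return max(eligible, key=lambda c: c[1])  # most points among near-ties


def nca(
    curve: TimeActivityCurve,
    dose_pid: float = 100.0,
    rule: str = "linear",
    extrapolation_warn_fraction: float = 0.30,
) -> NCAResult:
    """Noncompartmental parameters of a concentration–time curve.

    Parameters
    ----------
    curve : TimeActivityCurve
    dose_pid : float
        Nominal administered dose on the curve's %-scale.  100 %ID means
        CL carries the reciprocal of the concentration denominator
        (g/h for %ID/g, mL/h for %ID/mL).
    rule : {"linear", "linuplogdown"}
        Trapezoid variant for observed-span integration.
    """
    if rule not in ("linear", "linuplogdown"):
        raise InvalidInputError(f"unknown trapezoid rule {rule!r}")
    if len(curve) < 3:
        raise InsufficientDataError("NCA requires at least 3 samples")
    t = curve.times
    y = curve.values

    i_max = int(np.argmax(y))
    cmax = float(y[i_max])
    tmax = float(t[i_max])

    auc_last, aumc_last = _auc_segments(t, y, rule)
    lam, n_tail, r2_adj = _fit_lambda_z(t, y)

    clast, tlast = float(y[-1]), float(t[-1])
    if clast <= 0:
        raise CannotFitTerminalError("last observation must be positive")
    auc_tail = clast / lam
    auc_inf = auc_last + auc_tail
    aumc_inf = aumc_last + clast * tlast / lam + clast / lam**2

    extrap = auc_tail / auc_inf
    if extrap > extrapolation_warn_fraction:
        warnings.warn(
            f"{extrap:.0%} of AUC is extrapolated for "
            f"{curve.subject_id}/{curve.compartment}",
            stacklevel=2,
        )

    cl = dose_pid / auc_inf
    mrt = aumc_inf / auc_inf
    return NCAResult(
        cmax=cmax, tmax=tmax, auc_last=auc_last, auc_inf=auc_inf,
        aumc_inf=aumc_inf, lambda_z=lam, t_half=LN2 / lam, cl=cl,
        vss=cl * mrt, mrt=mrt, n_tail_points=n_tail, r2_adj=r2_adj,
        extrapolated_fraction=extrap,
    )


def apply_y90_decay(curve: TimeActivityCurve, half_life_h: float = 64.0) -> TimeActivityCurve:
    """Impose physical decay: value x 0.5^(t / half-life), pointwise."""
    if curve.unit not in ("fia", "fia_per_ml"):
        raise InvalidInputError("decay is applied to FIA-family curves")
    if half_life_h <= 0:
        raise InvalidInputError("half-life must be > 0")
    return curve.with_values(curve.values * 0.5 ** (curve.times / half_life_h))


def humanize_fia(curve: TimeActivityCurve, params: HumanizationParams) -> TimeActivityCurve:
    """Humanize a decay-corrected monkey blood FIA/mL curve and scale it.

    humanized = decayed FIA/mL x monkey mass / reference mass;
    humanized max FIA = peak humanized FIA/mL x reference blood volume;
    output = humanized / humanized max FIA, so that the scaled curve's
    whole-blood maximum is 1.0 (peak per-mL value = 1 / blood volume).
    """
    if curve.unit != "fia_per_ml":
        raise InvalidInputError("humanize_fia expects an FIA/mL curve")
    humanized = curve.values * (params.monkey_body_mass_g / params.reference_body_mass_g)
    peak = float(np.max(humanized)) if len(curve) else 0.0
    if peak <= 0:
        raise DegenerateCurveError("zero peak: cannot humanize")
    max_fia = peak * params.reference_blood_volume_ml
    return curve.with_values(humanized / max_fia)


def tiac_from_curve(curve: TimeActivityCurve, rule: str = "linear") -> float:
    """Time-integrated activity coefficient (h): AUC0–inf of an FIA curve.

    Decay must already be imposed.  An identically-zero curve integrates
    to 0 without attempting a terminal fit.
    """
    if curve.unit not in ("fia", "fia_per_ml"):
        raise InvalidInputError("TIAC integrates FIA-family curves")
    if np.all(curve.values == 0):
        return 0.0
    return nca(curve, rule=rule).auc_inf


def red_marrow_tiac(t_blood_per_ml: float, p: RedMarrowParams = RedMarrowParams()) -> float:
    """Red-marrow TIAC (h) from the blood coefficient (h/mL).

    T_marrow = T_blood/mL x marrow mass x RMECFF / (1 - HCT).
    """
    if t_blood_per_ml < 0:
        raise InvalidInputError("blood TIAC must be >= 0")
    return t_blood_per_ml * p.reference_red_marrow_mass_g * p.rmecff / (1.0 - p.hct)


#: organ sources subtracted from whole body when forming the remainder.
#: Red marrow is blood-derived, not image-derived, and is NOT subtracted.
REMAINDER_SOURCES = ("heart_contents", "liver", "lungs", "spleen")


def remainder_tiac(tiacs: Mapping[str, float], sources=REMAINDER_SOURCES) -> float:
    """Remainder-of-body TIAC: whole body minus the named organ sources."""
    if "whole_body" not in tiacs:
        raise InvalidInputError("whole_body TIAC required")
    organ_sum = sum(tiacs.get(s, 0.0) for s in sources)
    rem = tiacs["whole_body"] - organ_sum
    if rem < 0:
        raise InconsistentTiacsError(
            f"organ TIACs ({organ_sum:.3g} h) exceed whole body "
            f"({tiacs['whole_body']:.3g} h)"
        )
    return rem
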