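"""Synthetic-data generators with known ground truth.

Every generator returns both the data product (curve / DataFrame) and a
``truth`` dict holding the analytic quantities the pipeline is supposed
to recover, so each stage has a noiseless exact-recovery test and a
noisy statistical test.

Kinetic forms
-------------
* Blood: biexponential, FIA/mL(t) = A e^(-αt) + B e^(-βt).
* Organs: uptake-washout, FIA(t) = f (e^(-k_w t) - e^(-k_u t)) / g(t*)
  where g(t*) is the peak of the bracket, so f is the peak fraction.
* Whole body: slow monoexponential clearance.

Noise: Poisson on detector counts, multiplicative lognormal on
continuous measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import TimeActivityCurve
from .errors import InvalidInputError
from .quantify import (
    BACKGROUND_CORNER,
    BODY_BACKGROUND,
    CALIBRATION_SOURCE,
    WHOLE_BODY,
    CountingStandard,
)

LN2 = math.log(2.0)


@dataclass(frozen=True)
class OrganKinetics:
    """Rise-and-washout parameters for one organ."""

    uptake_fraction: float  # peak FIA in the organ
    uptake_rate: float  # 1/h, fast
    washout_rate: float  # 1/h, slow

    def __post_init__(self) -> None:
        if not (0 <= self.uptake_fraction <= 1):
            raise InvalidInputError("uptake fraction must be in [0, 1]")
        if not (self.uptake_rate > self.washout_rate > 0):
            raise InvalidInputError("need uptake rate > washout rate > 0")

    def _peak_bracket(self) -> float:
        ku, kw = self.uptake_rate, self.washout_rate
        t_star = math.log(ku / kw) / (ku - kw)
        return math.exp(-kw * t_star) - math.exp(-ku * t_star)

    def fia(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ku, kw = self.uptake_rate, self.washout_rate
        return self.uptake_fraction * (np.exp(-kw * t) - np.exp(-ku * t)) / self._peak_bracket()

    def analytic_tiac(self, decay_lambda: float = 0.0) -> float:
        """Exact 0..inf integral of the organ FIA under extra decay λ (h)."""
        ku, kw = self.uptake_rate, self.washout_rate
        c = self.uptake_fraction / self._peak_bracket()
        return c * (1.0 / (kw + decay_lambda) - 1.0 / (ku + decay_lambda))


@dataclass(frozen=True)
class SubjectSpec:
    """One synthetic subject: species, size, blood and organ kinetics."""

    species: str  # "mouse" or "monkey"
    body_weight_kg: float
    blood_a: float  # fast amplitude, FIA per mL (or per g for mice)
    blood_alpha: float  # 1/h
    blood_b: float  # slow amplitude
    blood_beta: float  # 1/h
    organ_params: Mapping[str, OrganKinetics] = field(default_factory=dict)
    whole_body_fia0: float = 0.0
    whole_body_clearance: float = 0.0  # 1/h
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "monkey"):
            raise InvalidInputError("species must be 'mouse' or 'monkey'")
        if self.blood_a < 0 or self.blood_b < 0:
            raise InvalidInputError("amplitudes must be >= 0")
        if not (self.blood_alpha > self.blood_beta > 0):
            raise InvalidInputError("need alpha > beta > 0")
        if sum(o.uptake_fraction for o in self.organ_params.values()) > 1:
            raise InvalidInputError("organ uptake fractions must sum to <= 1")

    def blood_fia_per_ml(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.blood_a * np.exp(-self.blood_alpha * t) + self.blood_b * np.exp(
            -self.blood_beta * t
        )

    def whole_body_fia(self, t: np.ndarray) -> np.ndarray:
        return self.whole_body_fia0 * np.exp(-self.whole_body_clearance * np.asarray(t, float))


@dataclass(frozen=True)
class NoiseSpec:
    """Counting and measurement noise switches."""

    counting: str = "none"  # "none" or "poisson"
    measurement_cv: float = 0.0  # lognormal CV on continuous values
    background_cpp_mean: float = 0.0  # counts/pixel added under every ROI

    def __post_init__(self) -> None:
        if self.counting not in ("none", "poisson"):
            raise InvalidInputError("counting noise must be 'none' or 'poisson'")
        if self.measurement_cv < 0 or self.background_cpp_mean < 0:
            raise InvalidInputError("noise magnitudes must be >= 0")


# ---------------------------------------------------------------------------
# default subjects (tuned to sit inside the study's reported ranges; the
# constants are calibration choices, not measured kinetics)

#: mouse blood: peak 35.3 %ID/g at 5 min, terminal biologic T1/2 ~273 h
DEFAULT_MOUSE = SubjectSpec(
    species="mouse", body_weight_kg=0.025,
    blood_a=0.05, blood_alpha=1.0,
    blood_b=0.3071, blood_beta=LN2 / 273.0,
    seed=0,
)

#: monkey: whole body 75 %ID at 3 h falling to ~55 %ID at 168 h; organ
#: peaks placed so the 3 h values land at heart ~8, liver ~11, spleen ~3,
#: lungs ~5 %ID
DEFAULT_MONKEY = SubjectSpec(
    species="monkey", body_weight_kg=3.2,
    blood_a=0.0008, blood_alpha=2.0,
    blood_b=0.0021, blood_beta=LN2 / 150.0,
    organ_params={
        "heart": OrganKinetics(0.085, 1.2, 0.004),
        "liver": OrganKinetics(0.112, 1.2, 0.004),
        "spleen": OrganKinetics(0.032, 1.2, 0.004),
        "lungs": OrganKinetics(0.051, 1.2, 0.004),
    },
    whole_body_fia0=0.75 * math.exp(3 * 0.0018797),
    whole_body_clearance=0.0018797,
    seed=0,
)

#: γ-camera imaging schedule (h)
MONKEY_IMAGING_TIMES = (3.0, 6.0, 24.0, 48.0, 72.0, 96.0, 144.0, 168.0)
#: blood sampling schedule (h)
MONKEY_BLOOD_TIMES = (0.17, 0.5, 1.0, 3.0, 6.0, 24.0, 48.0, 72.0, 96.0, 144.0, 168.0, 216.0)
MOUSE_BLOOD_TIMES = (5.0 / 60.0, 24.0, 48.0, 96.0, 192.0)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-median multiplicative lognormal noise with the given CV."""
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def gen_blood_curve(
    spec: SubjectSpec,
    times: Sequence[float] | None = None,
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
) -> tuple[TimeActivityCurve, dict]:
    """Sample the analytic blood curve, optionally with measurement noise.

    Returns a %ID/mL (monkey) or %ID/g (mouse) curve and a truth record
    with the analytic AUC (in matching %ID units x h), terminal half-life
    and the decayed (64 h) AUC of the FIA form.
    """
    if times is None:
        times = MONKEY_BLOOD_TIMES if spec.species == "monkey" else MOUSE_BLOOD_TIMES
    t = np.asarray(times, dtype=float)
    fia = spec.blood_fia_per_ml(t)
    values = fia * 100.0
    if noise.measurement_cv > 0:
        rng = np.random.default_rng(spec.seed) if rng is None else rng
        values = values * _lognormal_factor(rng, noise.measurement_cv, t.shape)
    unit = "pid_per_ml" if spec.species == "monkey" else "pid_per_g"
    curve = TimeActivityCurve(
        subject_id=f"{spec.species}-{spec.seed}", compartment="blood",
        unit=unit, times=t, values=values,
    )
    lam = LN2 / 64.0
    truth = {
        "auc_pid_h": 100.0 * (spec.blood_a / spec.blood_alpha + spec.blood_b / spec.blood_beta),
        "t_half_h": LN2 / spec.blood_beta,
        "cmax_pid": float(np.max(values)),
        "fia_auc_decayed_h_per_ml": spec.blood_a / (spec.blood_alpha + lam)
        + spec.blood_b / (spec.blood_beta + lam),
    }
    return curve, truth


def gen_gamma_counts(
    curve: TimeActivityCurve,
    std: CountingStandard,
    sample_amount: float = 1.0,
    amount_unit: str = "mL",
    noise: NoiseSpec = NoiseSpec(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Project a %ID curve into a ``gamma_counts.csv`` table.

    Inverse of the counting-standard arithmetic: counts = value/100 x
    administered activity x amount.  Exact in noiseless mode.
    """
    from .quantify import administered_activity

    adm = administered_activity(std)
    counts = curve.values / 100.0 * adm * sample_amount
    if noise.counting == "poisson":
        rng = np.random.default_rng(0) if rng is None else rng
        counts = rng.poisson(counts).astype(float)
    return pd.DataFrame(
        {
            "subject_id": curve.subject_id,
            "compartment": curve.compartment,
            "time_h": curve.times,
            "counts_cpm": counts,
            "amount": sample_amount,
            "amount_unit": amount_unit,
        }
    )


def gen_organ_curves(
    spec: SubjectSpec, times: Sequence[float] | None = None
) -> tuple[dict[str, TimeActivityCurve], dict]:
    """Noise-free organ and whole-body %ID curves for a monkey subject.

    Truth carries the exact decayed (64 h) TIAC of every organ, the whole
    body, and the implied remainder.
    """
    if times is None:
        times = MONKEY_IMAGING_TIMES
    t = np.asarray(times, dtype=float)
    sid = f"{spec.species}-{spec.seed}"
    curves: dict[str, TimeActivityCurve] = {}
    lam = LN2 / 64.0
    tiacs: dict[str, float] = {}
    for organ, kin in spec.organ_params.items():
        vals = kin.fia(t) * 100.0
        curves[organ] = TimeActivityCurve(
            subject_id=sid, compartment=organ, unit="pid", times=t, values=vals
        )
        tiacs[organ] = kin.analytic_tiac(lam)
    wb = spec.whole_body_fia(t) * 100.0
    if np.any(sum(c.values for c in curves.values()) > wb + 1e-9):
        raise InvalidInputError("organ sum exceeds whole body; retune the spec")
    curves[WHOLE_BODY] = TimeActivityCurve(
        subject_id=sid, compartment=WHOLE_BODY, unit="pid", times=t, values=wb
    )
    tiacs[WHOLE_BODY] = spec.whole_body_fia0 / (spec.whole_body_clearance + lam)
    truth = {
        "tiac_decayed_h": tiacs,
        "remainder_tiac_h": tiacs[WHOLE_BODY] - sum(
            tiacs[o] for o in spec.organ_params
        ),
        "pid_at": {c: dict(zip(t.tolist(), cv.values.tolist())) for c, cv in curves.items()},
    }
    return curves, truth


#: ROI geometry used by the planar projector (pixels)
_ROI_SIZES = {
    CALIBRATION_SOURCE: 250.0,
    WHOLE_BODY: 20_000.0,
    "heart": 900.0,
    "liver": 2_200.0,
    "spleen": 500.0,
    "lungs": 1_600.0,
}
_N_CORNER_BG = 4
_CORNER_BG_SIZE = 400.0
_N_BODY_BG = 8
_BODY_BG_SIZE = 100.0


def gen_planar_study(
    curves: Mapping[str, TimeActivityCurve],
    calibration_ratio: float,
    administered_count: float = 1.0e6,
    noise: NoiseSpec = NoiseSpec(),
    body_background_cpp: float | None = None,
    view_asymmetry: float = 0.1,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Project %ID curves into a two-view ``planar_rois.csv`` table.

    Exact inverse of the conjugate-view quantifier in noiseless mode:
    ROI count = net + background CPP x size, with net = %ID/100 x
    administered count (body-background CPP under organs, corner CPP
    under calibration source and whole body).  The two views carry nets
    scaled by (1 ± asymmetry) so their arithmetic mean is exact.

    ``curves`` must contain ``whole_body``; every other key becomes an
    organ ROI.
    """
    if WHOLE_BODY not in curves:
        raise InvalidInputError("curves must include whole_body")
    if calibration_ratio <= 0:
        raise InvalidInputError("calibration ratio must be > 0")
    rng = np.random.default_rng(0) if rng is None else rng
    bg_cpp = noise.background_cpp_mean
    body_cpp = bg_cpp if body_background_cpp is None else body_background_cpp

    times = curves[WHOLE_BODY].times
    sid = curves[WHOLE_BODY].subject_id
    rows = []

    def emit(time_h, view, label, expected, size):
        count = float(expected)
        if noise.counting == "poisson":
            count = float(rng.poisson(max(expected, 0.0)))
        rows.append(
            {
                "subject_id": sid, "time_h": time_h, "view": view,
                "roi_label": label, "count": count, "size_px": size,
            }
        )

    for i, t in enumerate(times):
        for view, sgn in (("anterior", 1.0), ("posterior", -1.0)):
            fac = 1.0 + sgn * view_asymmetry
            for _ in range(_N_CORNER_BG):
                emit(t, view, BACKGROUND_CORNER, bg_cpp * _CORNER_BG_SIZE, _CORNER_BG_SIZE)
            for _ in range(_N_BODY_BG):
                emit(t, view, BODY_BACKGROUND, body_cpp * _BODY_BG_SIZE, _BODY_BG_SIZE)
            calib_net = calibration_ratio * administered_count
            emit(t, view, CALIBRATION_SOURCE,
                 calib_net * fac + bg_cpp * _ROI_SIZES[CALIBRATION_SOURCE],
                 _ROI_SIZES[CALIBRATION_SOURCE])
            for label, curve in curves.items():
                pid = curve.values[i]
                net = pid / 100.0 * administered_count * fac
                cpp = bg_cpp if label == WHOLE_BODY else body_cpp
                size = _ROI_SIZES.get(label, 800.0)
                emit(t, view, label, net + cpp * size, size)

    truth = {
        "administered_count": administered_count,
        "calibration_ratio": calibration_ratio,
        "pid": {c: dict(zip(times.tolist(), cv.values.tolist())) for c, cv in curves.items()},
    }
    return pd.DataFrame(rows), truth


def gen_binding_assay(
    kd_nm: float = 1.083,
    bmax_cpm: float = 5_000.0,
    top_nm: float = 20.0,
    n_steps: int = 8,
    dilution: float = 2.0,
    ns_slope_cpm_per_nm: float = 30.0,
    noise_cv: float = 0.0,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Serial-dilution saturation assay as a ``binding.csv`` table.

    Concentrations form an exact geometric series (``n_steps`` steps of
    ``dilution``-fold).  Total wells carry specific (1-site) plus linear
    nonspecific counts; negative-control wells carry the nonspecific
    component only.  Lognormal noise with CV ``noise_cv`` per well.
    """
    if n_steps < 1 or dilution <= 1:
        raise InvalidInputError("need n_steps >= 1 and dilution > 1")
    rng = np.random.default_rng(0) if rng is None else rng
    conc = top_nm / dilution ** np.arange(n_steps)
    from .assays import one_site_binding

    specific = one_site_binding(conc, bmax_cpm, kd_nm)
    ns = ns_slope_cpm_per_nm * conc
    rows = []
    for rep in range(n_replicates):
        for c, s, n in zip(conc, specific, ns):
            tot, nsw = s + n, n
            if noise_cv > 0:
                tot *= _lognormal_factor(rng, noise_cv, None)
                nsw *= _lognormal_factor(rng, noise_cv, None)
            rows.append({"concentration_nm": c, "well_type": "total",
                         "counts_cpm": tot, "replicate": rep})
            rows.append({"concentration_nm": c, "well_type": "nonspecific",
                         "counts_cpm": nsw, "replicate": rep})
    truth = {"kd_nm": kd_nm, "bmax_cpm": bmax_cpm}
    return pd.DataFrame(rows), truth


def gen_tumor_study(
    groups: Mapping[str, float] | None = None,
    n_per_group: int = 6,
    start_mm3: float = 200.0,
    growth_rate_per_day: float = 0.10,
    days: Sequence[float] | None = None,
    start_weight_g: float = 25.0,
    noise_cv: float = 0.0,
    aspect_ratio: float = 1.6,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Xenograft growth log as a ``tumor_log.csv`` table.

    ``groups`` maps group name -> treatment effect in [0, 1]; net growth
    rate is g x (1 - effect) - g x effect, so effect 0 doubles freely and
    effect 1 shrinks monotonically (never regrows).  Measurements run
    twice a week.  Diameters derive from volume with a fixed long/short
    aspect ratio via V = L S² / 2.
    """
    if groups is None:
        groups = {"control": 0.0, "treated": 1.0}
    if days is None:
        days = [0, 3, 7, 10, 14, 17, 21, 24, 28]
    rng = np.random.default_rng(0) if rng is None else rng
    rows = []
    truth_rates = {}
    for gname, effect in groups.items():
        if not (0.0 <= effect <= 1.0):
            raise InvalidInputError("effect must be in [0, 1]")
        rate = growth_rate_per_day * (1.0 - 2.0 * effect)
        truth_rates[gname] = rate
        for k in range(n_per_group):
            v0 = start_mm3
            if noise_cv > 0:
                v0 *= _lognormal_factor(rng, noise_cv, None)
            for d in days:
                v = v0 * math.exp(rate * d)
                if noise_cv > 0:
                    v *= _lognormal_factor(rng, noise_cv, None)
                short = (2.0 * v / aspect_ratio) ** (1.0 / 3.0)
                rows.append(
                    {
                        "animal_id": f"{gname}-{k}", "group": gname, "day": d,
                        "long_mm": aspect_ratio * short, "short_mm": short,
                        "body_weight_g": start_weight_g,
                    }
                )
    truth = {"net_growth_rate_per_day": truth_rates, "start_mm3": start_mm3}
    return pd.DataFrame(rows), truth
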