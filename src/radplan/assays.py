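"""In vitro and in vivo assay models.

Saturation-binding Kd/Bmax estimation with the 1-site hyperbola, the
Scatchard linearization, serum-stability normalization, and tumor-study
bookkeeping (ellipsoid volume, humane-endpoint rules).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class BindingAssay:
    """Specific binding vs ligand concentration for one saturation assay.

    ``specific_bound`` is total-well minus negative-control (nonspecific)
    counts at matched concentrations.
    """

    concentrations_nm: np.ndarray
    specific_bound: np.ndarray
    total_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.concentrations_nm, dtype=float)
        y = np.asarray(self.specific_bound, dtype=float)
        object.__setattr__(self, "concentrations_nm", x)
        object.__setattr__(self, "specific_bound", y)
        if np.any(x <= 0):
            raise InvalidInputError("concentrations must be > 0")
        d = np.diff(x)
        if x.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidInputError("concentrations must be strictly monotone")
        if self.total_counts is not None:
            object.__setattr__(
                self, "total_counts", np.asarray(self.total_counts, dtype=float)
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BindingAssay":
        """Build from a ``binding.csv`` table.

        Wells are averaged over replicates per concentration; specific
        binding is mean(total) - mean(nonspecific).
        """
        piv = df.pivot_table(
            index="concentration_nm", columns="well_type", values="counts_cpm",
            aggfunc="mean",
        ).sort_index()
        total = piv["total"].to_numpy()
        ns = piv["nonspecific"].to_numpy() if "nonspecific" in piv else np.zeros_like(total)
        return cls(
            concentrations_nm=piv.index.to_numpy(dtype=float),
            specific_bound=total - ns,
            total_counts=total,
        )


@dataclass(frozen=True)
class BindingFit:
    kd_nm: float
    bmax: float
    residual_ss: float
    converged: bool
    n_points: int


@dataclass(frozen=True)
class TumorMeasurement:
    long_diameter_mm: float
    short_diameter_mm: float
    body_weight_g: float
    day: float

    def __post_init__(self) -> None:
        if not (self.long_diameter_mm >= self.short_diameter_mm > 0):
            raise InvalidInputError("need long >= short > 0")
        if self.body_weight_g <= 0:
            raise InvalidInputError("body weight must be > 0")


def one_site_binding(x, bmax: float, kd: float):
    """1-site hyperbola: bound = bmax * x / (kd + x)."""
    if kd <= 0:
        raise InvalidInputError("kd must be > 0")
    x = np.asarray(x, dtype=float)
    return bmax * x / (kd + x)


def _kd_initial_guess(x: np.ndarray, y: np.ndarray) -> float:
    """Concentration at half the observed maximum, by linear interpolation."""
    bmax0 = float(np.max(y))
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    half = bmax0 / 2.0
    above = np.nonzero(ys >= half)[0]
    if above.size == 0 or above[0] == 0:
        return float(xs[0])
    i = above[0]
    x0, x1, y0, y1 = xs[i - 1], xs[i], ys[i - 1], ys[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def fit_saturation(assay: BindingAssay, weighting: str = "none") -> BindingFit:
    """Nonlinear least-squares fit of the 1-site model.

    Unweighted by default (the common graphing-software default);
    ``weighting="1/y2"`` applies relative weighting.  Non-convergence is
    reported via the ``converged`` flag, never as an exception.
    """
    x = assay.concentrations_nm
    y = assay.specific_bound
    if np.unique(x).size < 4:
        raise InsufficientDataError("need >= 4 distinct concentrations")
    if weighting not in ("none", "1/y2"):
        raise InvalidInputError(f"unknown weighting {weighting!r}")

    if np.ptp(y) == 0:  # flat data: Kd unidentifiable
        return BindingFit(kd_nm=np.nan, bmax=float(y[0]) if y.size else np.nan,
                          residual_ss=0.0, converged=False, n_points=int(x.size))

    p0 = (float(np.max(y)), _kd_initial_guess(x, y))
    sigma = np.maximum(np.abs(y), np.max(y) * 1e-6) if weighting == "1/y2" else None
    try:
        popt, _ = curve_fit(
            lambda xx, bmax, kd: bmax * xx / (kd + xx),
            x, y, p0=p0, sigma=sigma,
            bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10_000,
        )
    except RuntimeError:
        return BindingFit(kd_nm=np.nan, bmax=np.nan, residual_ss=np.nan,
                          converged=False, n_points=int(x.size))
    bmax, kd = float(popt[0]), float(popt[1])
    resid = y - one_site_binding(x, bmax, kd)
    return BindingFit(kd_nm=kd, bmax=bmax, residual_ss=float(resid @ resid),
                      converged=True, n_points=int(x.size))


def scatchard(
    concentrations_nm: Sequence[float],
    bound: Sequence[float],
    free_nm: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatchard transform: (bound, bound/free) pairs — no fitting.

    ``free_nm`` defaults to the added ligand concentration (excess-ligand
    approximation).  For exact 1-site data the points fall on a line of
    slope -1/Kd with bound-axis intercept Bmax.
    """
    b = np.asarray(bound, dtype=float)
    f = np.asarray(free_nm if free_nm is not None else concentrations_nm, dtype=float)
    if np.any(f <= 0):
        raise InvalidInputError("free concentration must be > 0")
    return b, b / f


def stability_normalize(times_h: Sequence[float], values: Sequence[float]) -> np.ndarray:
    """Express a stability series as percent of its t = 0 value."""
    t = np.asarray(times_h, dtype=float)
    v = np.asarray(values, dtype=float)
    at0 = np.nonzero(t == 0)[0]
    if at0.size == 0:
        raise InvalidInputError("a t = 0 measurement is required")
    v0 = v[at0[0]]
    if v0 <= 0:
        raise InvalidInputError("t = 0 value must be > 0")
    return v / v0 * 100.0


def tumor_volume(m: TumorMeasurement) -> float:
    """Ellipsoid-style volume: long x short² / 2, in mm³."""
    return m.long_diameter_mm * m.short_diameter_mm**2 / 2.0


#: 1 mm³ of tumor is booked as 1 mg of tissue for the 10 %-of-body-weight rule
TUMOR_DENSITY_MG_PER_MM3 = 1.0


def endpoint_check(m: TumorMeasurement, baseline_weight_g: float) -> str:
    """Humane-endpoint decision: continue / euthanize_weight / euthanize_tumor.

    Weight rule: body weight fell below 80 % of baseline.
    Tumor rule: tumor mass (1 mm³ = 1 mg) exceeds 10 % of body weight.
    The weight rule is evaluated first when both trigger.
    """
    if baseline_weight_g <= 0:
        raise InvalidInputError("baseline weight must be > 0")
    if m.body_weight_g < 0.8 * baseline_weight_g:
        return "euthanize_weight"
    tumor_mg = tumor_volume(m) * TUMOR_DENSITY_MG_PER_MM3
    if tumor_mg > 0.10 * m.body_weight_g * 1000.0:
        return "euthanize_tumor"
    return "continue"
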