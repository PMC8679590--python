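"""Raw-count quantification.

Converts γ-counter sample counts and planar γ-camera ROI counts into
%ID-based time–activity curves.

Two input families are handled:

* **γ-counter samples** (blood, dissolved tissues): counts per sample are
  referenced to a counting standard (a diluted aliquot of the administered
  solution) to express activity as a percentage of the injected dose per
  mL or per gram.

* **Planar conjugate views**: anterior/posterior whole-body images with
  corner-background and body-background (muscle) ROIs, a co-imaged
  calibration source, and organ ROIs.  Net counts are
  background-subtracted per view, the two views are arithmetically
  averaged, and %ID is formed against the administered count inferred
  from the calibration source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curves import TimeActivityCurve
from .errors import (
    IncompleteTimepointError,
    InvalidInputError,
    MissingBackgroundError,
)

VIEWS = ("anterior", "posterior")

#: ROI labels with dedicated roles; anything else is treated as an organ.
BACKGROUND_CORNER = "background_corner"
BODY_BACKGROUND = "body_background"
CALIBRATION_SOURCE = "calibration_source"
WHOLE_BODY = "whole_body"
_SPECIAL_LABELS = {BACKGROUND_CORNER, BODY_BACKGROUND, CALIBRATION_SOURCE}


@dataclass(frozen=True)
class CountingStandard:
    """Diluted aliquot of the administered solution counted alongside samples."""

    counts: float  # cpm
    volume_counted: float  # mL
    dilution_factor: float  # >= 1
    administered_volume: float  # mL

    def __post_init__(self) -> None:
        if self.counts <= 0:
            raise InvalidInputError("counting standard counts must be > 0")
        if self.volume_counted <= 0 or self.administered_volume <= 0:
            raise InvalidInputError("counting standard volumes must be > 0")
        if self.dilution_factor < 1:
            raise InvalidInputError("dilution factor must be >= 1")


@dataclass(frozen=True)
class SampleCount:
    """One γ-counter measurement of a blood/tissue sample."""

    subject_id: str
    compartment: str
    time_h: float
    counts: float  # cpm, >= 0
    amount: float  # mL or g, > 0
    amount_unit: str = "mL"  # "mL" or "g"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise InvalidInputError("sample amount must be > 0")
        if self.counts < 0:
            raise InvalidInputError("sample counts must be >= 0")
        if self.time_h < 0:
            raise InvalidInputError("sample time must be >= 0")
        if self.amount_unit not in ("mL", "g"):
            raise InvalidInputError("amount_unit must be 'mL' or 'g'")


@dataclass(frozen=True)
class ROIRecord:
    """One ROI measurement from one planar view at one timepoint."""

    time_h: float
    view: str
    roi_label: str
    count: float  # raw counts >= 0
    size_px: float  # > 0

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise InvalidInputError(f"view must be one of {VIEWS}")
        if self.count < 0:
            raise InvalidInputError("ROI count must be >= 0")
        if self.size_px <= 0:
            raise InvalidInputError("ROI size must be > 0")


@dataclass
class PlanarStudy:
    """All ROI records for one subject across imaging sessions."""

    subject_id: str
    records: list[ROIRecord] = field(default_factory=list)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str | None = None) -> "PlanarStudy":
        """Build from a ``planar_rois.csv``-layout DataFrame."""
        if subject_id is not None:
            df = df[df["subject_id"].astype(str) == str(subject_id)]
        elif "subject_id" in df.columns:
            ids = df["subject_id"].astype(str).unique()
            if len(ids) != 1:
                raise InvalidInputError(f"expected one subject, got {list(ids)}")
            subject_id = ids[0]
        else:
            subject_id = "unknown"
        recs = [
            ROIRecord(
                time_h=float(r.time_h), view=str(r.view), roi_label=str(r.roi_label),
                count=float(r.count), size_px=float(r.size_px),
            )
            for r in df.itertuples()
        ]
        return cls(subject_id=str(subject_id), records=recs)

    def timepoints(self) -> list[float]:
        return sorted({r.time_h for r in self.records})

    def at(self, time_h: float, view: str) -> list[ROIRecord]:
        return [r for r in self.records if r.time_h == time_h and r.view == view]


def administered_activity(std: CountingStandard) -> float:
    """Total administered activity (cpm) from the counting standard.

    counts x dilution factor x administered volume / counted volume.
    """
    return std.counts * std.dilution_factor * std.administered_volume / std.volume_counted


def percent_id_per_ml(sample: SampleCount, std: CountingStandard) -> float:
    """%ID per mL (or per gram, when the amount is a mass) for one sample."""
    adm = administered_activity(std)
    if adm <= 0:
        raise InvalidInputError("invalid counting standard: administered activity <= 0")
    return (sample.counts / sample.amount) / adm * 100.0


def gamma_counts_to_curves(
    samples: pd.DataFrame, std: CountingStandard
) -> list[TimeActivityCurve]:
    """Convert a ``gamma_counts.csv`` table into %ID/mL (or %ID/g) curves."""
    curves = []
    for (sid, comp), grp in samples.groupby(["subject_id", "compartment"], sort=False):
        grp = grp.sort_values("time_h")
        units = grp["amount_unit"].unique()
        if len(units) != 1:
            raise InvalidInputError(f"mixed amount units for {sid}/{comp}")
        vals = [
            percent_id_per_ml(
                SampleCount(
                    subject_id=str(sid), compartment=str(comp), time_h=float(r.time_h),
                    counts=float(r.counts_cpm), amount=float(r.amount),
                    amount_unit=str(r.amount_unit),
                ),
                std,
            )
            for r in grp.itertuples()
        ]
        unit = "pid_per_ml" if units[0] == "mL" else "pid_per_g"
        curves.append(
            TimeActivityCurve(
                subject_id=str(sid), compartment=str(comp), unit=unit,
                times=grp["time_h"].to_numpy(dtype=float), values=np.array(vals),
            )
        )
    return curves


def background_cpp(rois: Iterable[ROIRecord], label: str) -> float:
    """Pooled counts-per-pixel over all ROIs carrying ``label``.

    Pooling (total counts / total pixels) rather than mean-of-ratios makes
    the estimate invariant to how the same pixels are partitioned into ROIs.
    """
    matched = [r for r in rois if r.roi_label == label]
    if not matched:
        raise MissingBackgroundError(f"no ROI labelled {label!r}")
    total_counts = sum(r.count for r in matched)
    total_px = sum(r.size_px for r in matched)
    return total_counts / total_px


def net_roi_count(roi: ROIRecord, cpp: float) -> float:
    """Background-subtracted ROI count: raw count - cpp x size.

    Negative nets are retained (clamping would bias whole-body-minus-organs
    arithmetic downstream) but flagged with a warning.
    """
    if cpp < 0:
        raise InvalidInputError("cpp must be >= 0")
    net = roi.count - cpp * roi.size_px
    if net < 0:
        warnings.warn(
            f"negative net count ({net:.1f}) for ROI {roi.roi_label!r} "
            f"at t={roi.time_h} h ({roi.view})",
            stacklevel=2,
        )
    return net


def conjugate_percent_id(
    study: PlanarStudy, std_ratio: float
) -> dict[str, TimeActivityCurve]:
    """Conjugate-view %ID curves for each organ and the whole body.

    Per timepoint and view: corner-background CPP is subtracted from the
    calibration-source and whole-body ROIs, body-background (muscle) CPP
    from organ ROIs.  Anterior/posterior nets are combined by arithmetic
    mean.  The administered count is the averaged calibration-source net
    divided by ``std_ratio`` (calibration-source activity / administered
    activity, both γ-counted).

    Returns a mapping compartment -> %ID curve, with key ``"whole_body"``
    included when a whole-body ROI is present.
    """
    if std_ratio <= 0:
        raise InvalidInputError("calibration-source ratio must be > 0")

    per_label: dict[str, dict[float, float]] = {}
    for t in study.timepoints():
        view_nets: dict[str, dict[str, float]] = {}
        for view in VIEWS:
            recs = study.at(t, view)
            if not recs:
                raise IncompleteTimepointError(f"missing {view} view at t={t} h")
            try:
                bg = background_cpp(recs, BACKGROUND_CORNER)
                body_bg = background_cpp(recs, BODY_BACKGROUND)
            except MissingBackgroundError as exc:
                raise IncompleteTimepointError(f"t={t} h ({view}): {exc}") from exc
            nets: dict[str, float] = {}
            for r in recs:
                if r.roi_label in (BACKGROUND_CORNER, BODY_BACKGROUND):
                    continue
                cpp = bg if r.roi_label in (CALIBRATION_SOURCE, WHOLE_BODY) else body_bg
                nets[r.roi_label] = net_roi_count(r, cpp)
            view_nets[view] = nets

        labels = set(view_nets["anterior"]) & set(view_nets["posterior"])
        if CALIBRATION_SOURCE not in labels:
            raise IncompleteTimepointError(f"missing calibration source at t={t} h")
        avg = {
            lab: 0.5 * (view_nets["anterior"][lab] + view_nets["posterior"][lab])
            for lab in labels
        }
        administered_count = avg.pop(CALIBRATION_SOURCE) / std_ratio
        if administered_count <= 0:
            raise IncompleteTimepointError(
                f"non-positive administered count at t={t} h"
            )
        for lab, net in avg.items():
            per_label.setdefault(lab, {})[t] = net / administered_count * 100.0

    out = {}
    for lab, series in per_label.items():
        times = np.array(sorted(series))
        out[lab] = TimeActivityCurve(
            subject_id=study.subject_id, compartment=lab, unit="pid",
            times=times, values=np.array([series[t] for t in times]),
            allow_negative=True,
        )
    return out


def scaled_percent_id(
    curve: TimeActivityCurve, body_weight_kg: float, blood_ml_per_kg: float = 65.0
) -> TimeActivityCurve:
    """Scale a blood %ID/mL curve to percent of its circulating-blood peak.

    max %ID = max(%ID/mL) x body weight (kg) x blood volume (mL/kg);
    every sample is divided by max %ID and multiplied by 100.
    """
    if curve.unit != "pid_per_ml":
        raise InvalidInputError("scaled_percent_id expects a %ID/mL curve")
    from .errors import DegenerateCurveError

    peak = float(np.max(curve.values)) if len(curve) else 0.0
    max_pid = peak * body_weight_kg * blood_ml_per_kg
    if max_pid <= 0:
        raise DegenerateCurveError("zero peak: cannot scale")
    return curve.with_values(curve.values / max_pid * 100.0, unit="pid_per_ml")


def read_counting_standard(df: pd.DataFrame, subject_id: str | None = None) -> CountingStandard:
    """Read one row of ``counting_standard.csv`` into a :class:`CountingStandard`."""
    if subject_id is not None:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    if len(df) != 1:
        raise InvalidInputError(f"expected exactly one counting-standard row, got {len(df)}")
    r = df.iloc[0]
    return CountingStandard(
        counts=float(r["counts_cpm"]), volume_counted=float(r["volume_ml"]),
        dilution_factor=float(r["dilution_factor"]),
        administered_volume=float(r["administered_volume_ml"]),
    )
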