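"""Time–activity curves.

A :class:`TimeActivityCurve` is the unit of exchange between pipeline
stages: an ordered list of ``(time_h, value)`` samples for one subject
and one compartment, with an explicit unit tag.

Units
-----
``pid_per_g``
    percent of injected dose per gram of tissue (%ID/g).
``pid_per_ml``
    percent of injected dose per mL (%ID/mL), the blood concentration form.
``pid``
    percent of injected dose in a whole region (%ID).
``fia``
    fraction of injected activity (= %ID / 100).
``fia_per_ml``
    fraction of injected activity per mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError

UNITS = frozenset({"pid_per_g", "pid_per_ml", "pid", "fia", "fia_per_ml"})

#: unit conversions within the %ID <-> FIA family (same geometric basis)
_PID_TO_FIA = {"pid_per_g": "fia", "pid_per_ml": "fia_per_ml", "pid": "fia"}


@dataclass(frozen=True)
class TimeActivityCurve:
    """Time-ordered samples of activity for one subject/compartment.

    Parameters
    ----------
    subject_id : str
    compartment : str
        e.g. ``"blood"``, ``"liver"``, ``"whole_body"``, ``"tumor"``.
    unit : str
        One of :data:`UNITS`.
    times : array-like of float
        Sample times in hours, strictly increasing, all >= 0.
    values : array-like of float
        Sample values in ``unit``.
    allow_negative : bool
        Permit negative values (background-subtracted planar data may
        carry small negative nets which are deliberately not clamped).
    """

    subject_id: str
    compartment: str
    unit: str
    times: np.ndarray
    values: np.ndarray
    allow_negative: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.unit not in UNITS:
            raise InvalidInputError(f"unknown unit {self.unit!r}")
        if t.ndim != 1 or v.shape != t.shape:
            raise InvalidInputError("times and values must be 1-D and congruent")
        if t.size and t[0] < 0:
            raise InvalidInputError("negative time")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if not self.allow_negative and t.size and np.any(v < 0):
            raise InvalidInputError("negative values (pass allow_negative=True to keep)")

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeActivityCurve":
        """Copy with new values (and optionally a new unit)."""
        return _dc_replace(
            self, values=np.asarray(values, dtype=float),
            unit=self.unit if unit is None else unit,
            allow_negative=self.allow_negative,
        )

    def to_fia(self) -> "TimeActivityCurve":
        """Convert a %ID-family curve to its FIA-family equivalent (/100)."""
        if self.unit in ("fia", "fia_per_ml"):
            return self
        return self.with_values(self.values / 100.0, unit=_PID_TO_FIA[self.unit])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "compartment": self.compartment,
                "unit": self.unit,
                "time_h": self.times,
                "value": self.values,
            }
        )


def curves_to_frame(curves) -> pd.DataFrame:
    """Concatenate curves into the canonical ``tac.csv`` layout."""
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)


def curves_from_frame(df: pd.DataFrame, allow_negative: bool = True) -> list[TimeActivityCurve]:
    """Inverse of :func:`curves_to_frame` (one curve per subject/compartment/unit)."""
    out = []
    for (sid, comp, unit), grp in df.groupby(["subject_id", "compartment", "unit"], sort=False):
        grp = grp.sort_values("time_h")
        out.append(
            TimeActivityCurve(
                subject_id=str(sid), compartment=str(comp), unit=str(unit),
                times=grp["time_h"].to_numpy(), values=grp["value"].to_numpy(),
                allow_negative=allow_negative,
            )
        )
    return out
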