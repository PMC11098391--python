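"""OGTT curve container and CSV I/O.

A standard 75 g oral glucose tolerance test in this design draws plasma
glucose at 0, 20, 40, 60, 80, 100 and 120 minutes.  Internally all glucose
values are kept in mg/mL and times in hours, which puts the model parameters
on comparable scales (roughly 0-10) and conditions the nonlinear fit; all
file I/O is in the clinical unit mg/dL with explicit conversion at the
boundary (1 mg/mL = 100 mg/dL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The fixed sampling grid in hours: 0, 20, ..., 120 minutes.
TIME_GRID_HOURS = np.array([0.0, 1 / 3, 2 / 3, 1.0, 4 / 3, 5 / 3, 2.0])

#: Conversion factor: glucose mg/mL -> mg/dL.
MG_ML_TO_MG_DL = 100.0

_CSV_COLUMNS = ["g0", "g20", "g40", "g60", "g80", "g100", "g120"]


@dataclass(frozen=True)
class OGTTCurve:
    """One participant's seven glucose measurements on the fixed time grid.

    Parameters
    ----------
    participant_id
        Identifier linking the curve to covariate records.
    glucose
        Seven glucose concentrations in mg/mL (canonical internal unit),
        all finite and strictly positive.
    """

    participant_id: str
    glucose: np.ndarray
    times: np.ndarray = field(default_factory=lambda: TIME_GRID_HOURS.copy())

    def __post_init__(self):
        glucose = np.asarray(self.glucose, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if glucose.shape != (7,):
            raise ValueError(f"expected 7 glucose values, got shape {glucose.shape}")
        if not np.all(np.isfinite(glucose)) or np.any(glucose <= 0):
            raise ValueError("glucose values must be finite and positive")
        if not np.allclose(times, TIME_GRID_HOURS, atol=1e-12):
            raise ValueError("times must equal the fixed 7-point grid in hours")
        object.__setattr__(self, "glucose", glucose)
        object.__setattr__(self, "times", times)

    @property
    def glucose_mg_dl(self) -> np.ndarray:
        return self.glucose * MG_ML_TO_MG_DL

    @classmethod
    def from_mg_dl(cls, participant_id: str, glucose_mg_dl) -> "OGTTCurve":
        """Build a curve from glucose values in mg/dL."""
        return cls(participant_id, np.asarray(glucose_mg_dl, dtype=float) / MG_ML_TO_MG_DL)


def curves_to_frame(curves: list[OGTTCurve]) -> pd.DataFrame:
    """Wide table (participant_id, g0..g120) with glucose in mg/dL."""
    rows = [
        {"participant_id": c.participant_id, **dict(zip(_CSV_COLUMNS, c.glucose_mg_dl))}
        for c in curves
    ]
    return pd.DataFrame(rows, columns=["participant_id"] + _CSV_COLUMNS)


def frame_to_curves(frame: pd.DataFrame) -> list[OGTTCurve]:
    """Inverse of :func:`curves_to_frame`; expects glucose in mg/dL."""
    missing = [c for c in ["participant_id"] + _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"curve table missing columns: {missing}")
    return [
        OGTTCurve.from_mg_dl(str(row["participant_id"]), [row[c] for c in _CSV_COLUMNS])
        for _, row in frame.iterrows()
    ]


def write_curves_csv(curves: list[OGTTCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves_csv(path) -> list[OGTTCurve]:
    return frame_to_curves(pd.read_csv(path, dtype={"participant_id": str}))
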