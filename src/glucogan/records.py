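"""Core data containers: per-patient time series on a uniform 5-minute grid.

A :class:`PatientRecord` holds the four aligned signals a T1D data pipeline
works with — CGM blood glucose, basal insulin rate, insulin boluses and meal
carbohydrates — plus a per-event meal label used to pick the carbohydrate
absorption kernel for that meal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical sampling period of CGM-style records, minutes
SAMPLING_PERIOD_MIN = 5

#: samples per day at the 5-minute grid
SAMPLES_PER_DAY = 24 * 60 // SAMPLING_PERIOD_MIN

MEAL_CLASSES = ("breakfast", "lunch", "dinner", "snack")

#: CGM device reporting range, mg/dL
BG_CLAMP = (20.0, 600.0)


@dataclass
class PatientRecord:
    """Aligned 5-minute series of BG, basal, boluses and meals for one patient.

    Parameters
    ----------
    patient_id : str
        Identifier, unique within a cohort.
    bg : ndarray of float
        CGM blood glucose, mg/dL, strictly positive.
    basal : ndarray of float
        Basal insulin rate, U/h.
    boluses : ndarray of float
        Bolus insulin, U delivered at each grid point (sparse, >= 0).
    meals : ndarray of float
        Meal carbohydrates, g announced at each grid point (sparse, >= 0).
    meal_labels : ndarray of object
        Meal class (one of ``MEAL_CLASSES``) where ``meals > 0``, '' elsewhere.
    start : pd.Timestamp
        Timestamp of the first sample.
    """

    patient_id: str
    bg: np.ndarray
    basal: np.ndarray
    boluses: np.ndarray
    meals: np.ndarray
    meal_labels: np.ndarray = None
    start: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2024-01-01"))
    sampling_period: int = SAMPLING_PERIOD_MIN

    def __post_init__(self) -> None:
        self.bg = np.asarray(self.bg, dtype=float)
        self.basal = np.asarray(self.basal, dtype=float)
        self.boluses = np.asarray(self.boluses, dtype=float)
        self.meals = np.asarray(self.meals, dtype=float)
        if self.meal_labels is None:
            self.meal_labels = np.array([""] * len(self.bg), dtype=object)
        else:
            self.meal_labels = np.asarray(self.meal_labels, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.bg)
        for name in ("basal", "boluses", "meals", "meal_labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"series length mismatch: {name} has {len(getattr(self, name))}, bg has {n}"
                )
        if n == 0:
            raise ValueError("empty record")
        if not np.all(self.bg > 0):
            raise ValueError("bg must be strictly positive everywhere")
        if np.any(self.boluses < 0):
            raise ValueError("boluses must be non-negative")
        if np.any(self.meals < 0):
            raise ValueError("meals must be non-negative")
        bad = (self.meals > 0) & ~np.isin(self.meal_labels.astype(str), MEAL_CLASSES)
        if np.any(bad):
            idx = int(np.nonzero(bad)[0][0])
            raise ValueError(f"meal at index {idx} has no valid meal_label")

    def __len__(self) -> int:
        return len(self.bg)

    @property
    def index(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=len(self), freq=f"{self.sampling_period}min"
        )

    def to_frame(self) -> pd.DataFrame:
        """Return the record as a DataFrame in the canonical CSV dialect."""
        return pd.DataFrame(
            {
                "timestamp": self.index,
                "bg_mgdl": self.bg,
                "basal_Uh": self.basal,
                "bolus_U": self.boluses,
                "meal_g": self.meals,
                "meal_label": self.meal_labels.astype(str),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, patient_id: str) -> "PatientRecord":
        required = {"timestamp", "bg_mgdl", "basal_Uh", "bolus_U", "meal_g", "meal_label"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        ts = pd.to_datetime(frame["timestamp"])
        if len(ts) > 1:
            deltas = ts.diff().dropna().dt.total_seconds().to_numpy() / 60.0
            off = np.nonzero(deltas != SAMPLING_PERIOD_MIN)[0]
            if off.size:
                i = int(off[0])
                raise ValueError(
                    f"non-uniform 5-min grid: gap after {ts.iloc[i].isoformat()}"
                )
        labels = frame["meal_label"].fillna("").astype(str).to_numpy(dtype=object)
        labels[labels == "nan"] = ""
        return cls(
            patient_id=patient_id,
            bg=frame["bg_mgdl"].to_numpy(float),
            basal=frame["basal_Uh"].to_numpy(float),
            boluses=frame["bolus_U"].to_numpy(float),
            meals=frame["meal_g"].to_numpy(float),
            meal_labels=labels,
            start=ts.iloc[0],
        )

    def meal_events(self):
        """Yield (grid_index, grams, label) for every meal in the record."""
        for i in np.nonzero(self.meals > 0)[0]:
            yield int(i), float(self.meals[i]), str(self.meal_labels[i])
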