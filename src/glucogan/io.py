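"""File-format plumbing: patient-record CSV and Ohio-T1DM-style XML ingress."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .records import MEAL_CLASSES, SAMPLING_PERIOD_MIN, PatientRecord

OHIO_TS_FORMAT = "%d-%m-%Y %H:%M:%S"


def write_patient_csv(record: PatientRecord, path) -> None:
    """Write a record in the canonical CSV dialect (ISO-8601 timestamps)."""
    frame = record.to_frame()
    frame["timestamp"] = frame["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    frame.to_csv(path, index=False, float_format="%.17g")  # lossless floats


def read_patient_csv(path, patient_id: str | None = None) -> PatientRecord:
    """Read a canonical patient CSV, validating the uniform 5-minute grid."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    return PatientRecord.from_frame(
        frame, patient_id=patient_id or path.stem
    )


def _parse_ts(text: str) -> pd.Timestamp:
    return pd.to_datetime(text, format=OHIO_TS_FORMAT)


def read_ohio_xml(path, max_cgm_gap_min: float = 15.0) -> list[PatientRecord]:
    """Read an Ohio-T1DM-style per-patient XML onto the 5-minute grid.

    CGM samples are linearly interpolated across gaps of at most
    ``max_cgm_gap_min``; longer gaps split the record into separate segments.
    Basal rates are forward-filled, boluses and meals snapped to the nearest
    grid point (doses preserved).

    Returns one :class:`PatientRecord` per contiguous CGM segment.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()
    patient_id = root.get("id", Path(path).stem)

    cgm = [
        (_parse_ts(e.get("ts")), float(e.get("value")))
        for e in root.findall(".//glucose_level/event")
    ]
    if not cgm:
        raise ValueError(f"{path}: empty glucose record")
    cgm.sort()
    basal = sorted(
        (_parse_ts(e.get("ts")), float(e.get("value")))
        for e in root.findall(".//basal/event")
    )
    boluses = sorted(
        (_parse_ts(e.get("ts_begin") or e.get("ts")), float(e.get("dose")))
        for e in root.findall(".//bolus/event")
    )
    meals = sorted(
        (_parse_ts(e.get("ts")), float(e.get("carbs")), e.get("type", "snack").lower())
        for e in root.findall(".//meal/event")
    )

    # split CGM into segments at gaps > max_cgm_gap_min
    times = pd.DatetimeIndex([t for t, _ in cgm])
    values = np.array([v for _, v in cgm])
    gap_min = np.diff(times.view("int64")) / 60e9
    breaks = np.nonzero(gap_min > max_cgm_gap_min)[0]
    bounds = np.concatenate([[0], breaks + 1, [len(cgm)]])

    records = []
    for seg, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg_t, seg_v = times[a:b], values[a:b]
        start = seg_t[0].ceil(f"{SAMPLING_PERIOD_MIN}min")
        stop = seg_t[-1].floor(f"{SAMPLING_PERIOD_MIN}min")
        if stop < start:
            continue
        grid = pd.date_range(start, stop, freq=f"{SAMPLING_PERIOD_MIN}min")
        n = len(grid)
        bg = np.interp(
            grid.view("int64"), seg_t.view("int64"), seg_v
        )

        basal_series = np.zeros(n)
        if basal:
            b_t = pd.DatetimeIndex([t for t, _ in basal]).view("int64")
            b_v = np.array([v for _, v in basal])
            pos = np.searchsorted(b_t, grid.view("int64"), side="right") - 1
            basal_series = np.where(pos >= 0, b_v[np.clip(pos, 0, None)], 0.0)

        bolus_series = np.zeros(n)
        for t, dose in boluses:
            if grid[0] <= t <= grid[-1]:
                idx = int(np.argmin(np.abs(grid.view("int64") - t.value)))
                bolus_series[idx] += dose

        meal_series = np.zeros(n)
        label_series = np.array([""] * n, dtype=object)
        for t, carbs, label in meals:
            if grid[0] <= t <= grid[-1]:
                idx = int(np.argmin(np.abs(grid.view("int64") - t.value)))
                meal_series[idx] += carbs
                # unrecognised meal types (e.g. hypo corrections) absorb fast
                label_series[idx] = label if label in MEAL_CLASSES else "snack"

        records.append(
            PatientRecord(
                patient_id=f"{patient_id}-seg{seg}" if len(bounds) > 2 else patient_id,
                bg=np.clip(bg, 20.0, 600.0),
                basal=basal_series,
                boluses=bolus_series,
                meals=meal_series,
                meal_labels=label_series,
                start=grid[0],
            )
        )
    if not records:
        raise ValueError(f"{path}: no CGM segment covers a full 5-min grid point")
    return records
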