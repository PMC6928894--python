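"""Trace-selection and sample-exclusion rules for a multi-sensor study.

A 10-day wear study yields, per sensor, a CGM trace and sparse reference
samples collected in three 12-h clinical sessions. Before
identification: saturated CGM readings (at the receiver display limits
40/400 mg/dL) are removed, and whole sensor records are excluded when
they carry too little data, when the final clinical session did not take
place on the last nominal wear day, or when too few reference samples
were collected on that day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .error_model import CGM_DISPLAY_RANGE, GlucoseTrace
from .smoothing import ReferenceSamples

__all__ = [
    "SensorRecord",
    "remove_saturated",
    "select_traces",
    "flag_reference_outliers",
]

MINUTES_PER_DAY = 1440.0


@dataclass
class SensorRecord:
    """One sensor's raw study data: CGM trace, reference samples and the
    nominal day of each clinical session (shared insertion-time origin)."""

    sensor_id: str
    cgm: GlucoseTrace
    reference: ReferenceSamples
    session_days: tuple[int, ...]

    def __post_init__(self) -> None:
        self.session_days = tuple(int(d) for d in self.session_days)
        if list(self.session_days) != sorted(self.session_days):
            raise ValueError("session_days must be sorted")


def remove_saturated(cgm: GlucoseTrace) -> GlucoseTrace:
    """Drop CGM samples saturated at the display limits (<= 40 or
    >= 400 mg/dL) and recompute segment ids so that runs broken by the
    removal are split."""
    lo, hi = CGM_DISPLAY_RANGE
    keep = (cgm.values > lo) & (cgm.values < hi)
    if not np.any(keep):
        if len(cgm):
            warnings.warn("all CGM samples saturated; empty trace", stacklevel=2)
        return GlucoseTrace(np.empty(0), np.empty(0), np.empty(0, int))
    idx = np.flatnonzero(keep)
    new_seg = np.zeros(idx.size, dtype=int)
    if idx.size > 1:
        broken = (np.diff(idx) > 1) | (np.diff(cgm.segment_ids[idx]) != 0)
        new_seg[1:] = broken.astype(int)
    return GlucoseTrace(
        cgm.times[idx].copy(), cgm.values[idx].copy(), np.cumsum(new_seg)
    )


def _day_window(day: int) -> tuple[float, float]:
    # nominal day d covers [ (d-1)*1440, d*1440 ) minutes from insertion
    return (day - 1) * MINUTES_PER_DAY, day * MINUTES_PER_DAY


def select_traces(
    records,
    min_duration_h: float = 12.0,
    required_last_day: int = 10,
    min_last_day_refs: int = 8,
) -> tuple[list[SensorRecord], list[tuple[SensorRecord, str]]]:
    """Partition records into (retained, excluded-with-reason).

    A record is retained when (i) its CGM trace spans at least
    ``min_duration_h`` hours, (ii) its final clinical session is on day
    ``required_last_day``, and (iii) at least ``min_last_day_refs``
    reference samples fall within that day. The three rules are pure
    filters, so the partition is order-independent.
    """
    retained: list[SensorRecord] = []
    excluded: list[tuple[SensorRecord, str]] = []
    for rec in records:
        span_h = (
            (rec.cgm.times[-1] - rec.cgm.times[0]) / 60.0 if len(rec.cgm) > 1 else 0.0
        )
        if span_h < min_duration_h:
            excluded.append((rec, "insufficient data"))
            continue
        if not rec.session_days or rec.session_days[-1] != required_last_day:
            excluded.append((rec, f"last session not day {required_last_day}"))
            continue
        lo, hi = _day_window(required_last_day)
        n_refs = int(np.sum((rec.reference.times >= lo) & (rec.reference.times < hi)))
        if n_refs < min_last_day_refs:
            excluded.append(
                (rec, f"fewer than {min_last_day_refs} reference samples "
                      f"in day {required_last_day}")
            )
            continue
        retained.append(rec)
    return retained, excluded


def flag_reference_outliers(samples: ReferenceSamples, k: float = 4.0) -> np.ndarray:
    """Synthetic stand-in for manual visual inspection of reference
    samples: flag sample i when it deviates more than ``k * cv * value``
    from the mean of its two neighbours. Not part of the published
    preprocessing procedure; OFF by default in every pipeline.
    """
    y = samples.values
    flags = np.zeros(y.size, dtype=bool)
    if y.size < 3:
        return flags
    mid = 0.5 * (y[:-2] + y[2:])
    flags[1:-1] = np.abs(y[1:-1] - mid) > k * samples.cv * y[1:-1]
    return flags
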