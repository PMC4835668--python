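"""Active-day classification and duration of step-counter use.

A day is *active* when its recorded total reaches the wear cutoff
(default >= 100 steps/day; fewer steps indicate the device was moved around
but not worn). Use is considered terminated after the *final day*: the last
day of the last run of at least ``min_consecutive_active`` (default 4)
consecutive active days, regardless of temporary breaks in use between runs.
A patient with no such qualifying run terminated without ever qualifying.

Duration of use (*total days*) runs from the starting day (first active day)
to the final day, inclusive; *active days* counts the active days inside
that span.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .types import AdherenceSummary, DailyStepSeries

__all__ = [
    "classify_active_days",
    "find_final_day",
    "summarize_adherence",
    "is_nonuser_at",
]


def classify_active_days(
    series: DailyStepSeries, config: AnalysisConfig
) -> np.ndarray:
    """Boolean mask over study days: day d is active iff steps >= cutoff."""
    return series.steps >= config.active_day_cutoff


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based inclusive (start_day, end_day) pairs."""
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_final_day(
    active_mask: np.ndarray, config: AnalysisConfig
) -> Optional[int]:
    """Last day of the last qualifying run of consecutive active days.

    A qualifying run has length >= ``config.min_consecutive_active``. Runs are
    calendar-consecutive: any inactive (or unrecorded) day breaks a run.
    Returns None when no qualifying run exists.
    """
    best = None
    for start, end in _runs(np.asarray(active_mask, dtype=bool)):
        if end - start + 1 >= config.min_consecutive_active:
            best = end
    return best


def summarize_adherence(
    series: DailyStepSeries, config: AnalysisConfig
) -> AdherenceSummary:
    """Adherence summary: start/final day, total and active days, active ratio.

    The starting day is the first active day (not study day 1: day 1 may
    precede device setup). Patients with no qualifying run keep an explicit
    zero-duration summary rather than being dropped, so cohort denominators
    stay explicit.
    """
    active = classify_active_days(series, config)
    active_days_all = np.flatnonzero(active) + 1
    start_day = int(active_days_all[0]) if len(active_days_all) else None
    final_day = find_final_day(active, config)

    if final_day is None or start_day is None:
        return AdherenceSummary(
            patient_id=series.patient_id,
            start_day=start_day,
            final_day=None,
            total_days=0,
            active_days=0,
            active_ratio=0.0,
            terminated_without_qualifying_run=True,
        )

    total_days = final_day - start_day + 1
    active_days = int(active[start_day - 1 : final_day].sum())
    return AdherenceSummary(
        patient_id=series.patient_id,
        start_day=start_day,
        final_day=final_day,
        total_days=total_days,
        active_days=active_days,
        active_ratio=active_days / total_days,
        terminated_without_qualifying_run=False,
    )


def is_nonuser_at(
    series: DailyStepSeries, config: AnalysisConfig, checkpoint_day: int
) -> bool:
    """True iff the patient has stopped using the device by ``checkpoint_day``.

    Patients who stopped are "nonusers" from the time they stopped: a patient
    is a nonuser at a checkpoint when their final day precedes it (or they
    never had a qualifying run).
    """
    if not 1 <= checkpoint_day <= config.horizon:
        raise ValueError(f"checkpoint {checkpoint_day} outside [1, {config.horizon}]")
    final_day = find_final_day(classify_active_days(series, config), config)
    return final_day is None or final_day < checkpoint_day
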