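"""Per-patient walking-activity metrics.

The *grand mean* is a patient's mean daily steps over their active days only
(inactive and unrecorded days are non-wear, not zeros of true activity).
Grand means are classified on the graduated step index: low activity below
3000 steps/day, medium 3000-9999, high at or above 10,000.

Weekly means are evaluated at fixed checkpoints (day 7 and months 1, 3, 6, 9,
12) over the 7 days ending at the checkpoint, again over active days only.
Patients who stopped using the device before a checkpoint are *nonusers*
there; their last defined weekly mean is carried forward (LOCF) so that
later checkpoint summaries are not inflated by the dropout of low-activity
patients.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .adherence import classify_active_days, find_final_day
from .config import AnalysisConfig
from .types import ActivityProfile, CheckpointEstimate, DailyStepSeries, PatientProfile

__all__ = [
    "NoActiveDaysError",
    "grand_mean",
    "classify_activity_level",
    "checkpoint_week_mean",
    "checkpoint_profile",
    "build_activity_profile",
    "bmi_change_summary",
    "format_percent",
]


class NoActiveDaysError(ValueError):
    """Raised when a metric requiring at least one active day has none."""


def grand_mean(series: DailyStepSeries, active_mask: np.ndarray) -> tuple[float, float]:
    """Mean and sample SD of daily steps over active days.

    Raises :class:`NoActiveDaysError` when the mask selects no day (the grand
    mean is undefined, never silently zero). The SD is the sample standard
    deviation (ddof=1); it is 0.0 for a single active day.
    """
    values = series.steps[np.asarray(active_mask, dtype=bool)]
    if len(values) == 0:
        raise NoActiveDaysError(f"{series.patient_id}: no active days")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def classify_activity_level(value: float, config: AnalysisConfig) -> str:
    """Graduated step index: low < low_threshold <= medium < high_threshold <= high."""
    if value < config.low_threshold:
        return "low"
    if value >= config.high_threshold:
        return "high"
    return "medium"


def checkpoint_week_mean(
    series: DailyStepSeries,
    active_mask: np.ndarray,
    checkpoint_day: int,
    config: AnalysisConfig,
) -> Optional[float]:
    """Mean steps over active days in the window ending at ``checkpoint_day``.

    The window is the ``config.window_days`` days ending at (and including)
    the checkpoint. Returns None when the window contains no active day.
    """
    if checkpoint_day < config.window_days:
        raise ValueError(
            f"checkpoint {checkpoint_day} precedes day {config.window_days}"
        )
    if checkpoint_day > series.horizon:
        raise ValueError(f"checkpoint {checkpoint_day} beyond horizon {series.horizon}")
    lo, hi = checkpoint_day - config.window_days, checkpoint_day
    mask = np.asarray(active_mask, dtype=bool)[lo:hi]
    window = series.steps[lo:hi][mask]
    if len(window) == 0:
        return None
    return float(window.mean())


def checkpoint_profile(
    series: DailyStepSeries, config: AnalysisConfig
) -> dict[int, CheckpointEstimate]:
    """Checkpoint weekly means with user/nonuser status and LOCF carry-forward.

    At checkpoints up to the patient's final day the window mean is reported
    with status ``user``. At later checkpoints (the patient is a nonuser)
    the last defined weekly mean is carried forward with status
    ``nonuser_locf``; when no weekly mean was ever defined the checkpoint is
    ``undefined``.
    """
    active = classify_active_days(series, config)
    final_day = find_final_day(active, config)
    out: dict[int, CheckpointEstimate] = {}
    last_defined: Optional[float] = None
    for cp in config.checkpoints:
        is_user = final_day is not None and final_day >= cp
        if is_user:
            value = checkpoint_week_mean(series, active, cp, config)
            if value is None:
                out[cp] = CheckpointEstimate(None, "undefined")
            else:
                out[cp] = CheckpointEstimate(value, "user")
                last_defined = value
        else:
            if last_defined is None:
                out[cp] = CheckpointEstimate(None, "undefined")
            else:
                out[cp] = CheckpointEstimate(last_defined, "nonuser_locf")
    return out


def build_activity_profile(
    series: DailyStepSeries, config: AnalysisConfig
) -> ActivityProfile:
    """Grand mean, activity level and checkpoint means for one patient."""
    active = classify_active_days(series, config)
    try:
        mean, sd = grand_mean(series, active)
        level = classify_activity_level(mean, config)
    except NoActiveDaysError:
        mean = sd = level = None  # type: ignore[assignment]
    return ActivityProfile(
        patient_id=series.patient_id,
        grand_mean=mean,
        grand_sd=sd,
        activity_level=level,
        checkpoint_means=checkpoint_profile(series, config),
    )


def bmi_change_summary(profile: PatientProfile) -> Optional[float]:
    """Patient's mean BMI over baseline and 3 months: (baseline + 3mo) / 2.

    Returns None when the 3-month BMI is missing (the patient is flagged by
    callers rather than imputed).
    """
    if profile.bmi_3mo is None:
        return None
    return (profile.bmi_baseline + profile.bmi_3mo) / 2.0


def format_percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half away from zero.

    Reproduces the reporting convention of cohort tables, e.g. 139 of 160
    days -> 87(%). Requires 0 <= numerator <= denominator, denominator > 0.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))
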