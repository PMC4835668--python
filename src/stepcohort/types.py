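"""Shared domain types: patients, daily step series, adherence and activity summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

__all__ = [
    "DIAGNOSES",
    "SETTINGS",
    "SEXES",
    "PatientProfile",
    "DailyStepSeries",
    "AdherenceSummary",
    "CheckpointEstimate",
    "ActivityProfile",
]

SEXES = ("male", "female")
DIAGNOSES = ("ACS", "surgery", "heart_failure", "ACS_and_HF")
SETTINGS = ("health_care_center", "hospital", "call_center")


@dataclass(frozen=True)
class PatientProfile:
    """Baseline metadata for one patient.

    ``diagnosis`` is the primary diagnosis or treatment group (acute coronary
    syndrome; surgery = CABG or valve replacement/repair; heart failure; or
    both ACS and heart failure). ``setting`` is the chosen telerehabilitation
    setting. ``bmi_3mo`` may be missing (patient not re-measured at 3 months).
    """

    patient_id: str
    age: float
    sex: str
    bmi_baseline: float
    bmi_3mo: Optional[float]
    diagnosis: str
    setting: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"{self.patient_id}: age must be positive")
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: sex must be one of {SEXES}")
        if self.bmi_baseline <= 0:
            raise ValueError(f"{self.patient_id}: bmi_baseline must be positive")
        if self.bmi_3mo is not None and self.bmi_3mo <= 0:
            raise ValueError(f"{self.patient_id}: bmi_3mo must be positive when present")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"{self.patient_id}: diagnosis must be one of {DIAGNOSES}")
        if self.setting not in SETTINGS:
            raise ValueError(f"{self.patient_id}: setting must be one of {SETTINGS}")


class DailyStepSeries:
    """Study-day-indexed daily step totals for one patient.

    Day 1 is the first monitoring day (day of inclusion). ``steps`` holds one
    non-negative total per study day up to the horizon; ``recorded`` marks
    days on which the device synced at least one record. Unrecorded days
    carry zero steps: the analysis cannot distinguish "no sync" from
    "0 steps", and both fall below the active-day cutoff downstream.
    """

    __slots__ = ("patient_id", "steps", "recorded")

    def __init__(self, patient_id: str, steps, recorded=None) -> None:
        steps = np.asarray(steps, dtype=np.int64)
        if steps.ndim != 1:
            raise ValueError("steps must be one-dimensional")
        if (steps < 0).any():
            raise ValueError(f"{patient_id}: negative step totals")
        if recorded is None:
            recorded = steps > 0
        recorded = np.asarray(recorded, dtype=bool)
        if recorded.shape != steps.shape:
            raise ValueError("recorded mask must match steps length")
        if (steps[~recorded] != 0).any():
            raise ValueError(f"{patient_id}: unrecorded days must carry zero steps")
        self.patient_id = patient_id
        self.steps = steps
        self.recorded = recorded

    @property
    def horizon(self) -> int:
        return len(self.steps)

    def day(self, d: int) -> int:
        """Steps on 1-based study day ``d``."""
        if not 1 <= d <= self.horizon:
            raise IndexError(f"study day {d} outside [1, {self.horizon}]")
        return int(self.steps[d - 1])

    def __len__(self) -> int:
        return self.horizon

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DailyStepSeries)
            and self.patient_id == other.patient_id
            and np.array_equal(self.steps, other.steps)
            and np.array_equal(self.recorded, other.recorded)
        )

    def __repr__(self) -> str:
        return (
            f"DailyStepSeries({self.patient_id!r}, horizon={self.horizon}, "
            f"recorded_days={int(self.recorded.sum())})"
        )


@dataclass(frozen=True)
class AdherenceSummary:
    """Duration-of-use summary for one patient.

    ``start_day`` is the first active day; ``final_day`` the last day of the
    last qualifying run (None when no qualifying run exists, in which case
    ``terminated_without_qualifying_run`` is set and the day counts are zero).
    ``total_days`` runs from start to final day inclusive regardless of
    intermittent non-wear; ``active_days`` counts active days inside that span.
    """

    patient_id: str
    start_day: Optional[int]
    final_day: Optional[int]
    total_days: int
    active_days: int
    active_ratio: float
    terminated_without_qualifying_run: bool

    def __post_init__(self) -> None:
        if self.active_days > self.total_days:
            raise ValueError("active_days cannot exceed total_days")
        if self.final_day is not None and self.start_day is not None:
            if self.total_days != self.final_day - self.start_day + 1:
                raise ValueError("total_days must equal final_day - start_day + 1")


@dataclass(frozen=True)
class CheckpointEstimate:
    """Weekly-mean estimate at one checkpoint.

    ``status`` is ``"user"`` (patient still using the device; value is the
    window mean), ``"nonuser_locf"`` (patient terminated earlier; value is
    their last defined weekly mean, carried forward), or ``"undefined"``
    (no value exists).
    """

    value: Optional[float]
    status: str

    def __post_init__(self) -> None:
        if self.status not in ("user", "nonuser_locf", "undefined"):
            raise ValueError(f"bad checkpoint status {self.status!r}")
        if (self.value is None) != (self.status == "undefined"):
            raise ValueError("value must be present iff status is not 'undefined'")


@dataclass(frozen=True)
class ActivityProfile:
    """Per-patient walking-activity summary.

    ``grand_mean``/``grand_sd`` are the mean and sample SD of steps over the
    patient's active days only (None when the patient has no active day);
    ``activity_level`` classifies the grand mean on the graduated step index.
    """

    patient_id: str
    grand_mean: Optional[float]
    grand_sd: Optional[float]
    activity_level: Optional[str]
    checkpoint_means: Mapping[int, CheckpointEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.activity_level not in (None, "low", "medium", "high"):
            raise ValueError(f"bad activity level {self.activity_level!r}")
        if (self.grand_mean is None) != (self.activity_level is None):
            raise ValueError("activity_level must be present iff grand_mean is")
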