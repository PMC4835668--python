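"""Reading and writing step records and patient tables.

Three plain-CSV interfaces (UTF-8, header row required):

* ``minute_steps.csv`` — ``patient_id,timestamp,steps`` with ISO-8601
  minute-resolution timestamps, one row per synced minute;
* ``daily_steps.csv`` — ``patient_id,study_day,steps`` with 1-based study
  days; days not listed are unrecorded (zero steps);
* ``patients.csv`` — one row per patient with the baseline profile fields
  plus ``inclusion_date``.

The device rolls its daily total over at midnight local time, so minute
records are bucketed by the timestamp's calendar date with no time-zone
arithmetic.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import DailyStepSeries, PatientProfile

__all__ = [
    "read_minute_records",
    "aggregate_daily",
    "read_daily_series",
    "write_daily_series",
    "read_patients",
    "write_patients",
]

logger = logging.getLogger(__name__)

MINUTE_COLUMNS = ["patient_id", "timestamp", "steps"]
DAILY_COLUMNS = ["patient_id", "study_day", "steps"]
PATIENT_COLUMNS = [
    "patient_id", "age", "sex", "bmi_baseline", "bmi_3mo",
    "diagnosis", "setting", "inclusion_date",
]


def read_minute_records(path: str | Path) -> pd.DataFrame:
    """Read minute-level step records.

    Returns a DataFrame with columns ``patient_id`` (str), ``timestamp``
    (datetime64, minute resolution) and ``steps`` (int). Duplicate
    (patient_id, timestamp) pairs, negative step counts and malformed
    timestamps are errors.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(MINUTE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed timestamp: {exc}") from exc
    if df["steps"].isna().any() or not np.issubdtype(df["steps"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric or missing step counts")
    if (df["steps"] < 0).any():
        bad = df.loc[df["steps"] < 0].iloc[0]
        raise ValueError(
            f"{path}: negative steps ({bad['steps']}) for patient "
            f"{bad['patient_id']} at {bad['timestamp']}"
        )
    dup = df.duplicated(subset=["patient_id", "timestamp"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate record for patient {bad['patient_id']} "
            f"at {bad['timestamp']}"
        )
    df["steps"] = df["steps"].astype(np.int64)
    return df[MINUTE_COLUMNS]


def aggregate_daily(
    records: pd.DataFrame,
    inclusion_dates: Mapping[str, dt.date],
    config: AnalysisConfig | None = None,
) -> dict[str, DailyStepSeries]:
    """Aggregate minute records into per-patient daily series.

    Study day ``d`` sums the minute steps on calendar day
    ``inclusion_date + d - 1``. Days with no records are unrecorded zeros.
    A record dated before its patient's inclusion date is an error; records
    beyond the horizon are dropped with a warning. Patients present in
    ``inclusion_dates`` but absent from ``records`` get all-unrecorded series.
    """
    config = config or AnalysisConfig()
    out: dict[str, DailyStepSeries] = {}
    for pid in inclusion_dates:
        out[pid] = DailyStepSeries(
            pid, np.zeros(config.horizon, dtype=np.int64),
            np.zeros(config.horizon, dtype=bool),
        )

    if len(records):
        unknown = set(records["patient_id"]) - set(inclusion_dates)
        if unknown:
            raise ValueError(f"records for patients without inclusion date: {sorted(unknown)}")
        dates = records["timestamp"].dt.normalize()
        incl = records["patient_id"].map(
            {p: pd.Timestamp(d) for p, d in inclusion_dates.items()}
        )
        study_day = (dates - incl).dt.days + 1
        if (study_day < 1).any():
            bad = records.loc[study_day < 1].iloc[0]
            raise ValueError(
                f"record for patient {bad['patient_id']} at {bad['timestamp']} "
                "predates inclusion"
            )
        beyond = study_day > config.horizon
        if beyond.any():
            logger.warning(
                "dropping %d minute records beyond the %d-day horizon",
                int(beyond.sum()), config.horizon,
            )
        kept = records.loc[~beyond].copy()
        kept["study_day"] = study_day[~beyond]
        totals = kept.groupby(["patient_id", "study_day"])["steps"].sum()
        for (pid, day), total in totals.items():
            series = out[pid]
            series.steps[day - 1] = total
            series.recorded[day - 1] = True
    return out


def read_daily_series(
    path: str | Path, config: AnalysisConfig | None = None
) -> dict[str, DailyStepSeries]:
    """Read per-patient daily series from ``daily_steps.csv``.

    Listed days are recorded (including explicit zeros); unlisted days are
    unrecorded zeros. Duplicate (patient, study_day) pairs and study days
    outside [1, horizon] are errors.
    """
    config = config or AnalysisConfig()
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(DAILY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["steps"] < 0).any():
        raise ValueError(f"{path}: negative step totals")
    bad_day = (df["study_day"] < 1) | (df["study_day"] > config.horizon)
    if bad_day.any():
        bad = df.loc[bad_day].iloc[0]
        raise ValueError(
            f"{path}: study_day {bad['study_day']} outside [1, {config.horizon}] "
            f"for patient {bad['patient_id']}"
        )
    dup = df.duplicated(subset=["patient_id", "study_day"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate study_day {bad['study_day']} for patient "
            f"{bad['patient_id']}"
        )
    out: dict[str, DailyStepSeries] = {}
    for pid, group in df.groupby("patient_id", sort=True):
        steps = np.zeros(config.horizon, dtype=np.int64)
        recorded = np.zeros(config.horizon, dtype=bool)
        idx = group["study_day"].to_numpy(dtype=int) - 1
        steps[idx] = group["steps"].to_numpy(dtype=np.int64)
        recorded[idx] = True
        out[str(pid)] = DailyStepSeries(str(pid), steps, recorded)
    return out


def write_daily_series(
    series: Mapping[str, DailyStepSeries], path: str | Path
) -> None:
    """Write ``daily_steps.csv``; only recorded days are listed, so a
    read-back reproduces both steps and the recorded mask exactly."""
    rows = []
    for pid in sorted(series):
        s = series[pid]
        for day in np.flatnonzero(s.recorded):
            rows.append((pid, int(day) + 1, int(s.steps[day])))
    pd.DataFrame(rows, columns=DAILY_COLUMNS).to_csv(path, index=False)


def read_patients(
    path: str | Path,
) -> tuple[dict[str, PatientProfile], dict[str, dt.date]]:
    """Read ``patients.csv`` into profiles and inclusion dates."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(PATIENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["patient_id"])
    if dup.any():
        raise ValueError(f"{path}: duplicate patient_id {df.loc[dup, 'patient_id'].iloc[0]}")
    profiles: dict[str, PatientProfile] = {}
    inclusion: dict[str, dt.date] = {}
    for row in df.itertuples(index=False):
        bmi_3mo = None if pd.isna(row.bmi_3mo) else float(row.bmi_3mo)
        profiles[row.patient_id] = PatientProfile(
            patient_id=row.patient_id,
            age=float(row.age),
            sex=str(row.sex),
            bmi_baseline=float(row.bmi_baseline),
            bmi_3mo=bmi_3mo,
            diagnosis=str(row.diagnosis),
            setting=str(row.setting),
        )
        inclusion[row.patient_id] = dt.date.fromisoformat(str(row.inclusion_date))
    return profiles, inclusion


def write_patients(
    profiles: Mapping[str, PatientProfile],
    inclusion_dates: Mapping[str, dt.date],
    path: str | Path,
) -> None:
    rows = []
    for pid in sorted(profiles):
        p = profiles[pid]
        rows.append(
            (
                pid, p.age, p.sex, p.bmi_baseline,
                "" if p.bmi_3mo is None else p.bmi_3mo,
                p.diagnosis, p.setting, inclusion_dates[pid].isoformat(),
            )
        )
    pd.DataFrame(rows, columns=PATIENT_COLUMNS).to_csv(path, index=False)
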