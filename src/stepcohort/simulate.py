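"""Seeded synthetic cohorts emulating a 64-patient telerehabilitation study.

The generator reproduces the statistical structure of the cohort the pipeline
is designed for: three activity strata (low/medium/high on the graduated step
index) with stratum-conditional patient-level step means, ages, BMI and
durations of step-counter use; higher dropout in less active patients
(shorter stratum duration means); intermittent multi-day wear gaps
("holidays"); and near-zero activity after the true termination day.

Because the study's strata are *defined* by the observed grand-mean band,
the stratum step means/SDs it reports are band-conditional. Patient-level
means are therefore drawn from normals truncated to the stratum's own band,
with the location parameter moment-matched so the truncated mean equals the
configured stratum mean exactly; the same matching is applied to durations on
[5, horizon]. Daily totals are gamma-mixed Poisson counts (negative
binomial), keeping counts non-negative without truncation bias.

Each series is constructed so the last qualifying run of consecutive active
days ends exactly on the drawn termination day, and day 1 starts a run,
making the adherence detector's target well-defined for recovery tests.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit

from .config import AnalysisConfig
from .types import DIAGNOSES, SETTINGS, DailyStepSeries, PatientProfile

__all__ = [
    "SimulationParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_minute_records",
    "simulate_termination_panel",
]

logger = logging.getLogger(__name__)

STRATA = ("low", "medium", "high")


@dataclass(frozen=True)
class SimulationParams:
    """Generating conditions for a synthetic cohort.

    Defaults encode the emulated study: n = 64 patients split 14/41/9 across
    low/medium/high activity strata; stratum step means 1996/6016/11439
    steps/day (SD 716/1784/440); stratum ages 70.7/61.1/58.2 years
    (SD 10.7/11.4/8.3); stratum durations of use 109/168/208 days
    (SD 56/103/112); 51/64 male; settings 29/64, 23/64, 12/64 for health care
    center / hospital / call center; diagnoses 33/64, 18/64, 8/64, 5/64 for
    ACS / surgery / heart failure / both.

    ``day_noise_dispersion`` is the gamma-mixing dispersion of daily counts
    (variance = mu + dispersion * mu^2; 0 gives pure Poisson).
    ``gap_prob`` is the per-day probability of starting a wear gap, with
    length drawn uniformly from ``holiday_gap_length_range``.
    ``steps_bmi_corr`` couples baseline BMI to the patient's standardized
    step mean (weak negative by default; purely structural, not calibrated
    to any reported effect). ``stray_active_prob`` is the per-day probability
    of a stray active day after termination (0 by default).
    ``termination_hazard_by_stratum``, when given, replaces the duration draw
    with a constant per-day geometric hazard per stratum.
    """

    n_patients: int = 64
    stratum_probs: tuple[float, float, float] = (14 / 64, 41 / 64, 9 / 64)
    stratum_step_means: tuple[float, float, float] = (1996.0, 6016.0, 11439.0)
    stratum_step_sds: tuple[float, float, float] = (716.0, 1784.0, 440.0)
    stratum_age_means: tuple[float, float, float] = (70.7, 61.1, 58.2)
    stratum_age_sds: tuple[float, float, float] = (10.7, 11.4, 8.3)
    stratum_duration_means: tuple[float, float, float] = (109.0, 168.0, 208.0)
    stratum_duration_sds: tuple[float, float, float] = (56.0, 103.0, 112.0)
    male_prob: float = 51 / 64
    setting_probs: tuple[float, float, float] = (29 / 64, 23 / 64, 12 / 64)
    diagnosis_probs: tuple[float, float, float, float] = (
        33 / 64, 18 / 64, 8 / 64, 5 / 64,
    )
    stratum_bmi_means: tuple[float, float, float] = (29.7, 27.7, 27.0)
    bmi_sd: float = 5.1
    steps_bmi_corr: float = -0.2
    bmi_3mo_missing_prob: float = 0.05
    day_noise_dispersion: float = 0.1
    gap_prob: float = 0.02
    holiday_gap_length_range: tuple[int, int] = (2, 14)
    stray_active_prob: float = 0.0
    termination_hazard_by_stratum: Optional[tuple[float, float, float]] = None
    horizon: int = 365
    active_day_cutoff: int = 100
    min_consecutive_active: int = 4
    inclusion_start: dt.date = dt.date(2012, 12, 1)
    inclusion_span_days: int = 456  # Dec 2012 - Mar 2014 recruitment window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("stratum_probs", "setting_probs", "diagnosis_probs"):
            probs = getattr(self, name)
            if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name} must lie in [0,1] and sum to 1")
        if not 0 <= self.male_prob <= 1:
            raise ValueError("male_prob must lie in [0,1]")
        for name in (
            "stratum_step_means", "stratum_step_sds", "stratum_age_means",
            "stratum_age_sds", "stratum_duration_means", "stratum_duration_sds",
        ):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be positive")
        if self.day_noise_dispersion < 0:
            raise ValueError("day_noise_dispersion must be >= 0")
        if not 0 <= self.gap_prob <= 1:
            raise ValueError("gap_prob must lie in [0,1]")
        lo, hi = self.holiday_gap_length_range
        if not 1 <= lo <= hi:
            raise ValueError("holiday_gap_length_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated profiles, series and the ground truth behind them."""

    profiles: dict[str, PatientProfile]
    series: dict[str, DailyStepSeries]
    inclusion_dates: dict[str, dt.date]
    ground_truth: pd.DataFrame  # patient_id, stratum, true_mean, true_termination_day
    params: SimulationParams


def _matched_truncnorm(
    target_mean: float, sd: float, lo: float, hi: float
) -> sps.rv_continuous:
    """Truncated normal on [lo, hi] whose *truncated* mean equals target_mean.

    Solves for the location of the parent normal; without this, band
    truncation would bias stratum means (by ~120 steps/day for the medium
    band) and parameter-recovery checks would fail by construction.
    """

    def frozen(mu: float):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return sps.truncnorm(a, b, loc=mu, scale=sd)

    if not lo < target_mean < hi:
        raise ValueError(
            f"target mean {target_mean} must lie strictly inside ({lo}, {hi})"
        )

    # the truncated mean is monotone in mu; bracket it over a wide mu range
    mu_lo, mu_hi = lo - 4 * sd, hi + 4 * sd
    m_min, m_max = frozen(mu_lo).mean(), frozen(mu_hi).mean()
    eps = 1e-3 * (m_max - m_min)
    target = float(np.clip(target_mean, m_min + eps, m_max - eps))
    if target != target_mean:
        logger.warning(
            "mean %.2f not achievable for sd %.2f on [%.1f, %.1f]; using %.2f",
            target_mean, sd, lo, hi, target,
        )

    def gap(mu: float) -> float:
        return frozen(mu).mean() - target

    mu = optimize.brentq(gap, mu_lo, mu_hi, xtol=1e-6)
    return frozen(mu)


_STEP_BANDS = {  # graduated step index bands; low band floored at wear cutoff
    "low": (100.0, 3000.0),
    "medium": (3000.0, 10000.0),
    "high": (10000.0, 30000.0),
}


def _draw_gap_days(
    rng: np.random.Generator, params: SimulationParams, first: int, last: int
) -> set[int]:
    """Wear-gap days within [first, last] (1-based, inclusive)."""
    gaps: set[int] = set()
    lo, hi = params.holiday_gap_length_range
    d = first
    while d <= last:
        if rng.random() < params.gap_prob:
            length = int(rng.integers(lo, hi + 1))
            gaps.update(range(d, min(d + length, last + 1)))
            d += length
        else:
            d += 1
    return gaps


def _daily_counts(
    rng: np.random.Generator, mean: float, n: int, dispersion: float
) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion == 0:
        lam = np.full(n, mean)
    else:
        shape = 1.0 / dispersion
        lam = mean * rng.gamma(shape, 1.0 / shape, size=n)
    return rng.poisson(lam).astype(np.int64)


def generate_cohort(params: SimulationParams | None = None) -> SyntheticCohort:
    """Generate a seeded synthetic cohort (deterministic given the seed).

    Each patient receives a stratum, demographics drawn from the stratum
    distributions, a patient-level step mean from the band-truncated stratum
    distribution, a true termination day, and a daily series in which days
    1-4 and the last ``min_consecutive_active`` days before termination are
    guaranteed active, interior days may fall into wear gaps, and days after
    termination are unrecorded zeros (up to ``stray_active_prob``).
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    run = params.min_consecutive_active

    step_dists = {
        s: _matched_truncnorm(
            params.stratum_step_means[i], params.stratum_step_sds[i], *_STEP_BANDS[s]
        )
        for i, s in enumerate(STRATA)
    }
    dur_dists = {}
    dur_lo, dur_hi = 2.0 * run, float(params.horizon)
    margin = 0.02 * (dur_hi - dur_lo)
    for i, s in enumerate(STRATA):
        target = params.stratum_duration_means[i]
        capped = float(np.clip(target, dur_lo + margin, dur_hi - margin))
        if capped != target:
            logger.warning(
                "stratum %s duration mean %.1f capped to %.1f to fit the "
                "%d-day horizon", s, target, capped, params.horizon,
            )
        dur_dists[s] = _matched_truncnorm(
            capped, params.stratum_duration_sds[i], dur_lo, dur_hi
        )

    overall_mean = float(np.dot(params.stratum_probs, params.stratum_step_means))
    overall_sd = max(np.std(params.stratum_step_means), 1.0)

    profiles: dict[str, PatientProfile] = {}
    series: dict[str, DailyStepSeries] = {}
    inclusion: dict[str, dt.date] = {}
    truth_rows = []
    width = len(str(params.n_patients))

    for i in range(params.n_patients):
        pid = f"P{i + 1:0{width}d}"
        stratum_idx = int(rng.choice(3, p=params.stratum_probs))
        stratum = STRATA[stratum_idx]
        true_mean = float(step_dists[stratum].rvs(random_state=rng))

        if params.termination_hazard_by_stratum is not None:
            hazard = params.termination_hazard_by_stratum[stratum_idx]
            term_day = int(min(rng.geometric(hazard) + 2 * run - 1, params.horizon))
        else:
            term_day = int(round(float(dur_dists[stratum].rvs(random_state=rng))))
            term_day = int(np.clip(term_day, 2 * run, params.horizon))

        age = float(np.clip(
            rng.normal(params.stratum_age_means[stratum_idx],
                       params.stratum_age_sds[stratum_idx]),
            30.0, 95.0,
        ))
        sex = "male" if rng.random() < params.male_prob else "female"
        z_steps = (true_mean - overall_mean) / overall_sd
        rho = params.steps_bmi_corr
        z_bmi = rho * z_steps + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal()
        bmi_base = float(np.clip(
            params.stratum_bmi_means[stratum_idx] + params.bmi_sd * z_bmi, 16.0, 55.0
        ))
        if rng.random() < params.bmi_3mo_missing_prob:
            bmi_3mo: Optional[float] = None
        else:
            bmi_3mo = float(np.clip(bmi_base - rng.normal(0.3, 0.8), 15.0, 55.0))
        diagnosis = DIAGNOSES[int(rng.choice(4, p=params.diagnosis_probs))]
        setting = SETTINGS[int(rng.choice(3, p=params.setting_probs))]
        profiles[pid] = PatientProfile(
            patient_id=pid, age=age, sex=sex, bmi_baseline=bmi_base,
            bmi_3mo=bmi_3mo, diagnosis=diagnosis, setting=setting,
        )
        inclusion[pid] = params.inclusion_start + dt.timedelta(
            days=int(rng.integers(0, params.inclusion_span_days))
        )

        steps = np.zeros(params.horizon, dtype=np.int64)
        recorded = np.zeros(params.horizon, dtype=bool)
        # interior gaps only: keep the opening and closing runs intact
        gaps = _draw_gap_days(rng, params, run + 1, term_day - run)
        worn = [d for d in range(1, term_day + 1) if d not in gaps]
        counts = _daily_counts(rng, true_mean, len(worn), params.day_noise_dispersion)
        for d, c in zip(worn, counts):
            forced = d <= run or d > term_day - run
            steps[d - 1] = max(c, params.active_day_cutoff) if forced else c
            recorded[d - 1] = True
        if params.stray_active_prob > 0:
            for d in range(term_day + 1, params.horizon + 1):
                if rng.random() < params.stray_active_prob:
                    steps[d - 1] = int(
                        max(params.active_day_cutoff,
                            _daily_counts(rng, true_mean, 1,
                                          params.day_noise_dispersion)[0])
                    )
                    recorded[d - 1] = True
        series[pid] = DailyStepSeries(pid, steps, recorded)
        truth_rows.append((pid, stratum, true_mean, term_day))

    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "stratum", "true_mean", "true_termination_day"],
    )
    return SyntheticCohort(profiles, series, inclusion, ground_truth, params)


def _diurnal_weights() -> np.ndarray:
    """Minute-of-day activity weights: zero overnight, bimodal waking bump."""
    minutes = np.arange(1440)
    hours = minutes / 60.0
    w = np.exp(-0.5 * ((hours - 10.5) / 2.5) ** 2) + 0.8 * np.exp(
        -0.5 * ((hours - 16.5) / 2.5) ** 2
    )
    w[(hours < 6.5) | (hours >= 22.0)] = 0.0
    return w / w.sum()


def generate_minute_records(
    series: Mapping[str, DailyStepSeries],
    inclusion_dates: Mapping[str, dt.date],
    seed: int = 0,
) -> pd.DataFrame:
    """Distribute daily totals over 1440 minutes with a diurnal profile.

    Per-day minute sums equal the daily total exactly (multinomial split), so
    aggregation round-trips the daily series. Only non-zero minutes are
    emitted, plus one explicit zero record at midnight for recorded days, so
    the recorded-day mask also round-trips.
    """
    rng = np.random.default_rng(seed)
    weights = _diurnal_weights()
    rows: list[tuple[str, dt.datetime, int]] = []
    for pid in sorted(series):
        s = series[pid]
        start = inclusion_dates[pid]
        for day_idx in np.flatnonzero(s.recorded):
            date = start + dt.timedelta(days=int(day_idx))
            midnight = dt.datetime(date.year, date.month, date.day)
            rows.append((pid, midnight, 0))
            total = int(s.steps[day_idx])
            if total == 0:
                continue
            per_minute = rng.multinomial(total, weights)
            for m in np.flatnonzero(per_minute):
                rows.append(
                    (pid, midnight + dt.timedelta(minutes=int(m)), int(per_minute[m]))
                )
    return pd.DataFrame(rows, columns=["patient_id", "timestamp", "steps"])


def simulate_termination_panel(
    n_patients: int,
    slope_per_1000: float,
    seed: int,
    checkpoints: Sequence[int] = (7, 30, 90, 180, 270, 365),
    baseline_logit: float = -1.8,
    mean_steps: float = 6000.0,
    sd_steps: float = 2500.0,
    week_noise_sd: float = 600.0,
) -> pd.DataFrame:
    """Patient x checkpoint panel with a controlled termination hazard.

    Between consecutive checkpoints each still-active patient terminates with
    probability expit(baseline_logit + slope_per_1000 * week_mean/1000);
    termination is absorbing. ``slope_per_1000 = 0`` gives a null in which
    termination is independent of steps. Used for null-recovery and power
    checks of :func:`stepcohort.stats.termination_vs_steps`.
    """
    rng = np.random.default_rng(seed)
    means = np.clip(rng.normal(mean_steps, sd_steps, size=n_patients), 300, None)
    rows = []
    for i in range(n_patients):
        terminated = False
        for cp in checkpoints:
            week_mean = max(50.0, means[i] + rng.normal(0.0, week_noise_sd))
            rows.append((f"S{i + 1:04d}", cp, week_mean, int(terminated)))
            if not terminated:
                p_term = expit(baseline_logit + slope_per_1000 * week_mean / 1000.0)
                terminated = bool(rng.random() < p_term)
    return pd.DataFrame(
        rows, columns=["patient_id", "checkpoint", "week_mean", "terminated"]
    )
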