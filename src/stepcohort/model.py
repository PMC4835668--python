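"""Study-level model object tying the pipeline together.

:class:`StepCountStudy` is built from per-patient daily step series plus
baseline profiles (from CSV files, in-memory containers, or the synthetic
cohort generator). Its :meth:`~StepCountStudy.fit` runs the full analysis —
active-day classification, the termination rule, grand means and graduated
activity levels, checkpoint weekly means with nonuser carry-forward, the
stratified cohort tables and the termination regression — and returns a
:class:`StepCountStudyResults` carrying the estimates, their tables and a
text ``summary()``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import ingest
from .adherence import summarize_adherence
from .config import AnalysisConfig
from .metrics import build_activity_profile
from .simulate import SimulationParams, SyntheticCohort, generate_cohort
from .stats import (
    TableResult,
    TerminationRegression,
    build_table1,
    build_table2,
    termination_panel,
)
from .types import ActivityProfile, AdherenceSummary, DailyStepSeries, PatientProfile

__all__ = ["StepCountStudy", "StepCountStudyResults"]

logger = logging.getLogger(__name__)


class StepCountStudy:
    """Step-counter cohort analysis model.

    Parameters
    ----------
    series : mapping of patient_id -> DailyStepSeries
        Daily step totals per patient, all with the config's horizon.
    profiles : mapping of patient_id -> PatientProfile
        Baseline metadata; must cover exactly the same patients.
    config : AnalysisConfig, optional
        Analysis constants; defaults to the study protocol.
    """

    def __init__(
        self,
        series: Mapping[str, DailyStepSeries],
        profiles: Mapping[str, PatientProfile],
        config: AnalysisConfig | None = None,
    ) -> None:
        self.config = config or AnalysisConfig()
        if not series:
            raise ValueError("empty cohort: no patients")
        if set(series) != set(profiles):
            raise ValueError(
                "patient sets differ between series and profiles: "
                f"{sorted(set(series) ^ set(profiles))}"
            )
        for pid, s in series.items():
            if s.horizon != self.config.horizon:
                raise ValueError(
                    f"{pid}: series horizon {s.horizon} != config horizon "
                    f"{self.config.horizon}"
                )
        self.series = dict(series)
        self.profiles = dict(profiles)

    @classmethod
    def from_csv(
        cls, directory: str | Path, config: AnalysisConfig | None = None
    ) -> "StepCountStudy":
        """Build a study from ``patients.csv`` plus ``daily_steps.csv``
        (preferred) or ``minute_steps.csv`` in ``directory``."""
        config = config or AnalysisConfig()
        directory = Path(directory)
        profiles, inclusion = ingest.read_patients(directory / "patients.csv")
        daily_path = directory / "daily_steps.csv"
        minute_path = directory / "minute_steps.csv"
        if daily_path.exists():
            series = ingest.read_daily_series(daily_path, config)
        elif minute_path.exists():
            records = ingest.read_minute_records(minute_path)
            series = ingest.aggregate_daily(records, inclusion, config)
        else:
            raise FileNotFoundError(
                f"neither daily_steps.csv nor minute_steps.csv found in {directory}"
            )
        # patients with no synced record at all get all-unrecorded series
        for pid in profiles:
            if pid not in series:
                series[pid] = DailyStepSeries(
                    pid,
                    np.zeros(config.horizon, dtype=np.int64),
                    np.zeros(config.horizon, dtype=bool),
                )
        extra = set(series) - set(profiles)
        if extra:
            raise ValueError(f"step records for unknown patients: {sorted(extra)}")
        return cls(series, profiles, config)

    @classmethod
    def from_simulation(
        cls,
        params: SimulationParams | None = None,
        config: AnalysisConfig | None = None,
    ) -> tuple["StepCountStudy", SyntheticCohort]:
        """Generate a synthetic cohort and wrap it as a study.

        Returns the study plus the :class:`SyntheticCohort` (whose
        ``ground_truth`` holds the generating stratum, patient-level mean and
        true termination day for recovery checks).
        """
        params = params or SimulationParams()
        if config is None:
            config = AnalysisConfig(
                active_day_cutoff=params.active_day_cutoff,
                min_consecutive_active=params.min_consecutive_active,
                horizon=params.horizon,
            )
        cohort = generate_cohort(params)
        return cls(cohort.series, cohort.profiles, config), cohort

    def fit(self) -> "StepCountStudyResults":
        """Run the full analysis and return the results object."""
        cfg = self.config
        adherence = {
            pid: summarize_adherence(s, cfg) for pid, s in sorted(self.series.items())
        }
        activity = {
            pid: build_activity_profile(s, cfg)
            for pid, s in sorted(self.series.items())
        }
        n_undef = sum(1 for a in activity.values() if a.grand_mean is None)
        if n_undef:
            logger.info("%d patients have no active day (undefined grand mean)", n_undef)
        table1 = build_table1(self.profiles, activity)
        table2 = build_table2(adherence, activity, self.profiles, cfg)
        panel = termination_panel(adherence, activity, cfg)
        term_raw = table2.stats["tests"]["termination_regression"]
        termination = TerminationRegression(
            slope_per_1000=term_raw["slope_per_1000"],
            se=term_raw["se"],
            pvalue=term_raw["pvalue"],
            n_patients=term_raw["n_patients"],
            n_obs=term_raw["n_obs"],
            flagged=term_raw["flagged"],
            reason=term_raw["reason"],
        )
        return StepCountStudyResults(
            model=self,
            adherence_summaries=adherence,
            activity_profiles=activity,
            table1=table1,
            table2=table2,
            termination_regression=termination,
            termination_panel_=panel,
        )


class StepCountStudyResults:
    """Fitted results of a :class:`StepCountStudy`.

    Attributes
    ----------
    adherence : pandas.DataFrame
        One row per patient: start/final day, total and active days,
        active ratio, termination-without-qualifying-run flag.
    activity : pandas.DataFrame
        One row per patient: grand mean/SD, activity level, and per-checkpoint
        weekly mean and user/nonuser status columns.
    table1, table2 : TableResult
        Formatted stratified cohort tables with machine-readable stats.
    termination_regression : TerminationRegression
        GEE slope (per 1000 steps/day) of termination on weekly means.
    """

    def __init__(
        self,
        model: StepCountStudy,
        adherence_summaries: Mapping[str, AdherenceSummary],
        activity_profiles: Mapping[str, ActivityProfile],
        table1: TableResult,
        table2: TableResult,
        termination_regression: TerminationRegression,
        termination_panel_: pd.DataFrame,
    ) -> None:
        self.model = model
        self.config = model.config
        self.adherence_summaries = dict(adherence_summaries)
        self.activity_profiles = dict(activity_profiles)
        self.table1 = table1
        self.table2 = table2
        self.termination_regression = termination_regression
        self.termination_panel = termination_panel_

    @property
    def n_patients(self) -> int:
        return len(self.adherence_summaries)

    @property
    def adherence(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.adherence_summaries):
            a = self.adherence_summaries[pid]
            rows.append(
                {
                    "patient_id": pid,
                    "start_day": a.start_day,
                    "final_day": a.final_day,
                    "total_days": a.total_days,
                    "active_days": a.active_days,
                    "active_ratio": round(a.active_ratio, 6),
                    "terminated_without_qualifying_run": a.terminated_without_qualifying_run,
                }
            )
        return pd.DataFrame(rows)

    @property
    def activity(self) -> pd.DataFrame:
        rows = []
        for pid in sorted(self.activity_profiles):
            p = self.activity_profiles[pid]
            row: dict[str, object] = {
                "patient_id": pid,
                "grand_mean": None if p.grand_mean is None else round(p.grand_mean, 4),
                "grand_sd": None if p.grand_sd is None else round(p.grand_sd, 4),
                "activity_level": p.activity_level,
            }
            for cp in self.config.checkpoints:
                est = p.checkpoint_means[cp]
                row[f"day{cp}_mean"] = (
                    None if est.value is None else round(est.value, 4)
                )
                row[f"day{cp}_status"] = est.status
            rows.append(row)
        return pd.DataFrame(rows)

    def activity_levels(self) -> dict[str, Optional[str]]:
        return {p: a.activity_level for p, a in self.activity_profiles.items()}

    def summary(self) -> str:
        """Plain-text overview in the style of a statistical results table."""
        s2 = self.table2.stats
        s1 = self.table1.stats
        gm = s2["grand_mean"]["all"]
        td = s2["total_days"]["all"]
        ad = s2["active_days"]["all"]
        term = self.termination_regression
        lines = [
            "Step-counter cohort analysis",
            "=" * 60,
            f"Patients analyzed:            {s1['n_total']}"
            + (
                f"  (+{s1['n_excluded_undefined_level']} with no active day excluded)"
                if s1["n_excluded_undefined_level"]
                else ""
            ),
            f"Activity strata (low/med/high): "
            f"{s2['stratum_n']['low']}/{s2['stratum_n']['medium']}/{s2['stratum_n']['high']}",
            f"Grand mean steps/day:         {gm['mean']:.1f} (SD {gm['sd']:.1f})",
            f"Total days of use:            {td['mean']:.1f} (SD {td['sd']:.1f})",
            f"Active days of use:           {ad['mean']:.1f} (SD {ad['sd']:.1f})",
            "-" * 60,
            "Table 1 (baseline characteristics by activity level):",
            self.table1.table.to_string(),
            "-" * 60,
            "Table 2 (duration of use and mean daily steps):",
            self.table2.table.to_string(),
            "-" * 60,
        ]
        if term.flagged:
            lines.append(
                f"Termination regression: not estimable ({term.reason})"
            )
        else:
            lines.append(
                "Termination vs weekly steps (GEE, exchangeable): "
                f"slope {term.slope_per_1000:.4f} per 1000 steps "
                f"(SE {term.se:.4f}, p={term.pvalue:.4f}, "
                f"{term.n_patients} patients, {term.n_obs} obs)"
            )
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Write all outputs as CSV/JSON into ``directory``.

        Files: adherence.csv, activity_profiles.csv, table1.csv, table2.csv,
        stats.json (full-precision test statistics) and summary.txt. Outputs
        are deterministically ordered and formatted, so re-running on
        unchanged inputs is byte-identical.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.adherence.to_csv(directory / "adherence.csv", index=False)
        self.activity.to_csv(directory / "activity_profiles.csv", index=False)
        self.table1.table.to_csv(directory / "table1.csv", index_label="row")
        self.table2.table.to_csv(directory / "table2.csv", index_label="row")
        stats = {"table1": self.table1.stats, "table2": self.table2.stats}
        (directory / "stats.json").write_text(
            json.dumps(stats, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (directory / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")
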