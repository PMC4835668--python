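"""Cohort-level statistics: group comparisons and summary tables.

Continuous baseline variables are compared across the three activity strata
with one-way ANOVA (post hoc pairwise t-tests, Bonferroni-corrected over the
three stratum pairs, when the omnibus test is significant). Categorical
variables use the Fisher exact test. Non-normally distributed durations
(total and active days) use Kruskal-Wallis with post hoc two-sample Wilcoxon
rank-sum tests. Gender-sorted grand means use a two-sample t-test.

The association between weekly mean steps and termination of step-counter
use is estimated with a repeated-measures (population-averaged) logistic
regression: a binomial GEE with an exchangeable working correlation over
each patient's checkpoints, slope reported per 1000 steps/day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .config import AnalysisConfig
from .metrics import bmi_change_summary, format_percent
from .types import (
    DIAGNOSES,
    SETTINGS,
    ActivityProfile,
    AdherenceSummary,
    PatientProfile,
)

__all__ = [
    "GroupComparison",
    "TerminationRegression",
    "TableResult",
    "compare_continuous_anova",
    "compare_categorical_fisher",
    "compare_nonparametric",
    "compare_gender_ttest",
    "termination_panel",
    "termination_vs_steps",
    "build_table1",
    "build_table2",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
STRATA = ("low", "medium", "high")


@dataclass(frozen=True)
class GroupComparison:
    """Omnibus statistic/p-value plus post hoc pairwise p-values.

    ``pairwise`` is populated only when the omnibus test is significant at
    ``alpha`` (mirroring "in the case of significant difference, a post hoc
    test was carried out"); keys are (group_a, group_b) label pairs.
    """

    statistic: float
    pvalue: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass(frozen=True)
class TerminationRegression:
    """Population-averaged logistic regression of termination on weekly steps."""

    slope_per_1000: Optional[float]
    se: Optional[float]
    pvalue: Optional[float]
    n_patients: int
    n_obs: int
    flagged: bool
    reason: Optional[str] = None


@dataclass(frozen=True)
class TableResult:
    """A formatted cohort table plus its machine-readable statistics."""

    table: pd.DataFrame
    stats: dict


def _split_groups(
    values: Sequence[float], groups: Sequence[str]
) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    labels = list(dict.fromkeys(groups.tolist()))  # first-appearance order
    return {g: values[groups == g] for g in labels}


def compare_continuous_anova(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = ALPHA,
    equal_var: bool = True,
) -> GroupComparison:
    """One-way ANOVA across groups with Bonferroni-corrected pairwise t-tests.

    With exactly two groups the ANOVA reduces to the (equal-variance)
    two-sample t-test via F = t². Each group needs >= 2 observations.
    The Bonferroni factor is the number of pairwise comparisons (3 for three
    strata); corrected p-values are capped at 1.
    """
    by_group = _split_groups(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("every group needs at least 2 observations")
    f, p = sps.f_oneway(*by_group.values())
    pairwise: dict[tuple[str, str], float] = {}
    labels = list(by_group)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    if p < alpha:
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                _, p_ab = sps.ttest_ind(by_group[a], by_group[b], equal_var=equal_var)
                pairwise[(a, b)] = min(1.0, float(p_ab) * n_pairs)
    return GroupComparison(float(f), float(p), pairwise)


def compare_categorical_fisher(
    table: Sequence[Sequence[int]],
    seed: int = 0,
    n_resamples: int = 19999,
) -> float:
    """Two-sided Fisher exact p-value for an r x k contingency table.

    2x2 tables are computed exactly (hypergeometric enumeration); larger
    tables use a Monte-Carlo permutation null with a fresh generator seeded
    by ``seed``, so repeated calls are deterministic.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("contingency table must have at least 2 rows and 2 columns")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("empty table")
    if arr.shape == (2, 2):
        return float(sps.fisher_exact(arr).pvalue)
    method = sps.PermutationMethod(
        n_resamples=n_resamples, rng=np.random.default_rng(seed)
    )
    return float(sps.fisher_exact(arr, method=method).pvalue)


def compare_nonparametric(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = ALPHA,
) -> GroupComparison:
    """Kruskal-Wallis across groups; post hoc two-sample rank-sum tests.

    Pairwise p-values are two-sided Wilcoxon rank-sum (Mann-Whitney) tests,
    exact for small samples without ties, reported uncorrected (matching the
    convention of reporting the three raw stratum-pair p-values).
    """
    by_group = _split_groups(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("every group needs at least 2 observations")
    pooled = np.concatenate(list(by_group.values()))
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence of any difference
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*by_group.values())
    pairwise: dict[tuple[str, str], float] = {}
    labels = list(by_group)
    if p < alpha:
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                _, p_ab = sps.mannwhitneyu(
                    by_group[a], by_group[b], alternative="two-sided", method="auto"
                )
                pairwise[(a, b)] = float(p_ab)
    return GroupComparison(float(h), float(p), pairwise)


def compare_gender_ttest(
    values: Sequence[float],
    sex_labels: Sequence[str],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test of (grand mean) values between sexes.

    Equal-variance by default; pass ``equal_var=False`` for Welch. Requires
    at least 2 patients of each sex.
    """
    by_group = _split_groups(values, sex_labels)
    if set(by_group) != {"male", "female"} or any(
        len(v) < 2 for v in by_group.values()
    ):
        raise ValueError("need both sexes with at least 2 patients each")
    t, p = sps.ttest_ind(by_group["male"], by_group["female"], equal_var=equal_var)
    return float(t), float(p)


def termination_panel(
    adherence: Mapping[str, AdherenceSummary],
    activity: Mapping[str, ActivityProfile],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Long-format patient x checkpoint panel for the termination regression.

    One row per patient per checkpoint with a defined weekly mean (user value
    or LOCF carry-forward) and the binary indicator of having terminated by
    that checkpoint.
    """
    rows = []
    for pid in sorted(adherence):
        summ = adherence[pid]
        prof = activity[pid]
        for cp in config.checkpoints:
            est = prof.checkpoint_means.get(cp)
            if est is None or est.value is None:
                continue
            terminated = summ.final_day is None or summ.final_day < cp
            rows.append((pid, cp, est.value, int(terminated)))
    return pd.DataFrame(
        rows, columns=["patient_id", "checkpoint", "week_mean", "terminated"]
    )


def termination_vs_steps(panel: pd.DataFrame) -> TerminationRegression:
    """GEE logistic regression of termination status on weekly mean steps.

    Population-averaged binomial model with an exchangeable working
    correlation across each patient's checkpoints. The slope is per 1000
    steps/day. Degenerate panels (no terminations, no users, or no variation
    in steps) are flagged with no estimate rather than fitted.
    """
    n_patients = panel["patient_id"].nunique() if len(panel) else 0
    n_obs = len(panel)
    y = panel["terminated"].to_numpy(dtype=float) if n_obs else np.array([])
    if n_obs == 0 or y.min() == y.max():
        reason = "empty panel" if n_obs == 0 else (
            "no terminations observed" if n_obs and y.max() == 0 else "no users observed"
        )
        return TerminationRegression(None, None, None, n_patients, n_obs, True, reason)
    x = panel["week_mean"].to_numpy(dtype=float) / 1000.0
    if np.ptp(x) == 0:
        return TerminationRegression(
            None, None, None, n_patients, n_obs, True, "no variation in weekly means"
        )
    exog = sm.add_constant(x)
    try:
        fit = sm.GEE(
            y,
            exog,
            groups=panel["patient_id"].to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
    except Exception as exc:  # separation / convergence failure
        return TerminationRegression(
            None, None, None, n_patients, n_obs, True, f"fit failed: {exc}"
        )
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(slope) or not np.isfinite(se) or se > 1e4:
        return TerminationRegression(
            slope, se, None, n_patients, n_obs, True, "unstable estimate (separation?)"
        )
    return TerminationRegression(
        slope, se, float(fit.pvalues[1]), n_patients, n_obs, False
    )


# ---------------------------------------------------------------------------
# table builders


def _fmt_mean_sd(values: Sequence[float]) -> str:
    """Paper-style cell: mean (SD) with one decimal; "0 (0)" for empty cells,
    SD 0 for singleton cells."""
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return "0 (0)"
    sd = v.std(ddof=1) if len(v) > 1 else 0.0
    return f"{v.mean():.1f} ({sd:.1f})"


def _fmt_n_pct(n: int, total: int) -> str:
    return f"{n} ({format_percent(n, total) if total else 0})"


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return "n/a"
    return f"{p:.3f}"


def _mean_sd_raw(values: Sequence[float]) -> dict:
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)], dtype=float)
    if len(v) == 0:
        return {"n": 0, "mean": None, "sd": None}
    return {
        "n": int(len(v)),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
    }


def _check_patients(*maps: Mapping[str, object]) -> list[str]:
    keys = [set(m) for m in maps]
    union, inter = set.union(*keys), set.intersection(*keys)
    if union != inter:
        raise ValueError(
            f"patient sets differ across inputs: {sorted(union - inter)}"
        )
    return sorted(inter)


def _try(func, *args, **kwargs):
    """Run a comparison; return None (marked 'n/a' in tables) when degenerate."""
    try:
        return func(*args, **kwargs)
    except ValueError as exc:
        logger.info("comparison skipped: %s", exc)
        return None


def build_table1(
    profiles: Mapping[str, PatientProfile],
    activity: Mapping[str, ActivityProfile],
    fisher_seed: int = 0,
) -> TableResult:
    """Baseline-characteristics table stratified by activity level.

    Rows: participants, age, sex, BMI (patient mean of baseline and 3-month
    values; baseline used, and the patient flagged, when the 3-month value is
    missing), primary diagnosis/treatment, telerehabilitation setting.
    Patients with no active days (undefined activity level) are excluded with
    a logged count.
    """
    pids = _check_patients(profiles, activity)
    classified = [p for p in pids if activity[p].activity_level is not None]
    dropped = len(pids) - len(classified)
    if dropped:
        logger.info("table1: excluded %d patients with undefined activity level", dropped)
    if not classified:
        raise ValueError("empty cohort: no patient with a defined activity level")
    level = {p: activity[p].activity_level for p in classified}
    total = len(classified)
    by_level = {s: [p for p in classified if level[p] == s] for s in STRATA}
    columns = ["all", *STRATA]

    def members(col: str) -> list[str]:
        return classified if col == "all" else by_level[col]

    ages = {p: profiles[p].age for p in classified}
    bmi_flagged = [p for p in classified if bmi_change_summary(profiles[p]) is None]
    bmi = {
        p: (
            bmi_change_summary(profiles[p])
            if bmi_change_summary(profiles[p]) is not None
            else profiles[p].bmi_baseline
        )
        for p in classified
    }

    present = [s for s in STRATA if by_level[s]]
    age_cmp = (
        _try(
            compare_continuous_anova,
            [ages[p] for p in classified],
            [level[p] for p in classified],
        )
        if len(present) > 1
        else None
    )
    bmi_cmp = (
        _try(
            compare_continuous_anova,
            [bmi[p] for p in classified],
            [level[p] for p in classified],
        )
        if len(present) > 1
        else None
    )

    def fisher_by(attr_values: Mapping[str, str], categories: Sequence[str]) -> Optional[float]:
        tab = [
            [sum(1 for p in by_level[s] if attr_values[p] == c) for s in present]
            for c in categories
        ]
        tab = [row for row in tab if sum(row)]
        if len(tab) < 2 or len(present) < 2:
            return None
        return _try(compare_categorical_fisher, tab, fisher_seed)

    sex_p = fisher_by({p: profiles[p].sex for p in classified}, ("male", "female"))
    diag_p = fisher_by({p: profiles[p].diagnosis for p in classified}, DIAGNOSES)
    setting_p = fisher_by({p: profiles[p].setting for p in classified}, SETTINGS)

    rows: dict[str, dict[str, str]] = {}

    def count_row(name: str, pred) -> dict[str, int]:
        counts = {c: sum(1 for p in members(c) if pred(p)) for c in columns}
        rows[name] = {c: _fmt_n_pct(counts[c], total) for c in columns}
        return counts

    counts_raw: dict[str, dict[str, int]] = {}
    counts_raw["participants"] = count_row("participants_n", lambda p: True)
    rows["age_mean_sd"] = {
        c: _fmt_mean_sd([ages[p] for p in members(c)]) for c in columns
    }
    for sex in ("male", "female"):
        counts_raw[f"sex_{sex}"] = count_row(
            f"sex_{sex}_n", lambda p, s=sex: profiles[p].sex == s
        )
    rows["bmi_mean_sd"] = {c: _fmt_mean_sd([bmi[p] for p in members(c)]) for c in columns}
    for d in DIAGNOSES:
        counts_raw[f"diagnosis_{d}"] = count_row(
            f"diagnosis_{d}_n", lambda p, d=d: profiles[p].diagnosis == d
        )
    for s in SETTINGS:
        counts_raw[f"setting_{s}"] = count_row(
            f"setting_{s}_n", lambda p, s=s: profiles[p].setting == s
        )

    table = pd.DataFrame.from_dict(rows, orient="index")[columns]
    p_col = {name: "" for name in table.index}
    p_col["age_mean_sd"] = _fmt_p(age_cmp.pvalue if age_cmp else None)
    p_col["sex_male_n"] = _fmt_p(sex_p)
    p_col["bmi_mean_sd"] = _fmt_p(bmi_cmp.pvalue if bmi_cmp else None)
    p_col["diagnosis_ACS_n"] = _fmt_p(diag_p)
    p_col["setting_health_care_center_n"] = _fmt_p(setting_p)
    table["p"] = pd.Series(p_col)

    stats = {
        "n_total": total,
        "n_excluded_undefined_level": dropped,
        "counts": counts_raw,
        "age": {c: _mean_sd_raw([ages[p] for p in members(c)]) for c in columns},
        "bmi": {c: _mean_sd_raw([bmi[p] for p in members(c)]) for c in columns},
        "n_bmi_3mo_missing": len(bmi_flagged),
        "tests": {
            "age_anova": _comparison_dict(age_cmp),
            "bmi_anova": _comparison_dict(bmi_cmp),
            "sex_fisher_p": sex_p,
            "diagnosis_fisher_p": diag_p,
            "setting_fisher_p": setting_p,
        },
    }
    return TableResult(table, stats)


def _comparison_dict(cmp: Optional[GroupComparison]) -> Optional[dict]:
    if cmp is None:
        return None
    return {
        "statistic": cmp.statistic,
        "pvalue": cmp.pvalue,
        "pairwise": {f"{a}_vs_{b}": p for (a, b), p in cmp.pairwise.items()},
    }


def build_table2(
    adherence: Mapping[str, AdherenceSummary],
    activity: Mapping[str, ActivityProfile],
    profiles: Mapping[str, PatientProfile],
    config: AnalysisConfig,
) -> TableResult:
    """Duration-of-use and mean-daily-steps table stratified by activity level.

    Duration rows (total and active days) are compared across strata with
    Kruskal-Wallis plus post hoc rank-sum tests; the gender row with a t-test
    on grand means; diagnosis and setting step rows with one-way ANOVA on
    grand means across those groupings; and the checkpoint (week) rows carry
    the p-value of the termination-vs-steps repeated-measures logistic
    regression.
    """
    pids = _check_patients(adherence, activity, profiles)
    classified = [p for p in pids if activity[p].activity_level is not None]
    if not classified:
        raise ValueError("empty cohort: no patient with a defined activity level")
    level = {p: activity[p].activity_level for p in classified}
    by_level = {s: [p for p in classified if level[p] == s] for s in STRATA}
    present = [s for s in STRATA if by_level[s]]
    columns = ["all", *STRATA]

    def members(col: str) -> list[str]:
        return classified if col == "all" else by_level[col]

    total_days = {p: adherence[p].total_days for p in classified}
    active_days = {p: adherence[p].active_days for p in classified}
    gmean = {p: activity[p].grand_mean for p in classified}

    multi = len(present) > 1
    td_cmp = (
        _try(
            compare_nonparametric,
            [total_days[p] for p in classified],
            [level[p] for p in classified],
        )
        if multi
        else None
    )
    ad_cmp = (
        _try(
            compare_nonparametric,
            [active_days[p] for p in classified],
            [level[p] for p in classified],
        )
        if multi
        else None
    )
    gender = _try(
        compare_gender_ttest,
        [gmean[p] for p in classified],
        [profiles[p].sex for p in classified],
    )
    diag_cmp = _try(
        compare_continuous_anova,
        [gmean[p] for p in classified],
        [profiles[p].diagnosis for p in classified],
    )
    setting_cmp = _try(
        compare_continuous_anova,
        [gmean[p] for p in classified],
        [profiles[p].setting for p in classified],
    )
    panel = termination_panel(
        {p: adherence[p] for p in classified},
        {p: activity[p] for p in classified},
        config,
    )
    term = termination_vs_steps(panel)

    rows: dict[str, dict[str, str]] = {}
    rows["total_days_mean_sd"] = {
        c: _fmt_mean_sd([total_days[p] for p in members(c)]) for c in columns
    }
    rows["active_days_mean_sd"] = {
        c: _fmt_mean_sd([active_days[p] for p in members(c)]) for c in columns
    }

    def pct_cell(col: str) -> str:
        ps = members(col)
        tot = sum(total_days[p] for p in ps)
        act = sum(active_days[p] for p in ps)
        return str(format_percent(act, tot)) if tot else "n/a"

    rows["active_total_pct"] = {c: pct_cell(c) for c in columns}
    rows["grand_mean_sd"] = {
        c: _fmt_mean_sd([gmean[p] for p in members(c)]) for c in columns
    }
    for sex in ("male", "female"):
        rows[f"gender_{sex}_mean_sd"] = {
            c: _fmt_mean_sd(
                [gmean[p] for p in members(c) if profiles[p].sex == sex]
            )
            for c in columns
        }
    week_raw: dict[str, dict[str, dict]] = {}
    for cp in config.checkpoints:
        values = {
            c: [
                activity[p].checkpoint_means[cp].value
                for p in members(c)
                if activity[p].checkpoint_means[cp].value is not None
            ]
            for c in columns
        }
        rows[f"week_day{cp}_mean_sd"] = {c: _fmt_mean_sd(values[c]) for c in columns}
        week_raw[str(cp)] = {c: _mean_sd_raw(values[c]) for c in columns}
    for d in DIAGNOSES:
        rows[f"diagnosis_{d}_mean_sd"] = {
            c: _fmt_mean_sd(
                [gmean[p] for p in members(c) if profiles[p].diagnosis == d]
            )
            for c in columns
        }
    for s in SETTINGS:
        rows[f"setting_{s}_mean_sd"] = {
            c: _fmt_mean_sd(
                [gmean[p] for p in members(c) if profiles[p].setting == s]
            )
            for c in columns
        }

    table = pd.DataFrame.from_dict(rows, orient="index")[columns]
    p_col = {name: "" for name in table.index}
    p_col["total_days_mean_sd"] = _fmt_p(td_cmp.pvalue if td_cmp else None)
    p_col["active_days_mean_sd"] = _fmt_p(ad_cmp.pvalue if ad_cmp else None)
    p_col["gender_male_mean_sd"] = _fmt_p(gender[1] if gender else None)
    p_col[f"week_day{config.checkpoints[0]}_mean_sd"] = _fmt_p(term.pvalue)
    p_col[f"diagnosis_{DIAGNOSES[0]}_mean_sd"] = _fmt_p(
        diag_cmp.pvalue if diag_cmp else None
    )
    p_col[f"setting_{SETTINGS[0]}_mean_sd"] = _fmt_p(
        setting_cmp.pvalue if setting_cmp else None
    )
    table["p"] = pd.Series(p_col)

    stats = {
        "n_total": len(classified),
        "stratum_n": {s: len(by_level[s]) for s in STRATA},
        "total_days": {
            c: _mean_sd_raw([total_days[p] for p in members(c)]) for c in columns
        },
        "active_days": {
            c: _mean_sd_raw([active_days[p] for p in members(c)]) for c in columns
        },
        "grand_mean": {c: _mean_sd_raw([gmean[p] for p in members(c)]) for c in columns},
        "weeks": week_raw,
        "tests": {
            "total_days_kruskal": _comparison_dict(td_cmp),
            "active_days_kruskal": _comparison_dict(ad_cmp),
            "gender_ttest": (
                {"t": gender[0], "pvalue": gender[1]} if gender else None
            ),
            "diagnosis_anova": _comparison_dict(diag_cmp),
            "setting_anova": _comparison_dict(setting_cmp),
            "termination_regression": {
                "slope_per_1000": term.slope_per_1000,
                "se": term.se,
                "pvalue": term.pvalue,
                "n_patients": term.n_patients,
                "n_obs": term.n_obs,
                "flagged": term.flagged,
                "reason": term.reason,
            },
        },
    }
    return TableResult(table, stats)
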