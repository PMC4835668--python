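import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps

from stepcohort import AnalysisConfig, PatientProfile
from stepcohort.adherence import summarize_adherence
from stepcohort.metrics import build_activity_profile
from stepcohort.simulate import simulate_termination_panel
from stepcohort.stats import (
    build_table1,
    build_table2,
    compare_categorical_fisher,
    compare_continuous_anova,
    compare_gender_ttest,
    compare_nonparametric,
    termination_panel,
    termination_vs_steps,
)

from conftest import make_series


def fisher_2x2_enumeration(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):  # hypergeometric pmf of top-left cell
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def ranksum_two_sided_enumeration(x, y):
    """Exact two-sided rank-sum p over all assignments of the pooled sample."""
    pooled = sorted(x + y)
    nx = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) + 0.5 * sum(
        1 for xi in x for yj in y if xi == yj
    )
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in gx for yj in gy if xi > yj) + 0.5 * sum(
            1 for xi in gx for yj in gy if xi == yj
        )
        us.append(u)
    us = np.array(us)
    lower = np.mean(us <= u_obs + 1e-12)
    upper = np.mean(us >= u_obs - 1e-12)
    return min(1.0, 2 * min(lower, upper))


class TestAnova:
    def test_identical_groups_f_zero(self):
        values = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_continuous_anova(values, groups)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)
        assert res.pairwise == {}

    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 10), rng.normal(2, 1, 12)
        res = compare_continuous_anova(
            np.concatenate([x, y]), ["a"] * 10 + ["b"] * 12
        )
        t, p = sps.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(t**2)
        assert res.pvalue == pytest.approx(p)

    def test_pairwise_bonferroni_when_significant(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(0.2, 1, 10), rng.normal(5, 1, 10)]
        )
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        res = compare_continuous_anova(values, groups)
        assert res.pvalue < 0.05
        assert set(res.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}
        t_ab = sps.ttest_ind(values[:10], values[10:20], equal_var=True).pvalue
        assert res.pairwise[("a", "b")] == pytest.approx(min(1.0, 3 * t_ab))

    def test_degenerate_group_is_error(self):
        with pytest.raises(ValueError):
            compare_continuous_anova([1, 2, 3], ["a", "a", "b"])

    def test_age_strata_rejected_in_majority_of_replicates(self):
        # stratum age structure: 70.7/61.1/58.2 (SD 10.7/11.4/8.3), n 14/41/9
        rejections = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            values = np.concatenate(
                [
                    rng.normal(70.7, 10.7, 14),
                    rng.normal(61.1, 11.4, 41),
                    rng.normal(58.2, 8.3, 9),
                ]
            )
            groups = ["low"] * 14 + ["medium"] * 41 + ["high"] * 9
            if compare_continuous_anova(values, groups).pvalue < 0.05:
                rejections += 1
        assert rejections > n_rep / 2


class TestFisher:
    def test_balanced_table_p_one(self):
        assert compare_categorical_fisher([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        p = compare_categorical_fisher([[10, 0], [0, 10]])
        assert p == pytest.approx(fisher_2x2_enumeration(10, 0, 0, 10))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_tables_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 6, size=4)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        p = compare_categorical_fisher([[a, b], [c, d]])
        assert p == pytest.approx(fisher_2x2_enumeration(a, b, c, d))

    def test_single_column_is_error(self):
        with pytest.raises(ValueError):
            compare_categorical_fisher([[3], [4]])

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            compare_categorical_fisher([[0, 0], [0, 0]])

    def test_rxc_deterministic_given_seed(self):
        table = [[5, 2, 7], [1, 6, 3]]
        p1 = compare_categorical_fisher(table, seed=11)
        p2 = compare_categorical_fisher(table, seed=11)
        assert p1 == p2
        # and close to the large-sample exact value regardless of seed
        assert compare_categorical_fisher(table, seed=99) == pytest.approx(p1, abs=0.02)


class TestNonparametric:
    def test_identical_groups_h_zero(self):
        values = [1, 2, 3] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = compare_nonparametric(values, groups)
        assert res.statistic == pytest.approx(0.0)

    def test_all_constant_values_h_zero(self):
        res = compare_nonparametric([5] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_pairwise_ranksum_matches_exact_enumeration(self):
        x, y = [1, 2, 3], [4, 5, 6]
        res = compare_nonparametric(x + y, ["a"] * 3 + ["b"] * 3, alpha=1.0)
        expected = ranksum_two_sided_enumeration(x, y)
        assert expected == pytest.approx(0.1)
        assert res.pairwise[("a", "b")] == pytest.approx(expected)

    def test_duration_strata_low_vs_high_rejected_in_majority(self):
        # stratum durations 109/168/208 days (SD 56/103/112), n 14/41/9
        rejections = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            values = np.concatenate(
                [
                    np.clip(rng.normal(109, 56, 14), 5, 365),
                    np.clip(rng.normal(168, 103, 41), 5, 365),
                    np.clip(rng.normal(208, 112, 9), 5, 365),
                ]
            )
            groups = ["low"] * 14 + ["medium"] * 41 + ["high"] * 9
            res = compare_nonparametric(values, groups, alpha=1.0)
            if res.pairwise[("low", "high")] < 0.05:
                rejections += 1
        assert rejections > n_rep / 2


class TestGenderTtest:
    def test_equal_means_give_t_zero(self):
        t, p = compare_gender_ttest(
            [2000, 4000, 2000, 4000], ["male", "male", "female", "female"]
        )
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_female_is_error(self):
        with pytest.raises(ValueError):
            compare_gender_ttest([1, 2, 3], ["male", "male", "female"])

    def test_similar_gender_means_not_rejected_in_majority(self):
        # grand means 5853 vs 6078 (SD 3274/2725), n 51/13
        non_rejections = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            males = rng.normal(5853, 3274, 51)
            females = rng.normal(6078, 2725, 13)
            _, p = compare_gender_ttest(
                np.concatenate([males, females]), ["male"] * 51 + ["female"] * 13
            )
            if p >= 0.05:
                non_rejections += 1
        assert non_rejections > n_rep / 2


class TestTerminationRegression:
    def test_null_slope_within_3_se_of_zero(self):
        panel = simulate_termination_panel(300, slope_per_1000=0.0, seed=42)
        res = termination_vs_steps(panel)
        assert not res.flagged
        assert abs(res.slope_per_1000) < 3 * res.se

    def test_negative_hazard_gives_negative_significant_slope(self):
        panel = simulate_termination_panel(200, slope_per_1000=-0.5, seed=7)
        res = termination_vs_steps(panel)
        assert not res.flagged
        assert res.slope_per_1000 < 0
        assert res.pvalue < 0.05

    def test_degenerate_no_terminations_flagged(self):
        panel = simulate_termination_panel(
            20, slope_per_1000=0.0, seed=1, baseline_logit=-50.0
        )
        res = termination_vs_steps(panel)
        assert res.flagged
        assert res.slope_per_1000 is None

    def test_empty_panel_flagged(self):
        import pandas as pd

        panel = pd.DataFrame(
            columns=["patient_id", "checkpoint", "week_mean", "terminated"]
        )
        res = termination_vs_steps(panel)
        assert res.flagged


def _tiny_cohort(config):
    """Three-stratum, six-patient cohort built by hand."""
    specs = {
        "p1": (1500, 80), "p2": (2500, 100),   # low
        "p3": (6000, 150), "p4": (7000, 200),  # medium
        "p5": (11000, 220), "p6": (12000, 250),  # high
    }
    series, profiles = {}, {}
    sexes = {"p1": "female", "p2": "male", "p3": "male",
             "p4": "male", "p5": "male", "p6": "female"}
    diags = {"p1": "ACS", "p2": "surgery", "p3": "ACS",
             "p4": "heart_failure", "p5": "ACS", "p6": "ACS_and_HF"}
    setts = {"p1": "hospital", "p2": "health_care_center", "p3": "call_center",
             "p4": "hospital", "p5": "health_care_center", "p6": "hospital"}
    for pid, (steps, dur) in specs.items():
        s = make_series(pid, set(range(1, dur + 1)), steps_on_active=steps)
        series[pid] = s
        profiles[pid] = PatientProfile(
            pid, 60.0 + dur / 10, sexes[pid], 28.0, 27.0, diags[pid], setts[pid]
        )
    adherence = {p: summarize_adherence(s, config) for p, s in series.items()}
    activity = {p: build_activity_profile(s, config) for p, s in series.items()}
    return profiles, adherence, activity


class TestTables:
    def test_table1_counts_conserved(self, config):
        profiles, adherence, activity = _tiny_cohort(config)
        res = build_table1(profiles, activity)
        counts = res.stats["counts"]
        for row, by_col in counts.items():
            assert by_col["all"] == sum(
                by_col[s] for s in ("low", "medium", "high")
            ), row
        assert counts["participants"]["all"] == 6

    def test_table2_structure_and_stats(self, config):
        profiles, adherence, activity = _tiny_cohort(config)
        res = build_table2(adherence, activity, profiles, config)
        assert res.stats["n_total"] == 6
        assert res.stats["stratum_n"] == {"low": 2, "medium": 2, "high": 2}
        gm = res.stats["grand_mean"]
        assert gm["low"]["mean"] == pytest.approx(2000)
        assert gm["high"]["mean"] == pytest.approx(11500)
        # active days == total days here, so the percent row is 100
        assert res.table.loc["active_total_pct", "all"] == "100"

    def test_single_stratum_degenerate_marked(self, config):
        profiles, adherence, activity = _tiny_cohort(config)
        keep = ["p3", "p4"]  # medium only
        res = build_table1(
            {p: profiles[p] for p in keep}, {p: activity[p] for p in keep}
        )
        assert res.table.loc["age_mean_sd", "p"] == "n/a"
        assert res.stats["counts"]["participants"]["medium"] == 2

    def test_mismatched_patient_sets_error(self, config):
        profiles, adherence, activity = _tiny_cohort(config)
        del profiles["p1"]
        with pytest.raises(ValueError, match="patient sets differ"):
            build_table1(profiles, activity)

    def test_termination_panel_contents(self, config):
        profiles, adherence, activity = _tiny_cohort(config)
        panel = termination_panel(adherence, activity, config)
        # p1 terminates at day 80: nonuser (LOCF) from checkpoint 90 onwards
        p1 = panel[panel["patient_id"] == "p1"]
        assert p1[p1["checkpoint"] == 30]["terminated"].item() == 0
        assert p1[p1["checkpoint"] == 90]["terminated"].item() == 1
        assert (p1["week_mean"] == 1500).all()  # constant series, LOCF carries 1500
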