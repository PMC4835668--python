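import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepcohort import AnalysisConfig, PatientProfile
from stepcohort.adherence import classify_active_days
from stepcohort.metrics import (
    NoActiveDaysError,
    bmi_change_summary,
    build_activity_profile,
    checkpoint_profile,
    checkpoint_week_mean,
    classify_activity_level,
    format_percent,
    grand_mean,
)

from conftest import make_series

CFG = AnalysisConfig()


def random_series(seed, horizon=365, p_zero=0.35, high=9000):
    rng = np.random.default_rng(seed)
    steps = rng.integers(0, high, size=horizon)
    steps[rng.random(horizon) < p_zero] = 0
    series = make_series("p", set(), horizon=horizon)
    series.steps[:] = steps
    series.recorded[:] = steps > 0
    return series


class TestGrandMean:
    def test_constant_active_days(self):
        series = make_series("p", set(range(1, 21)), steps_on_active=5000)
        mean, sd = grand_mean(series, classify_active_days(series, CFG))
        assert mean == 5000 and sd == 0

    def test_two_values(self):
        series = make_series("p", {1, 2})
        series.steps[0], series.steps[1] = 2000, 4000
        mean, _ = grand_mean(series, classify_active_days(series, CFG))
        assert mean == 3000

    def test_single_active_day_has_zero_sd(self):
        series = make_series("p", {5}, steps_on_active=4200)
        mean, sd = grand_mean(series, classify_active_days(series, CFG))
        assert mean == 4200 and sd == 0.0

    def test_no_active_days_is_signalled(self):
        series = make_series("p", set())
        with pytest.raises(NoActiveDaysError):
            grand_mean(series, classify_active_days(series, CFG))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_masked_mean(self, seed):
        series = random_series(seed)
        mask = classify_active_days(series, CFG)
        if not mask.any():
            return
        mean, sd = grand_mean(series, mask)
        vals = [int(s) for s, m in zip(series.steps, mask) if m]
        assert mean == pytest.approx(sum(vals) / len(vals))
        if len(vals) > 1:
            mu = sum(vals) / len(vals)
            var = sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)
            assert sd == pytest.approx(var**0.5)

    def test_invariant_to_permuting_active_days(self):
        series = random_series(11)
        mask = classify_active_days(series, CFG)
        mean, sd = grand_mean(series, mask)
        vals = series.steps[mask]
        perm = np.random.default_rng(0).permutation(vals)
        series2 = make_series("p", set())
        series2.steps[: len(perm)] = perm
        series2.recorded[: len(perm)] = True
        mask2 = classify_active_days(series2, CFG)
        mean2, sd2 = grand_mean(series2, mask2)
        assert mean2 == pytest.approx(mean) and sd2 == pytest.approx(sd)


class TestClassifyActivityLevel:
    @pytest.mark.parametrize(
        "value,expected",
        [(2999, "low"), (3000, "medium"), (9999, "medium"), (10000, "high"), (0, "low")],
    )
    def test_graduated_index_boundaries(self, value, expected):
        assert classify_activity_level(value, CFG) == expected

    @given(st.floats(min_value=0, max_value=50000, allow_nan=False))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exhaustive_and_exclusive(self, value):
        level = classify_activity_level(value, CFG)
        assert level in ("low", "medium", "high")
        assert (level == "low") == (value < 3000)
        assert (level == "high") == (value >= 10000)


class TestCheckpointWeekMean:
    def test_constant_window(self):
        series = make_series("p", set(range(1, 8)), steps_on_active=6000)
        mask = classify_active_days(series, CFG)
        assert checkpoint_week_mean(series, mask, 7, CFG) == 6000

    def test_inactive_day_excluded(self):
        series = make_series("p", set(range(1, 7)), steps_on_active=6000)  # day 7 inactive
        mask = classify_active_days(series, CFG)
        assert checkpoint_week_mean(series, mask, 7, CFG) == 6000

    def test_empty_window_is_undefined(self):
        series = make_series("p", set(range(50, 60)))
        mask = classify_active_days(series, CFG)
        assert checkpoint_week_mean(series, mask, 7, CFG) is None

    def test_checkpoint_before_window_is_error(self):
        series = make_series("p", {1})
        mask = classify_active_days(series, CFG)
        with pytest.raises(ValueError, match="precedes"):
            checkpoint_week_mean(series, mask, 5, CFG)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([7, 30, 90, 180, 270, 365]))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_slice_mean(self, seed, cp):
        series = random_series(seed)
        mask = classify_active_days(series, CFG)
        got = checkpoint_week_mean(series, mask, cp, CFG)
        window_days = range(cp - 6, cp + 1)  # 7 days ending at the checkpoint
        vals = [series.day(d) for d in window_days if series.day(d) >= 100]
        if not vals:
            assert got is None
        else:
            assert got == pytest.approx(sum(vals) / len(vals))


class TestCheckpointProfile:
    def test_user_at_all_checkpoints(self):
        series = make_series("p", set(range(1, 366)), steps_on_active=6000)
        prof = checkpoint_profile(series, CFG)
        assert all(est.status == "user" for est in prof.values())
        assert all(est.value == 6000 for est in prof.values())

    def test_locf_after_termination(self):
        # active days 1..100 at 6000: user at 7/30/90, terminated by 180
        series = make_series("p", set(range(1, 101)), steps_on_active=6000)
        prof = checkpoint_profile(series, CFG)
        assert prof[90].status == "user" and prof[90].value == 6000
        for cp in (180, 270, 365):
            assert prof[cp].status == "nonuser_locf"
            assert prof[cp].value == prof[90].value

    def test_never_active_all_undefined(self):
        series = make_series("p", set())
        prof = checkpoint_profile(series, CFG)
        assert all(est.status == "undefined" for est in prof.values())

    def test_locf_values_constant_after_termination(self):
        rng = np.random.default_rng(3)
        series = make_series("p", set(range(1, 96)))
        series.steps[:95] = rng.integers(2000, 9000, size=95)
        prof = checkpoint_profile(series, CFG)
        locf = [prof[cp].value for cp in (180, 270, 365)]
        assert locf[0] == locf[1] == locf[2] == prof[90].value

    def test_nonuser_with_no_defined_week_mean_is_undefined(self):
        # qualifying run at days 10..14 only: user at no checkpoint except none;
        # window at day 7 and 30 contain no active days... day 14 run means
        # final_day=14, so user at 7 (window empty -> undefined), nonuser later
        series = make_series("p", set(range(10, 15)))
        prof = checkpoint_profile(series, CFG)
        assert prof[7].status == "undefined"
        assert all(prof[cp].status == "undefined" for cp in (30, 90, 180, 270, 365))


class TestBmiAndPercent:
    def test_bmi_mean_of_two_measurements(self):
        p = PatientProfile("p", 60, "male", 30.0, 26.0, "ACS", "hospital")
        assert bmi_change_summary(p) == 28.0

    def test_bmi_identity(self):
        p = PatientProfile("p", 60, "male", 27.0, 27.0, "ACS", "hospital")
        assert bmi_change_summary(p) == 27.0

    def test_bmi_missing_followup_undefined(self):
        p = PatientProfile("p", 60, "male", 30.0, None, "ACS", "hospital")
        assert bmi_change_summary(p) is None

    @pytest.mark.parametrize(
        "num,den,expected",
        [(139, 160, 87), (51, 64, 80), (0, 10, 0), (1, 8, 13), (1, 200, 1)],
    )
    def test_format_percent(self, num, den, expected):
        assert format_percent(num, den) == expected

    def test_format_percent_errors(self):
        with pytest.raises(ValueError):
            format_percent(1, 0)
        with pytest.raises(ValueError):
            format_percent(5, 4)


class TestBuildActivityProfile:
    def test_profile_ties_pieces_together(self):
        series = make_series("p", set(range(1, 101)), steps_on_active=6000)
        prof = build_activity_profile(series, CFG)
        assert prof.grand_mean == 6000
        assert prof.activity_level == "medium"
        assert prof.checkpoint_means[365].status == "nonuser_locf"

    def test_undefined_profile(self):
        series = make_series("p", set())
        prof = build_activity_profile(series, CFG)
        assert prof.grand_mean is None and prof.activity_level is None
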