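import numpy as np
import pytest

from stepcohort import AnalysisConfig, DailyStepSeries
from stepcohort.simulate import SimulationParams, generate_cohort


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def short_config() -> AnalysisConfig:
    """60-day horizon for fast pipeline tests."""
    return AnalysisConfig(checkpoints=(7, 30, 60), horizon=60)


@pytest.fixture
def small_params(short_config) -> SimulationParams:
    """A small, fast cohort whose durations fit the 60-day horizon."""
    return SimulationParams(
        n_patients=6,
        stratum_duration_means=(20.0, 30.0, 40.0),
        stratum_duration_sds=(6.0, 8.0, 10.0),
        horizon=short_config.horizon,
        seed=7,
    )


@pytest.fixture
def small_cohort(small_params):
    return generate_cohort(small_params)


def make_series(
    pid: str,
    active_days: set[int],
    horizon: int = 365,
    steps_on_active: int = 5000,
) -> DailyStepSeries:
    """Series active (steps_on_active) exactly on the given 1-based days."""
    steps = np.zeros(horizon, dtype=np.int64)
    for d in active_days:
        steps[d - 1] = steps_on_active
    return DailyStepSeries(pid, steps)
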