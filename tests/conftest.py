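import numpy as np
import pytest

from growthrel import GroundTruth, VisitSchedule, generate_cohort, generate_test_retest


@pytest.fixture
def default_truth():
    """Hippocampus-like feature: moderate decline, mid-range reliability."""
    return GroundTruth(
        feature_id="hippocampus_volume",
        baseline_mean=4000.0,
        mean_yearly_change=-0.6,
        slope_sd=0.55,
        noise_sd=0.4,
    )


@pytest.fixture
def flat_truth():
    """No population trend, no covariate effects: slopes are the only signal."""
    return GroundTruth(
        feature_id="flat",
        baseline_mean=100.0,
        mean_yearly_change=0.0,
        slope_sd=0.5,
        noise_sd=0.5,
        trend=lambda age: np.full_like(np.asarray(age, dtype=float), 100.0),
        intercept_sd=0.0,
    )


@pytest.fixture
def small_cohort(default_truth):
    cohort, subjects = generate_cohort(
        default_truth, 200, VisitSchedule(6.0, 4), n_sites=2, seed=11
    )
    return cohort, subjects


@pytest.fixture
def retest_pair(default_truth):
    return generate_test_retest(default_truth, 300, n_sessions=2, seed=21)
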