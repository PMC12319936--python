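"""Generator contracts: row counts, determinism, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from growthrel import (
    GroundTruth,
    VisitSchedule,
    apply_attrition,
    compute_slope_table,
    generate_cohort,
    generate_test_retest,
)
from growthrel.error import EQ_TEST_RETEST_FACTOR, c4, error_dense, error_test_retest
from growthrel.reliability import sst_equispaced


def test_row_count_is_subjects_times_visits(default_truth):
    cohort, subjects = generate_cohort(default_truth, 100, VisitSchedule(6.0, 4), seed=1)
    assert len(cohort) == 400
    assert len(subjects) == 100


def test_same_seed_reproduces_identical_tables(default_truth):
    a, sa = generate_cohort(default_truth, 50, VisitSchedule(4.0, 3, jitter_sd=0.2), seed=5)
    b, sb = generate_cohort(default_truth, 50, VisitSchedule(4.0, 3, jitter_sd=0.2), seed=5)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(sa, sb)


def test_noiseless_slopes_match_truth_exactly(flat_truth):
    truth = GroundTruth(**{**flat_truth.__dict__, "noise_sd": 0.0})
    cohort, subjects = generate_cohort(truth, 100, VisitSchedule(6.0, 4), seed=3)
    slopes = compute_slope_table(cohort, detrended=False)
    merged = slopes.merge(subjects, on="subject_id")
    np.testing.assert_allclose(merged["slope_pct"], merged["true_slope_pct"], rtol=1e-9)


def test_slope_sd_recovered_from_noiseless_cohort(flat_truth):
    truth = GroundTruth(**{**flat_truth.__dict__, "noise_sd": 0.0})
    n = 5000
    cohort, _ = generate_cohort(truth, n, VisitSchedule(6.0, 4), seed=7)
    slopes = compute_slope_table(cohort, detrended=False)
    sd = slopes["slope_pct"].std(ddof=1)
    tol = 3 * 0.5 / np.sqrt(2 * (n - 1))
    assert abs(sd - 0.5) < tol


def test_test_retest_sessions_share_truth(default_truth):
    truth = GroundTruth(**{**default_truth.__dict__, "noise_sd": 0.0})
    trt = generate_test_retest(truth, 50, n_sessions=2, seed=9)
    wide = trt.pivot(index="subject_id", columns="session", values="value")
    stats = [error_test_retest(a, b) for a, b in wide.itertuples(index=False)]
    assert np.allclose(stats, 0.0)


def test_pairwise_error_statistic_converges_to_half_normal_mean(default_truth):
    truth = GroundTruth(**{**default_truth.__dict__, "noise_sd": 1.0})
    n = 5000
    trt = generate_test_retest(truth, n, n_sessions=2, seed=13)
    wide = trt.pivot(index="subject_id", columns="session", values="value")
    stats = np.array([error_test_retest(a, b) for a, b in wide.itertuples(index=False)])
    expected = EQ_TEST_RETEST_FACTOR * 1.0  # E|N(0, 2 sigma^2)| = 2 sigma / sqrt(pi)
    se = np.sqrt(2 * (1 - 2 / np.pi)) / np.sqrt(n)  # SD of half-normal / sqrt(n)
    assert abs(stats.mean() - expected) < 3 * se


def test_cv_statistic_converges_to_c4_scaled_sd(default_truth):
    truth = GroundTruth(**{**default_truth.__dict__, "noise_sd": 1.0})
    n = 5000
    trt = generate_test_retest(truth, n, n_sessions=3, seed=17)
    stats = trt.groupby("subject_id")["value"].apply(lambda v: error_dense(v.to_numpy()))
    expected = c4(3) * 1.0  # E[sample SD of 3 normals] = c4(3) sigma ~ 0.8862
    se = np.sqrt(1 - c4(3) ** 2) / np.sqrt(n)
    assert abs(stats.mean() - expected) < 3 * se


def test_observed_slope_variance_includes_error_propagation(flat_truth):
    # var(observed slopes) = sigma_s^2 + sigma_eps^2 / SST
    truth = GroundTruth(**{**flat_truth.__dict__, "noise_sd": 1.0, "slope_sd": 0.5})
    n = 4000
    cohort, _ = generate_cohort(truth, n, VisitSchedule(4.0, 4), seed=19)
    slopes = compute_slope_table(cohort, detrended=False)
    expected_var = 0.5**2 + 1.0**2 / sst_equispaced(4.0, 4)
    obs_var = slopes["slope_pct"].var(ddof=1)
    tol = 3 * expected_var * np.sqrt(2 / (n - 1))
    assert abs(obs_var - expected_var) < tol


def test_attrition_zero_is_identity(small_cohort, default_truth):
    cohort, _ = small_cohort
    out = apply_attrition(cohort, default_truth, mode="random", seed=1)
    pd.testing.assert_frame_equal(out, cohort)


def test_attrition_one_leaves_only_baseline(small_cohort, default_truth):
    truth = GroundTruth(**{**default_truth.__dict__, "attrition_per_visit": 1.0})
    cohort, _ = small_cohort
    out = apply_attrition(cohort, truth, mode="random", seed=1)
    assert (out.groupby("subject_id").size() == 1).all()
    assert (out["time_years"] == 0).all()


def test_attrition_is_monotone_dropout(small_cohort, default_truth):
    truth = GroundTruth(**{**default_truth.__dict__, "attrition_per_visit": 0.3})
    cohort, _ = small_cohort
    out = apply_attrition(cohort, truth, mode="random", seed=2)
    # retained visits per subject are always the first k of the schedule
    for _, g in out.groupby("subject_id"):
        full = cohort[cohort["subject_id"] == g["subject_id"].iloc[0]]
        assert g["time_years"].tolist() == full["time_years"].tolist()[: len(g)]


def test_slope_dependent_attrition_homogenizes_retained_slopes(flat_truth):
    truth = GroundTruth(**{**flat_truth.__dict__, "attrition_per_visit": 0.3})
    cohort, subjects = generate_cohort(truth, 5000, VisitSchedule(8.0, 6), seed=23)
    out = apply_attrition(cohort, truth, mode="slope_dependent", seed=24,
                          true_slopes=subjects, coef=1.5)
    counts = out.groupby("subject_id").size()
    retained = counts[counts >= 4].index
    sd_all = subjects["true_slope_pct"].std(ddof=1)
    sd_ret = subjects.set_index("subject_id").loc[retained, "true_slope_pct"].std(ddof=1)
    assert sd_ret < sd_all


def test_unknown_attrition_mode_rejected(small_cohort, default_truth):
    cohort, _ = small_cohort
    with pytest.raises(ValueError, match="mode"):
        apply_attrition(cohort, default_truth, mode="bogus")


def test_jitter_never_reorders_visits(default_truth):
    sched = VisitSchedule(4.0, 5, jitter_sd=1.0)  # jitter larger than spacing
    rng = np.random.default_rng(0)
    times = sched.draw_times(rng, 500)
    assert (np.diff(times, axis=1) > 0).all()
    assert (times[:, 0] == 0).all()


def test_skewed_slopes_keep_mean_and_sd():
    truth = GroundTruth("f", 100.0, -0.3, 0.5, 0.0, slope_skewness=-0.5,
                        intercept_sd=0.0)
    from growthrel.synthetic import _draw_slope_deviations

    rng = np.random.default_rng(31)
    s = _draw_slope_deviations(rng, truth, 200_000, mean=-0.3)
    assert abs(s.mean() - (-0.3)) < 0.005
    assert abs(s.std(ddof=1) - 0.5) < 0.005
    from scipy import stats as sps

    assert sps.skew(s) < -0.4  # negative skew direction preserved


@settings(max_examples=25, deadline=None)
@given(
    n_subjects=st.integers(5, 40),
    duration=st.floats(1.0, 12.0),
    n_obs=st.integers(2, 8),
    jitter=st.floats(0.0, 0.5),
    seed=st.integers(0, 10_000),
)
def test_structural_invariants_hold_for_random_configs(n_subjects, duration, n_obs, jitter, seed):
    truth = GroundTruth("f", 100.0, -0.2, 0.4, 0.6)
    cohort, subjects = generate_cohort(
        truth, n_subjects, VisitSchedule(duration, n_obs, jitter_sd=jitter), seed=seed
    )
    assert len(cohort) == n_subjects * n_obs
    assert (cohort["time_years"] >= 0).all()
    first = cohort.groupby("subject_id")["time_years"].min()
    assert (first == 0).all()
    assert not cohort.duplicated(["subject_id", "feature", "time_years"]).any()


def test_invalid_ground_truth_rejected():
    with pytest.raises(ValueError):
        GroundTruth("f", -1.0, 0.0, 0.5, 0.5)
    with pytest.raises(ValueError):
        GroundTruth("f", 100.0, 0.0, -0.5, 0.5)
    with pytest.raises(ValueError):
        GroundTruth("f", 100.0, 0.0, 0.5, 0.5, attrition_per_visit=1.5)
    with pytest.raises(ValueError):
        VisitSchedule(0.0, 3)
    with pytest.raises(ValueError):
        VisitSchedule(4.0, 1)
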