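"""Attenuation/power, distribution overlap, misclassification, membership."""

import math

import numpy as np
import pytest
from scipy import stats

from growthrel import (
    HypotheticalTrio,
    PowerScenario,
    attenuated_r,
    bc_normals,
    bhattacharyya,
    bhattacharyya_normals_numeric,
    group_membership,
    membership_closed_form,
    misclassification_probability,
    sample_size_correlation,
    trio_misclassification,
    trio_overlap,
)


@pytest.mark.parametrize(
    "r,icc,expected",
    [(0.5, 1.0, 0.5), (0.5, 0.24, 0.5 * math.sqrt(0.24)), (0.3, 0.0, 0.0)],
)
def test_attenuation_formula(r, icc, expected):
    assert attenuated_r(r, icc) == pytest.approx(expected)


def test_attenuation_rejects_out_of_range():
    with pytest.raises(ValueError):
        attenuated_r(1.5, 0.5)
    with pytest.raises(ValueError):
        attenuated_r(0.5, -0.1)


def test_sample_size_fisher_z_hand_values():
    # ((1.95996 + 0.84162) / atanh(0.5))^2 + 3 = 29.012 -> 30 after ceiling
    assert sample_size_correlation(PowerScenario(0.5), icc=1.0) == 30
    # atanh(0.5 sqrt(0.24)) = 0.25003 -> 128.55 -> 129
    assert sample_size_correlation(PowerScenario(0.5), icc=0.24) == 129


def test_sample_size_unbounded_at_zero_reliability():
    assert sample_size_correlation(PowerScenario(0.5), icc=0.0) == math.inf


def test_sample_size_nonincreasing_in_reliability():
    scen = PowerScenario(0.3)
    ns = [sample_size_correlation(scen, icc) for icc in (0.1, 0.3, 0.6, 0.9, 1.0)]
    assert all(a >= b for a, b in zip(ns, ns[1:]))


def test_power_scenario_validation():
    with pytest.raises(ValueError):
        PowerScenario(0.0)
    with pytest.raises(ValueError):
        PowerScenario(0.5, alpha=1.5)


def test_bhattacharyya_identical_normals():
    x = np.linspace(-8, 8, 4001)
    p = stats.norm.pdf(x)
    assert bhattacharyya(x, p, p) == pytest.approx(1.0, abs=1e-6)


def test_bhattacharyya_effectively_disjoint_densities():
    x = np.linspace(-28, 28, 8001)
    p = stats.norm.pdf(x, -20, 1)
    q = stats.norm.pdf(x, 20, 1)
    assert bhattacharyya(x, p, q) == pytest.approx(0.0, abs=1e-9)


def test_bhattacharyya_rejects_unnormalized():
    x = np.linspace(-8, 8, 1001)
    p = stats.norm.pdf(x)
    with pytest.raises(ValueError, match="integrates"):
        bhattacharyya(x, 2 * p, p)


@pytest.mark.parametrize(
    "mu1,sd1,mu2,sd2,expected",
    [
        (0.0, 1.0, 0.0, 1.0, 1.0),
        (0.0, 1.0, 2.0, 1.0, math.exp(-0.5)),        # mean-shift-only case
        (0.0, 1.0, 0.0, 2.0, math.sqrt(4.0 / 5.0)),  # variance-mismatch-only
    ],
)
def test_bc_normals_closed_form(mu1, sd1, mu2, sd2, expected):
    assert bc_normals(mu1, sd1, mu2, sd2) == pytest.approx(expected)


def test_bc_numeric_matches_closed_form_on_random_pairs():
    rng = np.random.default_rng(3)
    for _ in range(25):
        mu1, mu2 = rng.normal(0, 2, 2)
        sd1, sd2 = rng.uniform(0.2, 3.0, 2)
        num = bhattacharyya_normals_numeric(mu1, sd1, mu2, sd2)
        assert num == pytest.approx(bc_normals(mu1, sd1, mu2, sd2), abs=1e-4)


def test_misclassification_hand_values():
    assert misclassification_probability(0.0, 1.0) == 0.5
    assert misclassification_probability(1.0, math.inf) == 0.5
    assert misclassification_probability(1.0, 1.0 / math.sqrt(2.0)) == pytest.approx(
        stats.norm.cdf(-1.0), abs=1e-9
    )
    assert misclassification_probability(1.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        misclassification_probability(0.0, 0.0)


def test_misclassification_monte_carlo_oracle():
    rng = np.random.default_rng(5)
    delta, err = 1.0, 1.0 / math.sqrt(2.0)
    n = 1_000_000
    a = rng.normal(0.0, err, n)
    b = rng.normal(delta, err, n)
    p_mc = (b < a).mean()
    p = misclassification_probability(delta, err)
    assert p_mc == pytest.approx(p, abs=3 * math.sqrt(p * (1 - p) / n))


def test_misclassification_decreasing_in_delta_and_sst():
    ps = [misclassification_probability(d, 0.5) for d in (0.1, 0.5, 1.0, 2.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))
    # larger SST -> smaller slope error SD -> smaller misclassification
    ps2 = [misclassification_probability(1.0, 2.0 / math.sqrt(s)) for s in (2, 8, 32)]
    assert all(a > b for a, b in zip(ps2, ps2[1:]))


def test_misclassification_at_reliability_rho():
    # at reliability rho and offset k SDs: p = Phi(-k sqrt(rho / (2 (1-rho))))
    slope_sd, err = 0.5, 0.7
    rho = slope_sd**2 / (slope_sd**2 + err**2)
    k = 1.0
    expected = stats.norm.cdf(-k * math.sqrt(rho / (2 * (1 - rho))))
    assert misclassification_probability(k * slope_sd, err) == pytest.approx(expected)


def test_trio_helpers():
    trio = HypotheticalTrio(mean_change=-0.2, slope_sd=0.5, slope_error_sd=0.5)
    # decliner vs normal ager are 1 slope SD apart
    assert trio_misclassification(trio, ("decliner", "normal_ager")) == pytest.approx(
        misclassification_probability(0.5, 0.5)
    )
    # maintainer vs decliner are 2 SDs apart: strictly fewer errors
    assert trio_misclassification(trio, ("decliner", "maintainer")) < trio_misclassification(
        trio, ("decliner", "normal_ager")
    )
    assert trio_overlap(trio, ("decliner", "normal_ager")) == pytest.approx(
        bc_normals(-0.7, 0.5, -0.2, 0.5), abs=1e-4
    )


def test_membership_symmetric_at_zero_mean_change():
    rep = membership_closed_form(0.0, 0.5, 0.3)
    assert rep.p_observed_maintainer == pytest.approx(0.5)
    sim = group_membership(0.0, 0.5, 0.3, n_sim=200_000, seed=2)
    assert sim.p_observed_maintainer == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(200_000))


def test_membership_errorless_observation_is_truth():
    rep = membership_closed_form(-0.2, 0.5, 0.0)
    assert rep.p_true_maintainer_given_observed == 1.0
    assert rep.p_true_decliner_given_observed == 0.0
    assert rep.p_observed_maintainer == pytest.approx(1.0 - stats.norm.cdf(0.4), abs=1e-9)
    sim = group_membership(-0.2, 0.5, 0.0, n_sim=100_000, seed=3)
    assert sim.p_true_maintainer_given_observed == 1.0


def test_membership_simulation_matches_closed_form():
    n_sim = 100_000
    for mean, ssd, esd, seed in [
        (-0.2, 0.5, 0.3, 4),
        (-0.5, 0.4, 0.8, 5),
        (0.0, 0.5, 0.5, 6),
    ]:
        sim = group_membership(mean, ssd, esd, n_sim=n_sim, seed=seed)
        cf = membership_closed_form(mean, ssd, esd)
        for name in (
            "p_observed_maintainer",
            "p_true_maintainer_given_observed",
            "p_true_decliner_given_observed",
        ):
            p = getattr(cf, name)
            se = math.sqrt(max(p * (1 - p), 1e-6) / n_sim)
            assert getattr(sim, name) == pytest.approx(p, abs=3.5 * se)


def test_membership_complement_identity():
    # every observed maintainer either truly maintains or truly declines
    # (some severity): P(true decline | obs) = 1 - P(true maint | obs)
    cf = membership_closed_form(-0.3, 0.5, 0.4)
    s2 = 0.5**2
    o2 = s2 + 0.4**2
    mvn = stats.multivariate_normal(
        mean=[-0.3, -0.3], cov=[[s2, s2], [s2, o2]]
    )
    p_obs = stats.norm.sf(0.3 / math.sqrt(o2))
    p_any_decline_given_obs = (
        stats.norm.cdf(0.3 / 0.5) - mvn.cdf([0.0, 0.0])
    ) / p_obs
    assert cf.p_true_maintainer_given_observed + p_any_decline_given_obs == pytest.approx(
        1.0, abs=1e-6
    )


def test_membership_closed_form_mc_oracle_equal_sds():
    # brute-force oracle at sigma_s = sigma_err, zero mean change
    rng = np.random.default_rng(9)
    n = 2_000_000
    true = rng.normal(0.0, 0.5, n)
    obs = true + rng.normal(0.0, 0.5, n)
    sel = obs >= 0
    p_td_mc = (true[sel] < 0.0).mean()
    cf = membership_closed_form(0.0, 0.5, 0.5)
    assert cf.p_true_decliner_given_observed == pytest.approx(p_td_mc, abs=0.002)
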