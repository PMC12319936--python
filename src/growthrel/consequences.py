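"""Downstream consequences of imperfect slope reliability.

Three analyses that translate a reliability value into study-design
currency:

* **Sample size under attenuation** — an imperfectly reliable change
  score attenuates a true correlation r to r * sqrt(rho); the required n
  for 80% power then follows from the Fisher-z approximation.
* **Trajectory overlap and misclassification** — hypothetical individuals
  (normal ager, maintainer, decliner at 0 / +1 / -1 slope SDs from the
  population mean) have observed-slope distributions whose overlap is the
  Bhattacharyya coefficient; the probability of observing their slopes in
  the wrong order quantifies misclassification.
* **Group membership** — among subjects with no *observed* decline over
  the study, how many truly maintain, and how many truly decline faster
  than average? Simulated and in closed form from the joint normal of
  (true, observed) slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

_SQRT2 = math.sqrt(2.0)


@dataclass
class PowerScenario:
    """Target effect and error rates for a correlation power analysis."""

    true_r: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.true_r < 1.0:
            raise ValueError("true_r must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")


@dataclass
class HypotheticalTrio:
    """Normal ager / maintainer / decliner at 0 / +1 / -1 slope SDs."""

    mean_change: float       # percent/yr (population mean, negative = decline)
    slope_sd: float          # percent/yr
    slope_error_sd: float    # percent/yr (error SD of an estimated slope)

    def __post_init__(self) -> None:
        if self.slope_sd < 0 or self.slope_error_sd < 0:
            raise ValueError("SDs must be non-negative")

    @property
    def offsets(self) -> dict[str, float]:
        return {"normal_ager": 0.0, "maintainer": +1.0, "decliner": -1.0}

    def observed_mean(self, who: str) -> float:
        return self.mean_change + self.offsets[who] * self.slope_sd


@dataclass
class MembershipReport:
    """Proportions from the observed-maintainer classification."""

    p_observed_maintainer: float
    p_true_maintainer_given_observed: float
    p_true_decliner_given_observed: float

    def __post_init__(self) -> None:
        for v in (
            self.p_observed_maintainer,
            self.p_true_maintainer_given_observed,
            self.p_true_decliner_given_observed,
        ):
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def attenuated_r(true_r: float, icc: float) -> float:
    """Observed correlation after attenuation by change-score reliability.

    Assumes perfect reliability of the other variable: r_obs = r * sqrt(icc).
    """
    if not 0.0 <= true_r <= 1.0 or not 0.0 <= icc <= 1.0:
        raise ValueError("true_r and icc must lie in [0, 1]")
    return true_r * math.sqrt(icc)


def sample_size_correlation(scenario: PowerScenario, icc: float) -> float:
    """Required n to detect the attenuated correlation (Fisher-z approximation).

    n = ((z_{1-alpha/2} + z_{power}) / atanh(r_att))^2 + 3, rounded up.
    Returns ``math.inf`` when the attenuated correlation is zero.
    """
    r_att = attenuated_r(scenario.true_r, icc)
    if r_att == 0.0:
        return math.inf
    za = stats.norm.ppf(1.0 - scenario.alpha / 2.0)
    zb = stats.norm.ppf(scenario.power)
    n = ((za + zb) / math.atanh(r_att)) ** 2 + 3.0
    return int(math.ceil(n - 1e-9))


def bhattacharyya(x, p, q, tol: float = 1e-6) -> float:
    """Overlap of two densities on a common grid: trapezoid of sqrt(p q).

    Both densities must integrate to 1 on the grid within ``tol``.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if x.shape != p.shape or x.shape != q.shape:
        raise ValueError("grid and densities must share a shape")
    for name, d in (("p", p), ("q", q)):
        mass = np.trapezoid(d, x)
        if abs(mass - 1.0) > tol:
            raise ValueError(f"density {name} integrates to {mass:.8f}, not 1")
    return float(np.trapezoid(np.sqrt(np.clip(p * q, 0.0, None)), x))


def bhattacharyya_normals_numeric(
    mu1: float, sd1: float, mu2: float, sd2: float, n_grid: int = 8193
) -> float:
    """Numeric overlap of two normals on a grid spanning +-8 SD of both."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    lo = min(mu1 - 8 * sd1, mu2 - 8 * sd2)
    hi = max(mu1 + 8 * sd1, mu2 + 8 * sd2)
    x = np.linspace(lo, hi, n_grid)
    return bhattacharyya(x, stats.norm.pdf(x, mu1, sd1), stats.norm.pdf(x, mu2, sd2))


def bc_normals(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Closed-form Bhattacharyya coefficient of two normal densities."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    v1, v2 = sd1 * sd1, sd2 * sd2
    return float(
        math.exp(-((mu1 - mu2) ** 2) / (4.0 * (v1 + v2)))
        * math.sqrt(2.0 * sd1 * sd2 / (v1 + v2))
    )


def misclassification_probability(delta: float, slope_error_sd: float) -> float:
    """P(two independent observed slopes invert a true gap of ``delta``).

    For observed slopes with independent N(0, slope_error_sd^2) errors the
    difference has SD sqrt(2) * slope_error_sd, so the inversion
    probability is Phi(-delta / (sqrt(2) slope_error_sd)): 0.5 at delta = 0
    (or unbounded error) and 0 for error-free measurement of a real gap.
    """
    if delta < 0 or slope_error_sd < 0:
        raise ValueError("delta and slope_error_sd must be non-negative")
    if delta == 0.0 and slope_error_sd == 0.0:
        raise ValueError("misclassification undefined for delta = error = 0")
    if delta == 0.0 or math.isinf(slope_error_sd):
        return 0.5
    if slope_error_sd == 0.0:
        return 0.0
    return float(stats.norm.cdf(-delta / (_SQRT2 * slope_error_sd)))


def trio_misclassification(trio: HypotheticalTrio, pair=("decliner", "normal_ager")) -> float:
    """Misclassification probability for a pair of hypothetical individuals."""
    delta = abs(trio.observed_mean(pair[0]) - trio.observed_mean(pair[1]))
    return misclassification_probability(delta, trio.slope_error_sd)


def trio_overlap(trio: HypotheticalTrio, pair=("decliner", "normal_ager")) -> float:
    """Bhattacharyya overlap of observed-slope densities for a pair."""
    if trio.slope_error_sd == 0.0:
        return 1.0 if trio.observed_mean(pair[0]) == trio.observed_mean(pair[1]) else 0.0
    return bhattacharyya_normals_numeric(
        trio.observed_mean(pair[0]), trio.slope_error_sd,
        trio.observed_mean(pair[1]), trio.slope_error_sd,
    )


def group_membership(
    mean_change: float,
    slope_sd: float,
    slope_error_sd: float,
    n_sim: int = 100_000,
    seed: int = 0,
) -> MembershipReport:
    """Simulated membership proportions under the observed-maintainer rule.

    True slopes are N(mean_change, slope_sd^2); observed slopes add
    independent N(0, slope_error_sd^2) noise. "Observed maintainer" means
    observed slope >= 0; "true maintainer" true slope >= 0; "true
    decliner" true slope below the population mean.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if slope_sd <= 0:
        raise ValueError("slope_sd must be positive")
    rng = np.random.default_rng(seed)
    true = rng.normal(mean_change, slope_sd, n_sim)
    obs = true + rng.normal(0.0, slope_error_sd, n_sim)
    maint_obs = obs >= 0.0
    p_obs = maint_obs.mean()
    if maint_obs.sum() == 0:
        return MembershipReport(float(p_obs), np.nan, np.nan)
    p_tm = (true[maint_obs] >= 0.0).mean()
    p_td = (true[maint_obs] < mean_change).mean()
    return MembershipReport(float(p_obs), float(p_tm), float(p_td))


def membership_closed_form(
    mean_change: float, slope_sd: float, slope_error_sd: float
) -> MembershipReport:
    """Exact membership proportions from the joint normal of (true, observed).

    The pair (true, observed) is bivariate normal with correlation
    slope_sd / sqrt(slope_sd^2 + slope_error_sd^2); the three proportions
    are orthant probabilities of that joint.
    """
    if slope_sd <= 0:
        raise ValueError("slope_sd must be positive")
    s2 = slope_sd * slope_sd
    o2 = s2 + slope_error_sd * slope_error_sd
    so = math.sqrt(o2)
    p_obs = float(stats.norm.sf(-mean_change / so))  # P(obs >= 0)

    if slope_error_sd == 0.0:
        # observation equals truth: every observed maintainer is a true one
        if p_obs <= 0:
            return MembershipReport(p_obs, np.nan, np.nan)
        if mean_change <= 0:
            p_td = 0.0  # true >= 0 precludes true < mean_change <= 0
        else:
            lo = -mean_change / slope_sd  # z-threshold of true >= 0
            p_td = float((stats.norm.cdf(0.0) - stats.norm.cdf(lo)) / stats.norm.sf(lo))
        return MembershipReport(p_obs, 1.0, p_td)

    cov = np.array([[s2, s2], [s2, o2]])
    mean = np.array([mean_change, mean_change])
    mvn = stats.multivariate_normal(mean=mean, cov=cov, allow_singular=True)

    def p_joint(t_hi: float, o_hi: float) -> float:
        return float(mvn.cdf(np.array([t_hi, o_hi])))

    # P(true >= 0, obs >= 0) by inclusion-exclusion
    p_t_lt0 = float(stats.norm.cdf(-mean_change / slope_sd))
    p_o_lt0 = 1.0 - p_obs
    p_both_lt0 = p_joint(0.0, 0.0)
    p_tm_joint = 1.0 - p_t_lt0 - p_o_lt0 + p_both_lt0
    # P(true < mean_change, obs >= 0) = P(true < mean) - P(true < mean, obs < 0)
    p_td_joint = 0.5 - p_joint(mean_change, 0.0)

    if p_obs <= 0:
        return MembershipReport(p_obs, np.nan, np.nan)
    return MembershipReport(
        p_obs,
        float(np.clip(p_tm_joint / p_obs, 0.0, 1.0)),
        float(np.clip(p_td_joint / p_obs, 0.0, 1.0)),
    )
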