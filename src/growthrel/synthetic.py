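"""Synthetic longitudinal cohorts with known ground truth.

Simulates the data-generating process assumed by the linear-trajectory
model of change,

    Y_ij = b1_i + b2_i * t_j + e_ij,

where each subject i carries a true yearly rate of change ``b2_i`` drawn
from a (possibly skewed) normal population with mean ``mean_yearly_change``
and SD ``slope_sd`` (both in percent of the subject's reference value per
year), and every measurement carries i.i.d. cross-sectional noise ``e_ij``
with SD ``noise_sd`` (percent of the reference value). Subject intercepts
come from a population mean trajectory over age plus normal subject and
site offsets. Because the generative parameters are returned alongside the
data, every downstream estimator (measurement error, slope dispersion,
reliability) can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

#: column order of a long-format longitudinal cohort table
COHORT_COLUMNS = [
    "subject_id", "cohort_id", "site_id", "sex",
    "age_baseline", "time_years", "feature", "value",
]

#: column order of a repeated-measures (test-retest / dense) table
RETEST_COLUMNS = ["subject_id", "cohort_id", "feature", "session", "value"]

# |skewness| of a skew-normal cannot reach the half-normal bound ~0.9953
_MAX_SKEW = 0.99


@dataclass
class GroundTruth:
    """Generative parameters for one morphometric feature.

    Parameters
    ----------
    feature_id : str
        Name of the simulated feature (e.g. ``"hippocampus_volume"``).
    baseline_mean : float
        Population mean value, in feature units, at ``reference_age``.
    mean_yearly_change : float
        Population mean rate of change, percent of mean per year
        (negative for atrophy).
    slope_sd : float
        Between-subject SD of the true yearly change, percent per year.
    noise_sd : float
        SD of the cross-sectional measurement noise added to every
        observation, percent of the subject's reference value.
    trend : callable, optional
        Population mean trajectory as a function of age (years ->
        feature units). Defaults to the line implied by
        ``baseline_mean`` and ``mean_yearly_change`` anchored at
        ``reference_age``.
    site_offset_sd : float
        SD of multiplicative site (scanner) offsets, percent.
    attrition_per_visit : float
        Per-visit dropout hazard in [0, 1]; see :func:`apply_attrition`.
    slope_skewness : float
        Skewness of the slope distribution (0 = normal). The skew-normal
        is re-parameterized so mean and SD stay fixed.
    intercept_sd : float
        SD of subject-level intercept offsets, percent of the trend value.
    sex_effect_pct : float
        Additive offset (percent) applied to male subjects' reference value.
    age_range : (float, float)
        Baseline ages are drawn uniformly over this interval.
    reference_age : float
        Age anchoring ``baseline_mean`` and the default linear trend.
    """

    feature_id: str
    baseline_mean: float
    mean_yearly_change: float
    slope_sd: float
    noise_sd: float
    trend: Optional[Callable[[np.ndarray], np.ndarray]] = None
    site_offset_sd: float = 0.0
    attrition_per_visit: float = 0.0
    slope_skewness: float = 0.0
    intercept_sd: float = 5.0
    sex_effect_pct: float = 0.0
    age_range: tuple[float, float] = (60.0, 80.0)
    reference_age: float = 70.0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.slope_sd < 0 or self.noise_sd < 0:
            raise ValueError("slope_sd and noise_sd must be non-negative")
        if not 0.0 <= self.attrition_per_visit <= 1.0:
            raise ValueError("attrition_per_visit must lie in [0, 1]")
        if abs(self.slope_skewness) > _MAX_SKEW:
            raise ValueError(f"|slope_skewness| must be <= {_MAX_SKEW}")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be an increasing interval")

    def trend_values(self, ages: np.ndarray) -> np.ndarray:
        """Population mean trajectory evaluated at ``ages`` (feature units)."""
        ages = np.asarray(ages, dtype=float)
        if self.trend is not None:
            out = np.asarray(self.trend(ages), dtype=float)
        else:
            out = self.baseline_mean * (
                1.0 + self.mean_yearly_change / 100.0 * (ages - self.reference_age)
            )
        if np.any(~np.isfinite(out)):
            raise ValueError("trend not evaluable over the simulated age span")
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("trend")  # callables are not serializable; default trend implied
        return d


@dataclass
class VisitSchedule:
    """Visit design: roughly equispaced observations over a follow-up window.

    Baseline is always at time 0; the remaining visits are equispaced over
    ``[0, duration]`` with optional Gaussian jitter truncated so visits
    never reorder.
    """

    duration: float
    n_observations: int
    jitter_sd: float = 0.0
    equispaced: bool = True

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_observations < 2:
            raise ValueError("a schedule needs at least 2 observations")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    def nominal_times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_observations)

    def draw_times(self, rng: np.random.Generator, n_subjects: int) -> np.ndarray:
        """(n_subjects, n_observations) visit times; baseline fixed at 0."""
        base = np.tile(self.nominal_times(), (n_subjects, 1))
        if self.jitter_sd > 0:
            spacing = self.duration / (self.n_observations - 1)
            jit = rng.normal(0.0, self.jitter_sd, size=base.shape)
            # truncate to +-49% of the nominal spacing: ordering is preserved
            lim = 0.49 * spacing
            jit = np.clip(jit, -lim, lim)
            jit[:, 0] = 0.0  # baseline anchored
            base = base + jit
        return base


def _draw_slope_deviations(
    rng: np.random.Generator, truth: GroundTruth, n: int, mean: float = 0.0
) -> np.ndarray:
    """Subject slope deviations (percent/yr), mean/SD fixed regardless of skew."""
    if truth.slope_skewness == 0.0 or truth.slope_sd == 0.0:
        return rng.normal(mean, truth.slope_sd, size=n)
    g = truth.slope_skewness
    b = np.sqrt(2.0 / np.pi)
    c = abs(g) ** (2.0 / 3.0)
    delta = np.sign(g) * np.sqrt(
        (np.pi / 2.0) * c / (c + ((4.0 - np.pi) / 2.0) ** (2.0 / 3.0))
    )
    a = delta / np.sqrt(1.0 - delta**2)
    omega = truth.slope_sd / np.sqrt(1.0 - b**2 * delta**2)
    xi = mean - omega * b * delta
    return stats.skewnorm.rvs(a, loc=xi, scale=omega, size=n, random_state=rng)


def generate_cohort(
    truth: GroundTruth,
    n_subjects: int,
    schedule: VisitSchedule,
    n_sites: int = 1,
    cohort_id: str = "SIM",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a longitudinal cohort for one feature.

    Each subject's noiseless trajectory follows the population trajectory
    along their own aging, modulated by a subject-specific linear percent
    deviation: ``v0(t) = trend(age + t) * (1 + dev * t / 100)``, scaled by
    subject/site/sex multipliers; every observation then carries
    multiplicative noise with SD ``noise_sd`` percent. With the default
    linear trend the subjects' true percent slopes are (to first order)
    ``mean_yearly_change + dev``, i.e. normal with mean delta and SD
    sigma_s. When an explicit nonlinear ``trend`` is supplied, the trend —
    not ``mean_yearly_change`` — sets the population mean change.

    Returns
    -------
    cohort : DataFrame
        Long-format table with columns :data:`COHORT_COLUMNS`; one row per
        subject x visit, time 0-based per subject.
    subjects : DataFrame
        Per-subject ground truth: ``true_slope_pct`` is the exact
        noiseless OLS slope in percent of the subject's noiseless mean —
        the recovery target for the estimation pipeline —
        ``slope_deviation_pct`` the drawn deviation from the population
        trajectory, plus ``base_value``, ``age_baseline``, ``site_id``,
        ``sex``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)

    ages = rng.uniform(truth.age_range[0], truth.age_range[1], n_subjects)
    sex = np.where(rng.integers(0, 2, n_subjects) == 1, "M", "F")
    site_idx = rng.integers(0, n_sites, n_subjects)
    site_offsets = rng.normal(0.0, truth.site_offset_sd, n_sites)
    intercept_pct = rng.normal(0.0, truth.intercept_sd, n_subjects)
    deviations = _draw_slope_deviations(rng, truth, n_subjects)

    mult = (
        (1.0 + intercept_pct / 100.0)
        * (1.0 + site_offsets[site_idx] / 100.0)
        * (1.0 + truth.sex_effect_pct / 100.0 * (sex == "M"))
    )
    times = schedule.draw_times(rng, n_subjects)  # (n_subjects, n_obs)
    traj = truth.trend_values(ages[:, None] + times)
    noiseless = mult[:, None] * traj * (1.0 + deviations[:, None] * times / 100.0)
    if np.any(noiseless <= 0):
        raise ValueError("generative values must stay positive; "
                         "check trend/intercept_sd/slope_sd over the age span")
    noise = rng.normal(0.0, truth.noise_sd, size=times.shape)
    values = noiseless * (1.0 + noise / 100.0)

    # exact noiseless OLS percent slope: the recovery target
    tc = times - times.mean(axis=1, keepdims=True)
    slope_units = (tc * noiseless).sum(axis=1) / (tc * tc).sum(axis=1)
    true_slope_pct = 100.0 * slope_units / noiseless.mean(axis=1)
    base = mult * truth.trend_values(ages)

    n_obs = schedule.n_observations
    subject_ids = np.array([f"S{i:05d}" for i in range(n_subjects)])
    cohort = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_obs),
            "cohort_id": cohort_id,
            "site_id": np.repeat([f"site{s:02d}" for s in site_idx], n_obs),
            "sex": np.repeat(sex, n_obs),
            "age_baseline": np.repeat(ages, n_obs),
            "time_years": times.ravel(),
            "feature": truth.feature_id,
            "value": values.ravel(),
        }
    )[COHORT_COLUMNS]

    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "true_slope_pct": true_slope_pct,
            "slope_deviation_pct": deviations,
            "base_value": base,
            "age_baseline": ages,
            "site_id": [f"site{s:02d}" for s in site_idx],
            "sex": sex,
        }
    )
    return cohort, subjects


def generate_test_retest(
    truth: GroundTruth,
    n_subjects: int,
    n_sessions: int = 2,
    cohort_id: str = "SIM-TRT",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a short-interval repeated-measures set (no true change).

    All sessions share the subject's true value; only cross-sectional
    measurement noise differs between sessions, as in test-retest designs
    performed days to weeks apart.
    """
    if n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)

    ages = rng.uniform(truth.age_range[0], truth.age_range[1], n_subjects)
    intercept_pct = rng.normal(0.0, truth.intercept_sd, n_subjects)
    base = truth.trend_values(ages) * (1.0 + intercept_pct / 100.0)
    noise = rng.normal(0.0, truth.noise_sd, size=(n_subjects, n_sessions))
    values = base[:, None] * (1.0 + noise / 100.0)

    subject_ids = np.array([f"T{i:05d}" for i in range(n_subjects)])
    return pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, n_sessions),
            "cohort_id": cohort_id,
            "feature": truth.feature_id,
            "session": np.tile(np.arange(1, n_sessions + 1), n_subjects),
            "value": values.ravel(),
        }
    )[RETEST_COLUMNS]


def apply_attrition(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    mode: str = "random",
    seed: int = 0,
    true_slopes: Optional[pd.DataFrame] = None,
    coef: float = 1.0,
) -> pd.DataFrame:
    """Drop visits after baseline with a per-visit dropout hazard.

    Dropout is monotone: once a subject misses a visit, all later visits
    are lost. In ``"slope_dependent"`` mode the per-visit hazard follows a
    logistic link on the standardized true slope, so steeper decliners
    (more negative slopes) drop out more — the mechanism behind attrition
    bias, which homogenizes the retained sample and deflates the estimated
    slope SD.

    Parameters
    ----------
    true_slopes : DataFrame, required for slope_dependent mode
        The ``subjects`` table returned by :func:`generate_cohort`
        (columns ``subject_id``, ``true_slope_pct``).
    coef : float
        Logistic coefficient on the standardized (negated) slope;
        positive values penalize decliners.
    """
    if mode not in ("random", "slope_dependent"):
        raise ValueError(f"unknown attrition mode: {mode!r}")
    h = truth.attrition_per_visit
    if h == 0.0:
        return cohort.copy()

    rng = np.random.default_rng(seed)
    out = cohort.sort_values(["subject_id", "time_years"], kind="mergesort").copy()
    visit_idx = out.groupby("subject_id", sort=False).cumcount().to_numpy()
    subj = out["subject_id"].to_numpy()

    uniq, first_pos = np.unique(subj, return_index=True)
    if mode == "random" or h == 1.0:
        hazard = pd.Series(h, index=uniq)
    else:
        if true_slopes is None:
            raise ValueError("slope_dependent attrition requires true_slopes")
        s = true_slopes.set_index("subject_id")["true_slope_pct"].reindex(uniq)
        if s.isna().any():
            raise ValueError("true_slopes missing subjects present in cohort")
        z = (s - s.mean()) / s.std(ddof=1)
        hazard = pd.Series(expit(logit(h) - coef * z.to_numpy()), index=uniq)

    max_extra = int(visit_idx.max())
    u = rng.uniform(size=(len(uniq), max_extra))
    # survive[i, j] : subject i still enrolled at post-baseline visit j+1
    survive = np.cumprod(u >= hazard.to_numpy()[:, None], axis=1).astype(bool)
    pos = {sid: i for i, sid in enumerate(uniq)}
    row_subj = np.fromiter((pos[s_] for s_ in subj), dtype=int, count=len(subj))
    keep = visit_idx == 0
    extra = visit_idx >= 1
    keep[extra] = survive[row_subj[extra], visit_idx[extra] - 1]
    return out.loc[keep].reset_index(drop=True)


def write_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar with the generative parameters."""
    import json

    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
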