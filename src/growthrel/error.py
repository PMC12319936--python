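"""Cross-sectional measurement error from repeated-measures designs.

Two estimators of the per-measurement error, both expressed in percent of
the subject's mean value:

* test-retest (two sessions): ``|x1 - x2| / (0.5 (x1 + x2)) * 100``
* densely sampled (>= 2 sessions): coefficient of variation,
  ``sd / mean * 100``

Subjects are screened for extreme outliers (> 5 scaled MADs), estimates are
averaged within cohort, and the mean across cohorts is the parameter of
interest. Both statistics are *biased* estimators of a normal noise SD —
the test-retest statistic by a factor 2/sqrt(pi), the CV by c4(n) — and
:func:`calibrate_error_sd` converts either to a consistent SD when asked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: consistency factor of the paired absolute-difference statistic: E|N(0, 2s^2)| = 2s/sqrt(pi)
EQ_TEST_RETEST_FACTOR = 2.0 / np.sqrt(np.pi)

#: MAD -> SD scaling factor for normal data
MAD_SCALE = 1.4826


def c4(n: int) -> float:
    """Small-sample mean of a normal sample SD: E[s] = c4(n) * sigma."""
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2.0) - gammaln((n - 1) / 2.0))


@dataclass
class ErrorEstimate:
    """Pooled measurement-error estimate for one feature (percent of mean)."""

    feature_id: str
    sigma_epsilon: float
    per_cohort: list = field(default_factory=list)  # (cohort_id, mean percent)
    n_subjects_used: int = 0
    n_outliers_removed: int = 0
    design_kind: str = "test_retest"
    calibrated: bool = False

    def __post_init__(self) -> None:
        if np.isfinite(self.sigma_epsilon) and self.sigma_epsilon < 0:
            raise ValueError("sigma_epsilon must be non-negative")


def error_test_retest(x1: float, x2: float) -> float:
    """Percent error from a session pair: |x1-x2| / mean * 100.

    Symmetric in its arguments. Pairs with a zero or sign-mixed mean have
    no meaningful percent scale; they are flagged invalid (NaN returned,
    warning logged) so the caller can exclude the subject.
    """
    m = 0.5 * (x1 + x2)
    if m <= 0 or x1 * x2 < 0:
        logger.warning(
            "invalid test-retest pair (%.4g, %.4g): zero/negative or sign-mixed mean", x1, x2
        )
        return np.nan
    return abs(x1 - x2) / m * 100.0


def error_dense(values) -> float:
    """Percent error from a dense series: coefficient of variation * 100."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("error_dense needs at least 2 values")
    m = v.mean()
    if m <= 0:
        logger.warning("invalid dense series: zero or negative mean %.4g", m)
        return np.nan
    return v.std(ddof=1) / m * 100.0


def mad_screen(values, threshold: float = 5.0, center: str = "median") -> np.ndarray:
    """Indices of values within ``threshold`` scaled MADs of the center.

    The MAD is multiplied by 1.4826 so the threshold is in SD-equivalents.
    When the MAD is zero but values differ (a majority of exact ties),
    any nonzero deviation is infinitely many scaled MADs from the center,
    so all off-center values are flagged; a warning is logged because
    such data usually indicates an upstream problem.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("mad_screen needs at least 3 values")
    if center == "median":
        c = np.median(v)
    elif center == "mean":
        c = v.mean()
    else:
        raise ValueError(f"unknown center: {center!r}")
    dev = np.abs(v - c)
    mad = np.median(dev)
    if mad == 0.0:
        if np.all(v == v[0]):
            return np.arange(v.size)
        logger.warning(
            "MAD = 0 with non-identical values; flagging all off-center values"
        )
        return np.flatnonzero(dev == 0.0)
    return np.flatnonzero(dev / (mad * MAD_SCALE) <= threshold)


def pool_error(per_subject: pd.DataFrame) -> tuple[float, list]:
    """Cohort-balanced pooling: subject mean within cohort, then mean of cohorts.

    ``per_subject`` needs columns ``cohort_id`` and ``value`` (percent).
    Cohorts are weighted equally regardless of their size.
    """
    if len(per_subject) == 0:
        raise ValueError("pool_error requires at least one subject")
    cohort_means = per_subject.groupby("cohort_id")["value"].mean()
    return float(cohort_means.mean()), list(cohort_means.items())


def calibrate_error_sd(
    estimate: float,
    design_kind: str,
    n_sessions: int = 2,
    calibrate: bool = True,
) -> float:
    """Convert a raw error statistic into a normal-consistent SD.

    Divides test-retest estimates by 2/sqrt(pi) ~ 1.1284 and dense (CV)
    estimates by c4(n_sessions). With ``calibrate=False`` the input is
    returned unchanged (the raw statistic is the conventional reporting
    scale for the error slot of the reliability formula).
    """
    if design_kind not in ("test_retest", "dense"):
        raise ValueError(f"unknown design_kind: {design_kind!r}")
    if not calibrate:
        return estimate
    if design_kind == "test_retest":
        return estimate / EQ_TEST_RETEST_FACTOR
    if n_sessions < 2:
        raise ValueError("dense designs need n_sessions >= 2")
    return estimate / c4(n_sessions)


def estimate_error(
    rms: pd.DataFrame,
    design_kind: str = "test_retest",
    mad_threshold: float = 5.0,
    calibrate: bool = False,
    center: str = "median",
) -> dict[str, ErrorEstimate]:
    """Full error-estimation pipeline on a repeated-measures table.

    Parameters
    ----------
    rms : DataFrame
        Long table with columns ``subject_id, cohort_id, feature, session,
        value``.
    design_kind : {"test_retest", "dense"}
        Test-retest uses the first two sessions per subject (the pairwise
        statistic); dense uses all sessions (CV).
    calibrate : bool
        Apply the consistency factors of :func:`calibrate_error_sd`;
        default keeps the raw statistic.

    Returns
    -------
    dict mapping feature id to :class:`ErrorEstimate`.

    Notes
    -----
    Outlier screening (``> mad_threshold`` scaled MADs) is applied per
    cohort and feature: to between-subject averages for test-retest
    designs (whole subjects removed) and to within-subject deviations for
    dense designs (single sessions removed; subjects left with < 2
    sessions are dropped).
    """
    if design_kind not in ("test_retest", "dense"):
        raise ValueError(f"unknown design_kind: {design_kind!r}")
    required = {"subject_id", "cohort_id", "feature", "session", "value"}
    missing = required - set(rms.columns)
    if missing:
        raise ValueError(f"repeated-measures table missing columns: {sorted(missing)}")

    out: dict[str, ErrorEstimate] = {}
    for feature, df in rms.groupby("feature", sort=True):
        rows = []
        n_out = 0
        mean_sessions = []
        for cohort, cdf in df.groupby("cohort_id", sort=True):
            cdf = cdf.sort_values(["subject_id", "session"], kind="mergesort")
            if design_kind == "test_retest":
                sub_means = cdf.groupby("subject_id")["value"].mean()
                if len(sub_means) >= 3:
                    keep = mad_screen(sub_means.to_numpy(), mad_threshold, center)
                    kept_ids = sub_means.index.to_numpy()[keep]
                    n_out += len(sub_means) - len(keep)
                else:
                    kept_ids = sub_means.index.to_numpy()
                cdf = cdf[cdf["subject_id"].isin(kept_ids)]
                # pairwise statistic: first two sessions by session index
                first_two = cdf.groupby("subject_id").head(2)
                for sid, sdf in first_two.groupby("subject_id"):
                    if len(sdf) < 2:
                        continue
                    v = sdf["value"].to_numpy()
                    e = error_test_retest(v[0], v[1])
                    if np.isfinite(e):
                        rows.append((cohort, sid, e))
                mean_sessions.append(2)
            else:
                dev = cdf["value"] - cdf.groupby("subject_id")["value"].transform("mean")
                if len(dev) >= 3:
                    keep = mad_screen(dev.to_numpy(), mad_threshold, center)
                    n_out += len(dev) - len(keep)
                    cdf = cdf.iloc[keep]
                counts = cdf.groupby("subject_id")["value"].transform("count")
                cdf = cdf[counts >= 2]
                for sid, sdf in cdf.groupby("subject_id"):
                    e = error_dense(sdf["value"].to_numpy())
                    if np.isfinite(e):
                        rows.append((cohort, sid, e))
                        mean_sessions.append(len(sdf))
        if not rows:
            raise ValueError(f"no valid subjects for feature {feature!r}")
        per_subject = pd.DataFrame(rows, columns=["cohort_id", "subject_id", "value"])
        pooled, per_cohort = pool_error(per_subject)
        n_ses = int(round(np.mean(mean_sessions))) if mean_sessions else 2
        sigma = calibrate_error_sd(pooled, design_kind, n_ses, calibrate=calibrate)
        out[feature] = ErrorEstimate(
            feature_id=feature,
            sigma_epsilon=float(sigma),
            per_cohort=per_cohort,
            n_subjects_used=per_subject["subject_id"].nunique(),
            n_outliers_removed=int(n_out),
            design_kind=design_kind,
            calibrated=calibrate,
        )
    return out


def error_table(estimates: dict[str, ErrorEstimate]) -> pd.DataFrame:
    """Flatten :func:`estimate_error` output to the CSV reporting schema."""
    return pd.DataFrame(
        [
            {
                "feature": e.feature_id,
                "sigma_epsilon_pct": e.sigma_epsilon,
                "n_used": e.n_subjects_used,
                "n_outliers": e.n_outliers_removed,
                "design_kind": e.design_kind,
                "calibrated": e.calibrated,
            }
            for e in estimates.values()
        ]
    )
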