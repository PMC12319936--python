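"""Per-subject change rates and their between-subject dispersion.

The pipeline mirrors standard practice for multi-cohort morphometry:

1. remove the population age trend (smooth spline), a sex effect, and
   cohort/site mean offsets from the raw values (:func:`detrend`);
2. regress each subject's residuals on time from baseline to get an
   individual yearly slope (:func:`subject_slope`), converted to percent
   of the subject's mean observed value (:func:`to_percent`);
3. restrict to well-observed subjects (follow-up > 4 years, >= 4
   observations by default), screen extreme slopes (> 5 scaled MADs), and
   take the sample SD of the remainder as the slope-dispersion parameter
   sigma_s (:func:`slope_dispersion`).

Subject-level intercepts are deliberately not removed in step 1: the
within-subject regression of step 2 is invariant to any per-subject
constant, so a fixed-effects spline plus per-subject OLS recovers the
same slopes a subject-level random-intercept model would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix

from .error import mad_screen

logger = logging.getLogger(__name__)


@dataclass
class SlopeDispersion:
    """Between-subject SD of yearly percent change for one feature."""

    feature_id: str
    slope_sd: float
    n_subjects_used: int
    n_outliers_removed: int
    selection: tuple  # (min followup years, min observations)

    def __post_init__(self) -> None:
        if self.slope_sd < 0:
            raise ValueError("slope_sd must be non-negative")


class TrendFit:
    """Fixed-effect spline fit of value ~ s(age) + sex + cohort + site.

    Cohort, site and sex indicator columns are mean-centered before the
    fit, so ``predict`` returns the population mean trajectory at the
    sample-average covariate composition.
    """

    def __init__(self, coef, design_info, slices, age_range, feature_id):
        self._coef = coef
        self._design_info = design_info
        self._slices = slices
        self.age_range = age_range
        self.feature_id = feature_id

    def predict(self, ages) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        lo, hi = self.age_range
        if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
            raise ValueError(
                f"ages outside fitted support [{lo:.2f}, {hi:.2f}]"
            )
        (basis,) = build_design_matrices([self._design_info], {"age": ages})
        i0, i1 = self._slices["spline"]
        return self._coef[0] + np.asarray(basis) @ self._coef[i0:i1]


def detrend(
    cohort: pd.DataFrame, spline_df: int = 10
) -> tuple[pd.DataFrame, TrendFit]:
    """Residualize a cohort against age trend, sex, cohort and site.

    Returns the cohort with a ``residual`` column appended and the fitted
    :class:`TrendFit`. Requires columns ``age_baseline``, ``time_years``,
    ``sex``, ``cohort_id``, ``site_id``, ``value``; a single feature.
    """
    required = {"age_baseline", "time_years", "sex", "cohort_id", "site_id", "value"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort missing columns: {sorted(missing)}")
    n_subj = cohort["subject_id"].nunique() if "subject_id" in cohort else len(cohort)
    if n_subj < 30:
        logger.warning("detrend on %d subjects; trend estimate may be unstable", n_subj)

    age = (cohort["age_baseline"] + cohort["time_years"]).to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; cannot fit an age trend")
    y = cohort["value"].to_numpy(dtype=float)

    df_eff = min(spline_df, max(4, len(np.unique(age)) - 1))
    basis = dmatrix(
        f"bs(age, df={df_eff}, degree=3) - 1", {"age": age}, return_type="matrix"
    )
    design_info = basis.design_info
    basis = np.asarray(basis)

    def centered_dummies(series: pd.Series) -> np.ndarray:
        d = pd.get_dummies(series.astype(str), drop_first=True, dtype=float)
        if d.shape[1] == 0:
            return np.empty((len(series), 0))
        return (d - d.mean()).to_numpy()

    sex_c = centered_dummies(cohort["sex"])
    cohort_c = centered_dummies(cohort["cohort_id"])
    site_c = centered_dummies(cohort["site_id"])

    X = np.column_stack([np.ones(len(y)), basis, sex_c, cohort_c, site_c])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef

    slices = {"spline": (1, 1 + basis.shape[1])}
    fit = TrendFit(
        coef=coef,
        design_info=design_info,
        slices=slices,
        age_range=(float(age.min()), float(age.max())),
        feature_id=str(cohort["feature"].iloc[0]) if "feature" in cohort else "",
    )
    out = cohort.copy()
    out["residual"] = resid
    return out, fit


def subject_slope(times, residuals, observed=None) -> tuple[float, float]:
    """OLS slope of residuals on time, plus the subject's mean raw value.

    ``observed`` are the pre-residualization values used for the percent
    conversion downstream; when omitted the mean of ``residuals`` is
    returned in its place.
    """
    t = np.asarray(times, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("subject_slope needs >= 2 distinct times")
    tc = t - t.mean()
    slope = float(tc @ (r - r.mean()) / (tc @ tc))
    mean_value = float(np.mean(observed if observed is not None else r))
    return slope, mean_value


def to_percent(slope: float, mean_value: float) -> float:
    """Yearly change in percent of the subject's mean value."""
    if mean_value == 0:
        raise ValueError("cannot convert to percent with a zero mean value")
    if mean_value < 0:
        logger.warning(
            "negative mean value %.4g in percent conversion; "
            "check upstream processing", mean_value
        )
    return 100.0 * slope / mean_value


def compute_slope_table(
    cohort: pd.DataFrame, detrended: bool = True, spline_df: int = 10
) -> pd.DataFrame:
    """Per-subject slope table for every feature in a cohort.

    When ``detrended`` is True each feature is residualized with
    :func:`detrend` first; otherwise raw values are regressed on time
    directly (appropriate for simulations with no population trend).

    Returns one row per subject x feature with columns ``subject_id,
    cohort_id, feature, slope_pct, slope_se_pct, n_obs, followup,
    mean_value`` — slopes and their standard errors in percent of the
    subject's mean observed value per year; the SE is NaN below 3
    observations (zero residual degrees of freedom).
    """
    parts = []
    for feature, fdf in cohort.groupby("feature", sort=True):
        if detrended:
            fdf, _ = detrend(fdf, spline_df=spline_df)
            ycol = "residual"
        else:
            ycol = "value"
        parts.append(_slope_table_one(fdf, ycol, feature))
    return pd.concat(parts, ignore_index=True)


def _slope_table_one(df: pd.DataFrame, ycol: str, feature: str) -> pd.DataFrame:
    g = df.groupby("subject_id", sort=True)
    t = df["time_years"].to_numpy(dtype=float)
    y = df[ycol].to_numpy(dtype=float)
    raw = df["value"].to_numpy(dtype=float)

    agg = pd.DataFrame(
        {
            "n": g.size(),
            "st": g["time_years"].sum(),
            "cohort_id": g["cohort_id"].first(),
        }
    )
    tmp = df.assign(_t2=t * t, _ty=t * y, _y=y, _y2=y * y, _raw=raw)
    gg = tmp.groupby("subject_id", sort=True)
    agg["st2"] = gg["_t2"].sum()
    agg["sy"] = gg["_y"].sum()
    agg["sty"] = gg["_ty"].sum()
    agg["sy2"] = gg["_y2"].sum()
    agg["mean_value"] = gg["_raw"].mean()
    agg["followup"] = gg["time_years"].max() - gg["time_years"].min()

    n = agg["n"].to_numpy(dtype=float)
    sst = agg["st2"] - agg["st"] ** 2 / n
    valid = (n >= 2) & (sst > 0)
    agg = agg[valid]
    n = n[valid.to_numpy()]
    sst = sst[valid]

    slope = (agg["sty"] - agg["st"] * agg["sy"] / n) / sst
    syy = agg["sy2"] - agg["sy"] ** 2 / n
    rss = np.maximum(syy - slope**2 * sst, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / (n - 2) / sst)
    se = np.where(n >= 3, se, np.nan)

    mean_value = agg["mean_value"].to_numpy()
    if np.any(mean_value < 0):
        logger.warning(
            "%d subjects with negative mean values in feature %s",
            int((mean_value < 0).sum()), feature,
        )
    out = pd.DataFrame(
        {
            "subject_id": agg.index,
            "cohort_id": agg["cohort_id"].to_numpy(),
            "feature": feature,
            "slope_pct": 100.0 * slope.to_numpy() / mean_value,
            "slope_se_pct": 100.0 * se / mean_value,
            "n_obs": n.astype(int),
            "followup": agg["followup"].to_numpy(),
            "mean_value": mean_value,
        }
    )
    return out.reset_index(drop=True)


def slope_dispersion(
    slopes: pd.DataFrame,
    min_followup: float = 4.0,
    min_obs: int = 4,
    mad_threshold: float = 5.0,
    center: str = "median",
) -> SlopeDispersion:
    """Sample SD of percent slopes among well-observed subjects.

    Selection keeps subjects followed strictly longer than
    ``min_followup`` years with at least ``min_obs`` observations, then
    drops slopes more than ``mad_threshold`` scaled MADs from the center
    (median by default). Requires a single-feature slope table.
    """
    features = slopes["feature"].unique()
    if len(features) != 1:
        raise ValueError("slope_dispersion expects a single feature; "
                         "group by feature and call per feature")
    sel = slopes[(slopes["followup"] > min_followup) & (slopes["n_obs"] >= min_obs)]
    if len(sel) == 0:
        raise ValueError("no subjects pass the follow-up/observation selection")
    if len(sel) < 10:
        logger.warning("only %d subjects pass selection; slope SD unstable", len(sel))

    vals = sel["slope_pct"].to_numpy(dtype=float)
    if len(vals) >= 3:
        keep = mad_screen(vals, threshold=mad_threshold, center=center)
    else:
        keep = np.arange(len(vals))
    n_out = len(vals) - len(keep)
    if n_out:
        logger.info("slope_dispersion: screened %d outlier slope(s)", n_out)
    kept = vals[keep]
    sd = float(np.std(kept, ddof=1)) if len(kept) >= 2 else 0.0
    return SlopeDispersion(
        feature_id=str(features[0]),
        slope_sd=sd,
        n_subjects_used=int(len(kept)),
        n_outliers_removed=int(n_out),
        selection=(min_followup, min_obs),
    )


def mean_yearly_change(
    trend: TrendFit, age_lo: float = 60.0, age_hi: float = 80.0
) -> float:
    """Average derivative of the fitted trend over an age window, in percent.

    The average first derivative over ``[age_lo, age_hi]`` equals the
    endpoint difference divided by the window width; it is expressed in
    percent of the trend value at the window midpoint per year.
    """
    if age_hi <= age_lo:
        raise ValueError("age_hi must exceed age_lo")
    lo, hi = trend.age_range
    if age_lo < lo - 1e-9 or age_hi > hi + 1e-9:
        raise ValueError(
            f"window [{age_lo}, {age_hi}] outside fitted support [{lo:.2f}, {hi:.2f}]"
        )
    f_lo, f_hi = trend.predict([age_lo, age_hi])
    mid = float(trend.predict([(age_lo + age_hi) / 2.0])[0])
    if mid == 0:
        raise ValueError("trend value at window midpoint is zero")
    deriv = (f_hi - f_lo) / (age_hi - age_lo)
    return 100.0 * deriv / mid
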