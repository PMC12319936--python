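"""Empirical reliability from per-subject slope standard errors.

An independent route to the same reliability quantity: instead of deriving
the error variance of the slope analytically (sigma_eps^2 / SST), estimate
it from the data — each subject's OLS slope comes with a standard error,
and a log-link regression of those SEs on follow-up duration and number of
observations (with cohort offsets) predicts the slope-error SD of any
design cell. Holding the slope SD fixed,

    icc_empirical = slope_sd^2 / (slope_sd^2 + predicted_se^2).

OLS slope SEs slightly underestimate the true error SD in small samples
(the sample residual SD is biased low); :func:`correct_se` removes that
bias with the exact normal-theory factor 1/c4(n-1), where n-2 is the
residual degrees of freedom of a subject with n observations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .error import c4

logger = logging.getLogger(__name__)


def slope_se(times, values, mean_value: float | None = None) -> float:
    """Standard error of the OLS slope of ``values`` on ``times``.

    sqrt(RSS / (n-2) / SST); undefined below 3 observations. When
    ``mean_value`` is given the SE is converted to percent of it.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 3 or np.unique(t).size < 3:
        raise ValueError("slope_se needs >= 3 distinct times")
    tc = t - t.mean()
    sst = float(tc @ tc)
    slope = float(tc @ (y - y.mean()) / sst)
    resid = (y - y.mean()) - slope * tc
    rss = float(resid @ resid)
    se = np.sqrt(rss / (t.size - 2) / sst)
    if mean_value is not None:
        if mean_value == 0:
            raise ValueError("cannot convert to percent of a zero mean")
        se = 100.0 * se / abs(mean_value)
    return float(se)


def _design_basis(followup: np.ndarray, n_obs: np.ndarray) -> np.ndarray:
    """Log-scale basis: log(t) and the log of the equispaced SST n-factor.

    For equispaced designs log SE = const - log t - 0.5 log(n(n+1)/(n-1))
    + log(12)/2, so this basis spans the theoretical surface exactly.
    """
    n = np.asarray(n_obs, dtype=float)
    return np.column_stack(
        [np.log(np.asarray(followup, dtype=float)), np.log(n * (n + 1) / (n - 1))]
    )


@dataclass
class SlopeSEModel:
    """Fitted log-link model of slope SEs over design variables."""

    kind: str                    # "mixed" | "fixed" | "plain" | "cell_mean"
    params: np.ndarray           # intercept + basis coefficients
    n_cohorts: int
    feature_id: str = ""
    diagnostics: dict = field(default_factory=dict)

    def predict(self, followup, n_obs) -> np.ndarray:
        """Population-level predicted SE (percent/yr); always positive."""
        followup = np.atleast_1d(np.asarray(followup, dtype=float))
        n_obs = np.atleast_1d(np.asarray(n_obs, dtype=float))
        if self.kind == "cell_mean":
            return np.full(np.broadcast(followup, n_obs).shape, self.params[0])
        X = _design_basis(followup, n_obs)
        return np.exp(self.params[0] + X @ self.params[1:3])


def fit_se_model(slopes: pd.DataFrame) -> SlopeSEModel:
    """Fit the slope-SE surface from a slope table.

    Needs columns ``slope_se_pct, followup, n_obs, cohort_id``; rows with
    undefined SEs (n_obs < 3) or non-positive SEs are dropped. Cohort
    handling degrades gracefully with the number of cohorts: random
    intercepts (>= 5 cohorts), fixed dummies (2-4), none (1).
    """
    df = slopes.dropna(subset=["slope_se_pct"])
    df = df[(df["slope_se_pct"] > 0) & (df["n_obs"] >= 3) & (df["followup"] > 0)]
    if len(df) == 0:
        raise ValueError("no usable slope SEs to fit")
    feature = str(df["feature"].iloc[0]) if "feature" in df else ""

    cells = df.groupby(["followup", "n_obs"]).ngroups
    if cells < 3:
        if cells == 1:
            logger.warning("single design cell; returning the cell-mean SE model")
            return SlopeSEModel(
                kind="cell_mean",
                params=np.array([df["slope_se_pct"].mean()]),
                n_cohorts=df["cohort_id"].nunique(),
                feature_id=feature,
            )
        raise ValueError("fit_se_model needs >= 3 distinct (followup, n_obs) cells")

    y = np.log(df["slope_se_pct"].to_numpy())
    X = _design_basis(df["followup"].to_numpy(), df["n_obs"].to_numpy())
    n_cohorts = df["cohort_id"].nunique()

    if n_cohorts >= 5:
        exog = sm.add_constant(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, exog, groups=df["cohort_id"].to_numpy()).fit(reml=True)
        params = np.asarray(res.fe_params)
        diagnostics = {"kind": "mixed", "converged": bool(res.converged)}
        kind = "mixed"
    elif n_cohorts >= 2:
        dummies = pd.get_dummies(df["cohort_id"].astype(str), drop_first=True, dtype=float)
        dummies = (dummies - dummies.mean()).to_numpy()  # centered: intercept = population level
        exog = sm.add_constant(np.column_stack([X, dummies]))
        res = sm.OLS(y, exog).fit()
        params = np.asarray(res.params[:3])
        diagnostics = {"kind": "fixed", "r2": float(res.rsquared)}
        kind = "fixed"
    else:
        exog = sm.add_constant(X)
        res = sm.OLS(y, exog).fit()
        params = np.asarray(res.params)
        diagnostics = {"kind": "plain", "r2": float(res.rsquared)}
        kind = "plain"

    return SlopeSEModel(
        kind=kind,
        params=params,
        n_cohorts=n_cohorts,
        feature_id=feature,
        diagnostics=diagnostics,
    )


def correction_factor(n_obs: int) -> float:
    """Small-sample inflation for an OLS slope SE with ``n_obs`` points.

    The residual SD with nu = n-2 degrees of freedom has mean
    c4(nu+1) * sigma, so dividing a mean SE by c4(n_obs - 1) makes it
    unbiased for the true slope-error SD. The factor decreases to 1 as
    n grows.
    """
    if n_obs < 3:
        raise ValueError("SE correction needs n_obs >= 3")
    return 1.0 / c4(n_obs - 1)


def correct_se(se, n_obs) -> np.ndarray:
    """Apply the small-sample SE correction; never decreases the SE."""
    se = np.asarray(se, dtype=float)
    n_obs = np.atleast_1d(np.asarray(n_obs))
    factors = np.array([correction_factor(int(n)) for n in n_obs.ravel()]).reshape(
        n_obs.shape
    )
    return se * factors


def empirical_icc(slope_sd: float, predicted_se: float) -> float:
    """Reliability with the error SD taken from the empirical SE model."""
    if slope_sd < 0 or predicted_se < 0:
        raise ValueError("slope_sd and predicted_se must be non-negative")
    if slope_sd == 0 and predicted_se == 0:
        raise ValueError("slope_sd and predicted_se cannot both be zero")
    return slope_sd**2 / (slope_sd**2 + predicted_se**2)


def empirical_surface(
    model: SlopeSEModel,
    slope_sd: float,
    durations,
    n_list,
    correct: bool = True,
    feature_id: str | None = None,
) -> pd.DataFrame:
    """Empirical reliability over a design grid, analytic-surface format.

    Columns ``feature, duration, n_obs, icc, slope_error_sd`` — directly
    differencable against :func:`growthrel.reliability.reliability_surface`.
    """
    rows = []
    fid = feature_id if feature_id is not None else model.feature_id
    for t in durations:
        for n in n_list:
            se = float(model.predict(t, n)[0])
            if correct:
                se = float(correct_se(se, n)[0])
            rows.append(
                {
                    "feature": fid,
                    "duration": float(t),
                    "n_obs": int(n),
                    "icc": empirical_icc(slope_sd, se),
                    "slope_error_sd": se,
                }
            )
    return pd.DataFrame(rows)
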