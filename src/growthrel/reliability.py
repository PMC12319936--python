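"""Closed-form reliability of individual change rates (growth-rate reliability).

Under the linear-trajectory model the error variance of a subject's OLS
slope is sigma_eps^2 / SST, where SST = sum_j (t_j - tbar)^2 measures how
widely the visit times are spread. Reliability of the slope — the
intraclass correlation between true and observed rates of change — is then

    rho = sigma_s^2 / (sigma_s^2 + sigma_eps^2 / SST),

with sigma_s the between-subject SD of true yearly change (percent/yr)
and sigma_eps the cross-sectional measurement error (percent of mean).
For n equispaced observations over a total duration t,
SST = t^2 n (n+1) / (12 (n-1)), which makes follow-up duration the
dominant design lever (SST grows with t^2) and the number of
observations a comparatively minor one.

Two-way agreement ICCs (single-rater ICC(2,1) and mean-of-k ICC(2,k))
are provided for comparing parameter sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DesignSpec:
    """Longitudinal design: total duration, number and timing of visits."""

    duration: float
    n_observations: int
    times: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_observations < 2:
            raise ValueError("n_observations must be >= 2")
        if self.times is not None:
            t = np.asarray(self.times, dtype=float)
            if len(t) != self.n_observations:
                raise ValueError("len(times) must equal n_observations")
            if np.any(np.diff(t) <= 0):
                raise ValueError("times must be strictly increasing")
            if abs((t.max() - t.min()) - self.duration) > 1e-9:
                raise ValueError("times span must equal duration")

    def sst(self) -> float:
        """Time leverage of the design (years^2); explicit times win."""
        if self.times is not None:
            return sst(self.times)
        return sst_equispaced(self.duration, self.n_observations)


@dataclass
class VarianceComponents:
    """The two parameters of growth-rate reliability for one feature."""

    feature_id: str
    slope_sd: float   # percent per year
    error_sd: float   # percent of mean
    source: str = ""

    def __post_init__(self) -> None:
        if self.slope_sd < 0 or self.error_sd < 0:
            raise ValueError("variance components must be non-negative")
        if self.slope_sd == 0 and self.error_sd == 0:
            raise ValueError("slope_sd and error_sd cannot both be zero")


@dataclass
class ReliabilityEstimate:
    """Reliability of yearly change for one feature under one design."""

    feature_id: str
    design: DesignSpec
    icc: float
    slope_error_sd: float  # percent per year: error_sd / sqrt(SST)
    sst: float


def sst(times) -> float:
    """Sum of squared deviations of visit times from their mean (years^2)."""
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("sst needs at least 2 times")
    out = float(np.sum((t - t.mean()) ** 2))
    if out == 0.0:
        logger.warning("degenerate design: all visit times identical (SST = 0)")
    return out


def sst_equispaced(t: float, n: int) -> float:
    """SST of n equispaced visits spanning t years: t^2 n (n+1) / (12 (n-1))."""
    if n < 2:
        raise ValueError("sst_equispaced needs n >= 2")
    if t <= 0:
        raise ValueError("duration must be positive")
    return t * t * n * (n + 1) / (12.0 * (n - 1))


def grr_reliability(vc: VarianceComponents, design: DesignSpec) -> ReliabilityEstimate:
    """Growth-rate reliability of a design given variance components."""
    s = design.sst()
    if s == 0.0:
        raise ValueError("design has zero SST; slope is not identified")
    slope_err = vc.error_sd / np.sqrt(s)
    icc = vc.slope_sd**2 / (vc.slope_sd**2 + slope_err**2)
    return ReliabilityEstimate(
        feature_id=vc.feature_id,
        design=design,
        icc=float(icc),
        slope_error_sd=float(slope_err),
        sst=float(s),
    )


def reliability_surface(
    components: Sequence[VarianceComponents],
    durations: Sequence[float],
    n_list: Sequence[int],
) -> pd.DataFrame:
    """Reliability over the full design grid, one row per feature x cell.

    Columns: ``feature, duration, n_obs, icc, slope_error_sd``.
    """
    if len(components) == 0 or len(durations) == 0 or len(n_list) == 0:
        raise ValueError("reliability_surface needs non-empty grids")
    rows = []
    for vc in components:
        for t in durations:
            for n in n_list:
                est = grr_reliability(vc, DesignSpec(t, n))
                rows.append(
                    {
                        "feature": vc.feature_id,
                        "duration": float(t),
                        "n_obs": int(n),
                        "icc": est.icc,
                        "slope_error_sd": est.slope_error_sd,
                    }
                )
    return pd.DataFrame(rows)


def summarize_surface(surface: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mean and SD of ICC across features, per design cell and marginally.

    Returns ``{"cell": ..., "by_duration": ..., "by_n_obs": ...}`` — the
    per-cell table averages across features only; the marginal tables
    additionally average over the other design axis.
    """
    cell = (
        surface.groupby(["duration", "n_obs"])["icc"]
        .agg(icc_mean="mean", icc_sd="std")
        .reset_index()
    )
    by_t = (
        surface.groupby("duration")["icc"]
        .agg(icc_mean="mean", icc_sd="std")
        .reset_index()
    )
    by_n = (
        surface.groupby("n_obs")["icc"]
        .agg(icc_mean="mean", icc_sd="std")
        .reset_index()
    )
    return {"cell": cell, "by_duration": by_t, "by_n_obs": by_n}


def icc_two_way(matrix) -> tuple[float, float]:
    """Two-way random-effects absolute-agreement ICCs of a targets x raters matrix.

    Returns ``(ICC(2,1), ICC(2,k))`` — agreement of a single rater
    (parameter source) and of the mean of all k raters.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("icc_two_way needs >= 3 targets and >= 2 raters")
    if np.any(~np.isfinite(m)):
        raise ValueError("icc_two_way does not accept missing cells")
    if np.allclose(m, m.flat[0]):
        raise ValueError("degenerate input: zero variance everywhere")

    import pingouin as pg

    n, k = m.shape
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": m.ravel(),
        }
    )
    res = pg.intraclass_corr(
        data=long, targets="target", raters="rater", ratings="score"
    ).set_index("Type")
    # two-way random effects, absolute agreement (Shrout-Fleiss 2,1 / 2,k);
    # pingouin labels these with McGraw-Wong names ICC(A,1) / ICC(A,k)
    single = res.loc["ICC(A,1)"] if "ICC(A,1)" in res.index else res.loc["ICC2"]
    mean_k = res.loc["ICC(A,k)"] if "ICC(A,k)" in res.index else res.loc["ICC2k"]
    return float(single["ICC"]), float(mean_k["ICC"])
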