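"""Model/Results facade over the estimation pipeline.

``GrowthReliabilityModel`` is constructed from data (a longitudinal cohort
and, optionally, a repeated-measures set); ``fit()`` estimates the slope
dispersion and measurement error per feature and returns a
``GrowthReliabilityResults`` carrying the variance components and every
downstream quantity (reliability surfaces, sample sizes,
misclassification, membership) as methods.

Example
-------
>>> from growthrel import GroundTruth, VisitSchedule, generate_cohort, generate_test_retest
>>> from growthrel.model import GrowthReliabilityModel
>>> truth = GroundTruth("hippocampus", 4000.0, -0.6, 0.55, 0.4)
>>> cohort, _ = generate_cohort(truth, 800, VisitSchedule(8, 5), seed=7)
>>> retest = generate_test_retest(truth, 400, seed=8)
>>> res = GrowthReliabilityModel(cohort, retest).fit()
>>> round(res.reliability("hippocampus", duration=6, n_obs=3), 2)  # doctest: +SKIP
0.87
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .consequences import (
    HypotheticalTrio,
    PowerScenario,
    group_membership,
    membership_closed_form,
    sample_size_correlation,
    trio_misclassification,
    trio_overlap,
)
from .error import estimate_error
from .reliability import (
    DesignSpec,
    VarianceComponents,
    grr_reliability,
    reliability_surface,
    summarize_surface,
)
from .slopes import compute_slope_table, slope_dispersion

logger = logging.getLogger(__name__)

_DEFAULT_DURATIONS = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
_DEFAULT_N_OBS = (3, 5, 7, 9)


class GrowthReliabilityModel:
    """Reliability of individual change rates, estimated from data.

    Parameters
    ----------
    cohort : DataFrame
        Long-format longitudinal table (see
        :data:`growthrel.synthetic.COHORT_COLUMNS`).
    retest : DataFrame, optional
        Repeated-measures set for the measurement-error estimate. When
        omitted, ``error_sd`` must be supplied per feature via
        ``error_components``.
    retest_kind : {"test_retest", "dense"}
    error_components : mapping feature -> percent, optional
        Pre-computed measurement-error SDs, bypassing ``retest``.
    detrend : bool
        Remove the population age trend before per-subject slopes.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        retest: Optional[pd.DataFrame] = None,
        retest_kind: str = "test_retest",
        error_components: Optional[dict] = None,
        detrend: bool = True,
        min_followup: float = 4.0,
        min_obs: int = 4,
        mad_threshold: float = 5.0,
        calibrate_error: bool = False,
        spline_df: int = 10,
    ):
        if retest is None and error_components is None:
            raise ValueError("need either a retest table or error_components")
        self.cohort = cohort
        self.retest = retest
        self.retest_kind = retest_kind
        self.error_components = error_components
        self.detrend = detrend
        self.min_followup = min_followup
        self.min_obs = min_obs
        self.mad_threshold = mad_threshold
        self.calibrate_error = calibrate_error
        self.spline_df = spline_df

    @classmethod
    def from_csv(cls, cohort_path, retest_path=None, **kwargs):
        from .io import read_long_table

        cohort = read_long_table(cohort_path, kind="cohort")
        retest = read_long_table(retest_path, kind="retest") if retest_path else None
        return cls(cohort, retest, **kwargs)

    def fit(self) -> "GrowthReliabilityResults":
        slopes = compute_slope_table(
            self.cohort, detrended=self.detrend, spline_df=self.spline_df
        )
        max_fu = slopes["followup"].max()
        min_fu = self.min_followup
        if min_fu >= max_fu:
            logger.warning(
                "min_followup %.1f >= longest follow-up %.1f; relaxing selection",
                min_fu, max_fu,
            )
            min_fu = max_fu * 0.5

        components = []
        errors = {}
        if self.retest is not None:
            errors = estimate_error(
                self.retest,
                self.retest_kind,
                mad_threshold=self.mad_threshold,
                calibrate=self.calibrate_error,
            )
        for feature, sl in slopes.groupby("feature", sort=True):
            disp = slope_dispersion(
                sl,
                min_followup=min_fu,
                min_obs=min(self.min_obs, int(sl["n_obs"].max())),
                mad_threshold=self.mad_threshold,
            )
            if self.error_components is not None and feature in self.error_components:
                err_sd = float(self.error_components[feature])
            elif feature in errors:
                err_sd = errors[feature].sigma_epsilon
            else:
                raise ValueError(f"no measurement-error source for feature {feature!r}")
            components.append(
                VarianceComponents(
                    feature_id=str(feature),
                    slope_sd=disp.slope_sd,
                    error_sd=err_sd,
                    source="fit",
                )
            )
        return GrowthReliabilityResults(self, components, slopes)


class GrowthReliabilityResults:
    """Estimated variance components and everything they imply."""

    def __init__(self, model, components, slope_table):
        self.model = model
        self.components = components
        self.slope_table = slope_table
        self._by_feature = {c.feature_id: c for c in components}

    @property
    def variance_components(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": c.feature_id,
                    "slope_sd_pct_per_yr": c.slope_sd,
                    "error_sd_pct": c.error_sd,
                }
                for c in self.components
            ]
        )

    def reliability(self, feature: str, duration: float, n_obs: int,
                    times: Optional[Sequence[float]] = None) -> float:
        vc = self._by_feature[feature]
        est = grr_reliability(vc, DesignSpec(duration, n_obs, times))
        return est.icc

    def surface(
        self,
        durations: Sequence[float] = _DEFAULT_DURATIONS,
        n_list: Sequence[int] = _DEFAULT_N_OBS,
    ) -> pd.DataFrame:
        return reliability_surface(self.components, durations, n_list)

    def surface_summary(self, durations=_DEFAULT_DURATIONS, n_list=_DEFAULT_N_OBS):
        return summarize_surface(self.surface(durations, n_list))

    def sample_size(
        self, feature: str, true_r: float, duration: float, n_obs: int,
        alpha: float = 0.05, power: float = 0.80,
    ) -> float:
        icc = self.reliability(feature, duration, n_obs)
        return sample_size_correlation(PowerScenario(true_r, alpha, power), icc)

    def _trio(self, feature, duration, n_obs, mean_change) -> HypotheticalTrio:
        vc = self._by_feature[feature]
        est = grr_reliability(vc, DesignSpec(duration, n_obs))
        return HypotheticalTrio(
            mean_change=mean_change,
            slope_sd=vc.slope_sd,
            slope_error_sd=est.slope_error_sd,
        )

    def misclassification(
        self, feature: str, duration: float, n_obs: int,
        mean_change: float = 0.0, pair=("decliner", "normal_ager"),
    ) -> dict:
        trio = self._trio(feature, duration, n_obs, mean_change)
        return {
            "bc": trio_overlap(trio, pair),
            "p_misclassification": trio_misclassification(trio, pair),
        }

    def membership(
        self, feature: str, duration: float, n_obs: int, mean_change: float,
        n_sim: int = 0, seed: int = 0,
    ):
        """Membership report; closed form by default, simulated if n_sim > 0."""
        vc = self._by_feature[feature]
        est = grr_reliability(vc, DesignSpec(duration, n_obs))
        if n_sim > 0:
            return group_membership(
                mean_change, vc.slope_sd, est.slope_error_sd, n_sim=n_sim, seed=seed
            )
        return membership_closed_form(mean_change, vc.slope_sd, est.slope_error_sd)

    def summary(self, durations=(2.0, 6.0, 12.0), n_obs: int = 3) -> str:
        """Plain-text summary table of components and reliability by design."""
        lines = [
            "Growth-rate reliability of longitudinal change",
            "=" * 70,
            f"{'feature':<28}{'slope_sd':>9}{'error_sd':>9}"
            + "".join(f"{f'icc@{int(t)}y':>8}" for t in durations),
            "-" * 70,
        ]
        for c in self.components:
            iccs = [
                self.reliability(c.feature_id, t, n_obs) for t in durations
            ]
            lines.append(
                f"{c.feature_id:<28}{c.slope_sd:>9.3f}{c.error_sd:>9.3f}"
                + "".join(f"{icc:>8.2f}" for icc in iccs)
            )
        lines.append("-" * 70)
        lines.append(
            f"slope_sd in %/yr; error_sd in % of mean; icc at {n_obs} observations"
        )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<GrowthReliabilityResults: {len(self.components)} feature(s), "
            f"{self.slope_table['subject_id'].nunique()} subjects>"
        )
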