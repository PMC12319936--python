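"""File I/O, validation, configuration, and pipeline orchestration.

All tables travel as plain CSV. Longitudinal cohorts use the long-format
header ``subject_id, cohort_id, site_id, sex, age_baseline, time_years,
feature, value`` (times in decimal years, 0-based per subject);
repeated-measures sets use ``subject_id, cohort_id, feature, session,
value``. Parameter tables carry percent units end-to-end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .consequences import (
    HypotheticalTrio,
    PowerScenario,
    group_membership,
    sample_size_correlation,
    trio_misclassification,
    trio_overlap,
)
from .empirical import empirical_surface, fit_se_model
from .error import error_table, estimate_error
from .reliability import (
    VarianceComponents,
    reliability_surface,
    summarize_surface,
)
from .slopes import compute_slope_table, slope_dispersion
from .synthetic import (
    COHORT_COLUMNS,
    RETEST_COLUMNS,
    GroundTruth,
    VisitSchedule,
    generate_cohort,
    generate_test_retest,
)

logger = logging.getLogger(__name__)


def read_long_table(path, kind: str = "cohort") -> pd.DataFrame:
    """Read and validate a long-format table.

    ``kind="cohort"`` expects the longitudinal schema and enforces the
    0-based time convention (subjects whose earliest visit is after 0 are
    re-zeroed, with a log notice); ``kind="retest"`` expects the
    repeated-measures schema.
    """
    df = pd.read_csv(path)
    required = COHORT_COLUMNS if kind == "cohort" else RETEST_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if kind == "cohort":
        if (df["time_years"] < 0).any():
            raise ValueError(f"{path}: negative time_years values")
        dup = df.duplicated(subset=["subject_id", "feature", "time_years"])
        if dup.any():
            raise ValueError(
                f"{path}: duplicate (subject, feature, time) rows: "
                f"{df.loc[dup, 'subject_id'].unique()[:5].tolist()}"
            )
        t0 = df.groupby(["subject_id", "feature"])["time_years"].transform("min")
        if (t0 > 0).any():
            n = df.loc[t0 > 0, "subject_id"].nunique()
            logger.info("re-zeroing times for %d subject(s) with baseline > 0", n)
            df = df.assign(time_years=df["time_years"] - t0)
    else:
        counts = df.groupby(["subject_id", "feature"])["session"].transform("count")
        if (counts < 2).any():
            logger.warning("dropping subjects with a single session")
            df = df[counts >= 2]
    return df.reset_index(drop=True)


def write_long_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_variance_components(path) -> list[VarianceComponents]:
    """Parameter table: feature, slope_sd_pct_per_yr, error_sd_pct[, source]."""
    df = pd.read_csv(path)
    for col in ("feature", "slope_sd_pct_per_yr", "error_sd_pct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        VarianceComponents(
            feature_id=str(r.feature),
            slope_sd=float(r.slope_sd_pct_per_yr),
            error_sd=float(r.error_sd_pct),
            source=str(getattr(r, "source", "")),
        )
        for r in df.itertuples()
    ]


def write_variance_components(components, path) -> None:
    pd.DataFrame(
        [
            {
                "feature": c.feature_id,
                "slope_sd_pct_per_yr": c.slope_sd,
                "error_sd_pct": c.error_sd,
                "source": c.source,
            }
            for c in components
        ]
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Declarative configuration for the end-to-end pipeline."""

    features: list = field(default_factory=list)  # list of GroundTruth-like dicts
    n_subjects: int = 2000
    n_retest_subjects: int = 500
    schedule_duration: float = 8.0
    schedule_n_obs: int = 5
    n_sites: int = 3
    durations: list = field(default_factory=lambda: [2, 4, 6, 8, 10, 12])
    n_obs_grid: list = field(default_factory=lambda: [3, 5, 7, 9])
    min_followup: float = 4.0
    min_obs: int = 4
    mad_threshold: float = 5.0
    calibrate_error: bool = False
    true_r: list = field(default_factory=lambda: [0.1, 0.3, 0.5])
    alpha: float = 0.05
    power: float = 0.80
    n_sim_membership: int = 100_000
    n_subjects_empirical: int = 200
    seed: int = 0
    outdir: str = "growthrel_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.durations or not self.n_obs_grid:
            raise ValueError("design grids must be non-empty")
        if self.seed is None:
            raise ValueError("a master seed is required")
        if not self.features:
            raise ValueError("at least one feature (GroundTruth spec) is required")

    def ground_truths(self) -> list[GroundTruth]:
        return [GroundTruth(**f) for f in self.features]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, estimate parameters, and run every downstream analysis.

    Deterministic given the master seed. Writes parameter tables,
    reliability surfaces (analytic and empirical), power, misclassification
    and membership reports, and a manifest into ``config.outdir``; returns
    the same objects in a dict.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truths = config.ground_truths()

    schedule = VisitSchedule(config.schedule_duration, config.schedule_n_obs)
    components, slope_tables, error_rows = [], [], []
    for truth in truths:
        s_cohort = int(rng.integers(0, 2**31 - 1))
        s_retest = int(rng.integers(0, 2**31 - 1))
        cohort, _ = generate_cohort(
            truth, config.n_subjects, schedule, n_sites=config.n_sites, seed=s_cohort
        )
        retest = generate_test_retest(
            truth, config.n_retest_subjects, n_sessions=2, seed=s_retest
        )
        slopes = compute_slope_table(cohort)
        slope_tables.append(slopes)
        disp = slope_dispersion(
            slopes,
            min_followup=min(config.min_followup, config.schedule_duration - 1e-9),
            min_obs=min(config.min_obs, config.schedule_n_obs),
            mad_threshold=config.mad_threshold,
        )
        err = estimate_error(
            retest, "test_retest",
            mad_threshold=config.mad_threshold,
            calibrate=config.calibrate_error,
        )[truth.feature_id]
        error_rows.append(err)
        components.append(
            VarianceComponents(
                feature_id=truth.feature_id,
                slope_sd=disp.slope_sd,
                error_sd=err.sigma_epsilon,
                source="synthetic",
            )
        )

    slopes_all = pd.concat(slope_tables, ignore_index=True)
    slopes_all.to_csv(outdir / "slope_table.csv", index=False)
    error_table(
        {e.feature_id: e for e in error_rows}
    ).to_csv(outdir / "error_estimates.csv", index=False)
    write_variance_components(components, outdir / "variance_components.csv")

    surface = reliability_surface(components, config.durations, config.n_obs_grid)
    surface.to_csv(outdir / "reliability_surface.csv", index=False)
    summary = summarize_surface(surface)
    summary["cell"].to_csv(outdir / "reliability_surface_summary.csv", index=False)

    # power / sample sizes
    power_rows = []
    for r in config.true_r:
        scen = PowerScenario(true_r=r, alpha=config.alpha, power=config.power)
        for _, row in surface.iterrows():
            power_rows.append(
                {
                    "feature": row["feature"],
                    "duration": row["duration"],
                    "n_obs": row["n_obs"],
                    "true_r": r,
                    "required_n": sample_size_correlation(scen, row["icc"]),
                }
            )
    power_df = pd.DataFrame(power_rows)
    power_df.to_csv(outdir / "sample_sizes.csv", index=False)

    # trajectory overlap / misclassification and membership per feature x cell
    mis_rows, mem_rows = [], []
    comp_by_feature = {c.feature_id: c for c in components}
    for truth in truths:
        vc = comp_by_feature[truth.feature_id]
        for _, row in surface[surface["feature"] == truth.feature_id].iterrows():
            trio = HypotheticalTrio(
                mean_change=truth.mean_yearly_change,
                slope_sd=vc.slope_sd,
                slope_error_sd=row["slope_error_sd"],
            )
            mis_rows.append(
                {
                    "feature": truth.feature_id,
                    "duration": row["duration"],
                    "n_obs": row["n_obs"],
                    "bc_decliner_normal": trio_overlap(trio, ("decliner", "normal_ager")),
                    "bc_decliner_maintainer": trio_overlap(trio, ("decliner", "maintainer")),
                    "p_misclass_decliner_normal": trio_misclassification(
                        trio, ("decliner", "normal_ager")
                    ),
                    "p_misclass_decliner_maintainer": trio_misclassification(
                        trio, ("decliner", "maintainer")
                    ),
                }
            )
            rep = group_membership(
                truth.mean_yearly_change,
                vc.slope_sd,
                row["slope_error_sd"],
                n_sim=config.n_sim_membership,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            mem_rows.append(
                {
                    "feature": truth.feature_id,
                    "duration": row["duration"],
                    "n_obs": row["n_obs"],
                    "p_observed_maintainer": rep.p_observed_maintainer,
                    "p_true_maintainer_given_observed": rep.p_true_maintainer_given_observed,
                    "p_true_decliner_given_observed": rep.p_true_decliner_given_observed,
                }
            )
    mis_df = pd.DataFrame(mis_rows)
    mem_df = pd.DataFrame(mem_rows)
    mis_df.to_csv(outdir / "misclassification.csv", index=False)
    mem_df.to_csv(outdir / "membership.csv", index=False)

    # empirical reliability: slope SEs from cohorts simulated across the
    # design grid, pooled into one SE model per feature
    emp_parts = []
    for truth in truths:
        vc = comp_by_feature[truth.feature_id]
        cell_tables = []
        for t in config.durations:
            for n in config.n_obs_grid:
                cohort, _ = generate_cohort(
                    truth,
                    config.n_subjects_empirical,
                    VisitSchedule(float(t), int(n)),
                    n_sites=1,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                cell_tables.append(compute_slope_table(cohort, detrended=False))
        try:
            model = fit_se_model(pd.concat(cell_tables, ignore_index=True))
        except ValueError as exc:
            logger.warning(
                "empirical surface skipped for %s: %s", truth.feature_id, exc
            )
            continue
        emp_parts.append(
            empirical_surface(
                model, vc.slope_sd, config.durations, config.n_obs_grid,
                feature_id=truth.feature_id,
            )
        )
    emp_df = (
        pd.concat(emp_parts, ignore_index=True) if emp_parts else pd.DataFrame()
    )
    emp_df.to_csv(outdir / "empirical_surface.csv", index=False)

    manifest = {
        "growthrel_version": __version__,
        "seed": config.seed,
        "settings": {
            k: v for k, v in config.__dict__.items() if k != "features"
        },
        "features": [t.feature_id for t in truths],
        "n_rows_cohort_slopes": int(len(slopes_all)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return {
        "components": components,
        "slope_table": slopes_all,
        "surface": surface,
        "surface_summary": summary,
        "sample_sizes": power_df,
        "misclassification": mis_df,
        "membership": mem_df,
        "empirical_surface": emp_df,
        "manifest": manifest,
    }
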