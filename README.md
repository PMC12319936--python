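# growthrel

**Reliability of individual differences in longitudinal change.**

Longitudinal studies increasingly ask not just *whether* a brain structure
(or any other quantity) changes with age, but *who* changes faster or
slower — individual differences in rates of change that can be correlated
with genes, behavior, or clinical outcomes. Those analyses stand or fall
with the reliability of the individual slope estimates, which is usually
far lower than the familiar cross-sectional test–retest reliability of the
measure itself. `growthrel` implements a complete, closed-form framework
for quantifying that reliability and its practical consequences, aimed at
researchers planning or interpreting longitudinal morphometry studies
(FreeSurfer-style regional volume/thickness/area tables), but applicable
to any repeated measure with approximately linear individual change.

## The model

Each subject *i* measured at occasions *t<sub>j</sub>* is assumed to follow
a linear trajectory

&nbsp;&nbsp;&nbsp;&nbsp;Y<sub>ij</sub> = β<sub>1i</sub> + β<sub>2i</sub> t<sub>j</sub> + ε<sub>ij</sub>,

with slopes β<sub>2i</sub> ~ N(δ, σ<sub>s</sub>²) across subjects and
cross-sectional measurement noise ε<sub>ij</sub> ~ N(0, σ<sub>ε</sub>²).
The error variance of an OLS slope is σ<sub>ε</sub>²/SST, where
SST = Σ<sub>j</sub>(t<sub>j</sub> − t̄)² is the spread of the visit times;
for *n* equispaced visits spanning *t* years,
SST = t²n(n+1)/(12(n−1)). The reliability of individual change — the
growth-rate reliability (GRR) intraclass correlation — is then

&nbsp;&nbsp;&nbsp;&nbsp;ρ = σ<sub>s</sub>² / (σ<sub>s</sub>² + σ<sub>ε</sub>² / SST).

Because SST grows with the *square* of follow-up duration, study length
dominates design quality; adding observations helps only modestly.

The package provides:

- **`synthetic`** — a longitudinal cohort generator implementing exactly
  this data-generating process (population age trend, site/sex/intercept
  offsets, visit jitter, random or slope-dependent attrition), with the
  ground truth exported so every estimator can be validated by recovery.
- **`error`** — σ<sub>ε</sub> estimators from test–retest pairs
  (|x₁−x₂|/mean × 100) and densely sampled series (CV × 100), with
  5-scaled-MAD outlier screening, cohort-balanced pooling, and optional
  bias calibration (2/√π and c₄(n) factors).
- **`slopes`** — σ<sub>s</sub> estimation: spline detrending over age with
  sex/cohort/site adjustment, per-subject slopes in percent of the
  subject's mean, outlier screening, and selection of well-observed
  subjects (>4 years, ≥4 observations by default).
- **`reliability`** — the closed form above, reliability surfaces over
  design grids, and ICC(2,1)/ICC(2,k) agreement utilities.
- **`consequences`** — required sample sizes under correlation
  attenuation (r<sub>obs</sub> = r√ρ, Fisher-z power), Bhattacharyya
  overlap and misordering probability for hypothetical maintainers /
  normal agers / decliners (±1 slope SD), and observed-maintainer
  misclassification analysis.
- **`empirical`** — an independent validation route: per-subject slope
  standard errors, a log-link SE surface model over design variables with
  small-sample correction, and empirical ICCs holding σ<sub>s</sub> fixed.

## Worked example

```python
from growthrel import GroundTruth, VisitSchedule, generate_cohort, generate_test_retest
from growthrel.model import GrowthReliabilityModel

# a hippocampus-like feature: -0.6 %/yr mean atrophy, 0.55 %/yr slope SD,
# 0.4 % cross-sectional noise
truth = GroundTruth(
    feature_id="hippocampus_volume", baseline_mean=4000.0,
    mean_yearly_change=-0.6, slope_sd=0.55, noise_sd=0.4,
)
cohort, _ = generate_cohort(truth, 1000, VisitSchedule(duration=8, n_observations=5),
                            n_sites=2, seed=7)
retest = generate_test_retest(truth, 500, seed=8)

res = GrowthReliabilityModel(cohort, retest).fit()
print(res.summary())
```

```
Growth-rate reliability of longitudinal change
======================================================================
feature                      slope_sd error_sd  icc@2y  icc@6y icc@12y
----------------------------------------------------------------------
hippocampus_volume              0.538    0.486    0.71    0.96    0.99
----------------------------------------------------------------------
slope_sd in %/yr; error_sd in % of mean; icc at 3 observations
```

The fit recovers the generative parameters (slope SD 0.538 vs 0.55 true;
the error statistic 0.486 sits near 0.4 × 2/√π ≈ 0.451, the expected
value of the raw test–retest statistic). Reliability of yearly change is
only 0.71 with a 2-year design but near-perfect by 12 years. Downstream:

```python
res.sample_size("hippocampus_volume", true_r=0.3, duration=2, n_obs=3)   # 121
res.misclassification("hippocampus_volume", 2, 3, mean_change=-0.6)
#  {'bc': 0.736, 'p_misclassification': 0.134}
rep = res.membership("hippocampus_volume", 2, 3, mean_change=-0.6)
#  P(observed maintainer) = 0.173; of those, 56.3% truly maintain
#  and 2.3% are actually above-average decliners
```

With only 2 years of follow-up, detecting a true r = 0.3 correlate of
hippocampal change needs 121 subjects (vs 85 at perfect reliability); a
decliner and a normal ager have heavily overlapping observed-slope
distributions (BC = 0.74) and are mis-ordered 13% of the time; and close
to half of the subjects whose hippocampus *appears* stable are in fact
declining.

A `growthrel` command-line tool mirrors the library
(`simulate`, `error-estimate`, `slope-variance`, `reliability`, `power`,
`misclassify`, `membership`, `empirical`, `run-all`).

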