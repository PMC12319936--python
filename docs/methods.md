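# Methods

This note documents the statistical model behind `growthrel`, the
estimators and their defaults, what the synthetic-data generator does and
does not emulate, and the numerical and design choices that were genuinely
open.

## Model and reliability formula

Individual change is modeled as linear in time with normally distributed
slopes: Y_ij = b1_i + b2_i t_j + e_ij, slopes b2_i ~ N(delta, sigma_s^2)
across subjects, noise e_ij ~ N(0, sigma_eps^2) i.i.d. across visits.
All rate quantities are expressed in percent of the subject's mean value
per year and all error quantities in percent of the mean, which makes
features of different modalities and scales directly comparable.

The OLS slope of a subject observed at times t_1..t_n has error variance
sigma_eps^2 / SST with SST = sum_j (t_j - tbar)^2; for n equispaced visits
over t years SST = t^2 n (n+1) / (12 (n-1)). Growth-rate reliability is

    rho = sigma_s^2 / (sigma_s^2 + sigma_eps^2 / SST).

`rho` is an intraclass correlation: it equals the squared correlation
between true and estimated slopes across subjects, which is exactly how
the test suite validates it (Monte-Carlo cohorts with known ground truth,
agreement required within 3 Monte-Carlo standard errors). When explicit
visit times are supplied the general SST sum takes precedence over the
equispaced closed form; the two agree to 1e-9 on equispaced grids.

No intercept–slope covariance is modeled; the framework treats the two
variance components as sufficient.

## Parameter estimators

**Measurement error (sigma_eps).** From test–retest pairs the statistic is
|x1 - x2| / (0.5 (x1 + x2)) * 100; from densely sampled short-interval
series it is the coefficient of variation * 100. Estimates are averaged
across subjects within cohort and across cohorts with equal weight
(cohorts, not subjects, are the sampling unit of scanner/protocol
variation). Both statistics are biased for a normal noise SD: the paired
absolute difference has expectation (2/sqrt(pi)) sigma ~ 1.1284 sigma, and
a sample SD of n values has expectation c4(n) sigma (c4(3) ~ 0.8862).
`calibrate_error_sd` removes these factors; the *raw* statistic remains
the default convention for reporting, the calibrated SD is the
statistically consistent input when comparing estimation routes. Subjects
with more than two sessions in a test–retest design contribute their
first two sessions by session index (the statistic is pairwise; extra
sessions would change its sampling distribution). Pairs with zero,
negative, or sign-mixed means have no percent scale and are excluded with
a logged warning.

**Outlier screening.** Values more than 5 scaled MADs (MAD * 1.4826, the
MAD-to-SD factor for normal data) from the center are discarded; both the
threshold and the center (median by default, mean available) are
configurable. Screening is applied to between-subject averages in
test–retest designs (whole subjects removed) and to within-subject
deviations in dense designs (single sessions removed). When the MAD is
zero with non-identical values — a majority of exact ties — any nonzero
deviation is infinitely many scaled MADs out; off-center values are
flagged and a warning logged, since such data indicate an upstream
problem. At threshold 5 the false-positive rate on clean normal data is
negligible (~6e-7), which the suite checks at n = 5000.

**Slope dispersion (sigma_s).** The pipeline removes a population age
trend, a sex effect, and cohort/site mean offsets with a fixed-effects
regression: a cubic B-spline basis over age (default 10 df) plus centered
indicator columns. Subject-level intercepts are deliberately left in the
residuals: the subsequent per-subject OLS regression of residuals on time
from baseline is algebraically invariant to any per-subject constant, so
a random-intercept model would produce identical slopes. This is why a
fixed-effects spline suffices in place of a penalized mixed-model smooth;
a fixed moderate df was preferred over GCV smoothing because it is
deterministic, orders of magnitude cheaper, and exact for the polynomial
trends used in validation. Slopes are converted to percent of the
subject's mean *observed* value (the fitted value is an alternative the
data cannot distinguish; observed means are simpler and estimator-free).
Dispersion is the sample SD of percent slopes among subjects followed
more than 4 years with at least 4 observations (configurable), after the
5-scaled-MAD screen around the median.

Observed slope SD overestimates sigma_s by the error-propagation factor
sqrt(1 + mean(sigma_eps^2 / SST_i) / sigma_s^2); for long, densely
observed selections this inflation is a few percent at most, which is the
rationale for the selection thresholds. Selective attrition acts in the
opposite direction: dropping steep decliners homogenizes the retained
sample and deflates the estimate (a directional property the suite
verifies by simulation). No correction is applied for either effect; the
selection rule is the mitigation.

**Population mean change.** The average derivative of the fitted age
trend over a window (default 60–80 years) equals the endpoint difference
divided by the window width; it is reported in percent of the trend value
at the window midpoint per year and feeds the trajectory-misclassification
and membership analyses.

## Synthetic data

The generator emulates multi-cohort structural-morphometry tables: a
population mean trajectory over age (default linear, arbitrary callable
accepted), subjects whose noiseless values follow that trajectory along
their own aging modulated by a subject-specific linear percent deviation
(SD sigma_s, optionally skew-normal with mean and SD held fixed),
multiplicative subject/site/sex offsets, visit schedules equispaced over
the follow-up with optional truncated Gaussian jitter (never reordering,
baseline anchored at 0), multiplicative per-visit noise (SD sigma_eps
percent), and monotone per-visit dropout, either random or logistic in
the standardized slope (steeper decliners more likely to drop). The
exact noiseless OLS percent slope of every subject is exported as the
recovery target.

Defaults represent a cognitively healthy aging cohort: ages uniform over
60–80, 5% intercept SD, mean changes of -0.3 to -0.6 %/yr and slope SDs
of 0.35–0.55 %/yr with noise 0.35–1.0 % for the three demo features
(volume-like features more reliable than thickness-like ones).

Not emulated: image acquisition and segmentation (noise is i.i.d.
Gaussian; real FreeSurfer error has scanner-, region- and session-level
structure), nonlinear individual trajectories, age-dependent slope
dispersion, floor effects, correlated error across features, and
informative missingness beyond the slope-dependent hazard. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated model, not robustness to every artifact of real MRI data.

Determinism: every generator call takes a seed and uses an independent
numpy `default_rng` stream; identical seeds reproduce tables byte for
byte. Pipeline-level runs draw per-stage seeds from a master seed.

## Empirical reliability route

As an internal validation, reliability is also estimated without the
closed form: each subject with >= 3 observations yields an OLS slope
standard error sqrt(RSS/(n-2)/SST) (percent of the subject's mean). The
log of these SEs is regressed on log(followup) and
log(n(n+1)/(n-1)) — the basis in which the theoretical surface
log SE = const - log t - 0.5 log(n(n+1)/(12(n-1))) is exactly linear —
with cohort handling that degrades gracefully: random intercepts with
>= 5 cohorts, centered fixed dummies with 2–4, none with 1; a single
design cell falls back to the cell mean with a warning. Predicted SEs are
corrected for small-sample bias: the residual SD with nu = n - 2 degrees
of freedom has expectation c4(nu + 1) sigma, so the correction multiplies
by 1/c4(n - 1) — an exact normal-theory factor (verified against a
simulation oracle in the tests) in place of a simulation-estimated one.
Empirical reliability is sigma_s^2 / (sigma_s^2 + SE_pred^2) with
sigma_s held fixed; when the predicted SE equals sigma_eps/sqrt(SST) this
reproduces the analytic formula identically. On synthetic equispaced
cohorts across the standard design grid (durations 2–12 years, 3–9
observations), the mean absolute difference between the two routes is
required to stay below 0.05. For that comparison the analytic route uses
the *calibrated* error SD, so both routes estimate the same quantity.

## Consequence analyses

**Sample size.** An observed change score with reliability rho attenuates
a true correlation r to r sqrt(rho) (the other variable is assumed
perfectly reliable). Required n for two-sided alpha = 0.05 and 80% power
uses the Fisher-z approximation n = ((z_{1-alpha/2} + z_{power}) /
atanh(r_att))^2 + 3, rounded up; zero attenuated correlation reports an
unbounded requirement.

**Trajectory overlap and misordering.** Hypothetical individuals —
normal ager, maintainer, decliner at 0, +1, -1 slope SDs from the
population mean — have observed-slope densities N(mu, slope_error_sd^2).
Overlap is the Bhattacharyya coefficient BC = integral sqrt(p q) dx,
computed by trapezoid on a grid spanning ±8 SD of both densities and
checked against the normal closed form
exp(-(mu1-mu2)^2/(4(s1^2+s2^2))) sqrt(2 s1 s2/(s1^2+s2^2)) to 1e-4.
The misordering probability for two independent individuals a true gap
delta apart is Phi(-delta/(sqrt(2) slope_error_sd)): 0.5 at zero gap or
unbounded error, and equal to Phi(-k sqrt(rho/(2(1-rho)))) for a k-SD
offset at reliability rho.

**Group membership.** True slopes N(delta, sigma_s^2), observed = true +
error. "Observed maintainer" is operationalized as observed slope >= 0
(ties count as maintaining; the convention is stated because zero slopes
have measure zero anyway). Reported are P(observed maintainer), P(true
maintainer | observed) and P(true above-average decliner | observed),
both by simulation and exactly from the bivariate normal of (true,
observed) with correlation sigma_s/sqrt(sigma_s^2 + slope_error_sd^2);
the simulation is required to match the closed form within 3 binomial
SEs at 1e5 draws.

## Numerical notes and degenerate inputs

- ICC(2,1)/ICC(2,k) agreement indices use two-way random-effects
  absolute agreement (via `pingouin`); tests verify against hand-computed
  Shrout–Fleiss mean squares. Missing cells and zero-variance matrices
  are rejected.
- SST = 0 (all visits coincident) is flagged degenerate; reliability is
  undefined there and raises.
- sigma_s = sigma_eps = 0 is rejected at construction (no variance to
  apportion).
- Percent conversions with zero means raise; negative means convert but
  log a warning (negative morphometry means indicate an upstream error).
- Sample-size ceilings subtract 1e-9 before `ceil` to absorb
  floating-point dust at exact-integer boundaries.
- Problem sizes in the validation suite (2000–5000 subjects per
  Monte-Carlo check, 24-cell design grids, 1e5 membership draws) were
  chosen so that 3-SE tolerances are decisive while the full suite runs
  in seconds.

## Known limitations

- The closed form assumes equal design (same t, n) across subjects when
  applied at the surface level; heterogeneous designs are handled per
  subject through explicit times or the empirical route.
- The log-linear SE model is exact for equispaced designs; strongly
  irregular visit schedules shift its intercept and are only approximated.
- The SE small-sample correction assumes Gaussian residuals.
- Attrition bias on sigma_s is simulated and demonstrated but not
  corrected; the estimator inherits whatever selection the input cohort
  carries.
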