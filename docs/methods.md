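# Methods

`nadirpath` implements an end-to-end epidemiological analysis of newborn
weight change (NWC) and childhood cardio-metabolic traits, together with a
synthetic-cohort generator that stands in for the (non-public) cohort data.
This note documents the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic data do and do not emulate.

## The growth model and NWC

Postnatal weight in the first four days is modelled as a cubic polynomial in
hours since birth with a per-subject random intercept and slope:

    weight_i(t) = b0 + b1 t + b2 t^2 + b3 t^3 + u0_i + u1_i t + eps_it,
    (u0, u1) ~ N(0, G),   eps ~ N(0, sigma^2)

Each newborn contributes exactly two observations: the birthweight, treated
as an observation of the subject's curve at t = 0 (the population intercept
of ~3.24 kg is, consistently, the mean birthweight), and one weight at an
irregular time in (6.3, 96] h.

**Estimation.** Maximum likelihood with the fixed effects profiled out.
Because every subject has two observations, the marginal covariance of each
subject's response is a closed-form 2x2 matrix; the profiled log-likelihood
over the four variance parameters (log sd of intercept and slope, atanh
correlation, log residual sd) is evaluated in one vectorised pass and
minimised by Nelder-Mead (xatol 1e-8, fatol 1e-10). ML rather than REML so
log-likelihoods are comparable across mean structures. Standard generic
mixed-model routines struggle on this design (as many random effects as
observations); the specialised profiled form is fast (~0.6 s at n = 1500)
and is cross-checked against R/lme4 in the test suite. Log-scale variance
parameters carry a tiny additive floor (1e-6 g) and a clip at exp(±30) so
degenerate, noise-free inputs keep the likelihood bounded; a random-slope SD
collapsing below 1e-4 g/h triggers a flagged fall-back to a random-intercept
model. Fixed-effect covariance is the GLS information inverse at the ML
variance estimates.

**Per-subject prediction** is empirical-Bayes (BLUP): u_i = G Z_i' V_i^-1 r_i.
With two observations per subject this interpolates the subject's data in
the zero-residual limit. Subjects lacking a timed measurement never reach
the fit (the cascade removes them); if the slope variance is singular, the
slope prediction is exactly zero.

**Nadir and NWC.** The population nadir is the root of
b1 + 2 b2 t + 3 b3 t^2 = 0 in (0, 96] with positive second derivative,
solved in closed form (a cubic has at most one interior minimum; asserted).
NWC(%) = (predicted weight at nadir − birthweight) / birthweight × 100.
Note that the published rounded coefficients imply a nadir of 54.2 h; the
package always reports the nadir of the curve it was given or fitted and
never hard-codes a time.

**Exclusion cascade**, applied in order with a first-triggered-reason per
row: missing measurement time → measured after 96 h → outlying hourly
change rate → incomplete covariates. Outlier fences are Tukey Q1 − 3·IQR /
Q3 + 3·IQR on the *rate* (% of birthweight per hour), computed from the
rows still in the sample (quantiles by linear interpolation); a config
option substitutes fixed fences, since published thresholds are themselves
realized fences of a particular sample. The report object conserves counts
at every stage and renders as a text flow chart.

## Clinical derivations

* **Friedewald LDL-C** = TC − HDL − TG/5 (mg/dL), missing when TG > 400
  mg/dL (the equation's validity bound). Units are fixed; no inference.
* **Blood pressure**: two readings differing by less than 5 mmHg are
  averaged; otherwise the mean of the two closest of three readings is
  used. A difference of exactly 5 counts as discordant (the protocol
  defines only "<5" and ">5"). When the third reading is equidistant from
  the other two, the pair with the lower mean is taken (deterministic and
  conservative; configurable). Two discordant readings with no third give
  a missing value with a warning.
* **Reference tables / z-scores**: per (sex × 6-month age-bin) means and
  SDs (n−1), optionally subdivided into within-cell height-quantile bands —
  used for blood pressure so its z-scores are height-independent. Scoring a
  value with no matching cell returns missing with a warning; there is no
  silent extrapolation. The normative pediatric BP table itself is treated
  as a pluggable external CSV; the pipeline defaults to cohort-internal
  references (with height bands for BP). External percentile-based "high"
  definitions would need that table; the shipped flags are cohort-internal.
* **High flags**: strictly above the empirical 90th percentile
  (linear-interpolation quantile), defined only with ≥10 observations.

## Path models and FIML

Association models are recursive linear structural equations among observed
variables (no latent variables, no residual covariances among endogenous
variables). Per trait: a total-association model for the age-4 trait on NWC
plus maternal education, pre-pregnancy BMI, gestational age and birthweight;
a total-association model for the age-7 trait (without gestational age, as
specified); a direct-association model adding the age-4 trait (the
"tracking" edge); and a joint two-equation mediation model giving the
direct/indirect/total decomposition of the NWC effect (indirect = product
of the two mediated coefficients; total = direct + indirect, an identity at
point estimates).

**FIML.** Rows are grouped by missingness pattern; each pattern contributes
the multivariate-normal log-likelihood of its observed marginal of the
model-implied moments, which is valid under missing-at-random. Exogenous
means and covariance are estimated jointly as auxiliary parameters so
incomplete exogenous values are handled too. Parameterisation: free
structural coefficients and intercepts, log residual SDs, exogenous
covariance via its Cholesky factor with log diagonal — the optimisation is
unconstrained (L-BFGS-B with a Nelder-Mead polish on demand; tolerance 1e-8
on the log-likelihood; log-scale entries clipped at ±20 and floored so
degenerate data cannot unbound the likelihood). Implied moments are built
incrementally in topological order. On complete data the estimates coincide
with per-equation least squares (classical recursive-system equivalence;
tested at 1e-6).

**Fit statistics.** The saturated model (free mean vector and covariance)
and the independence baseline (means and variances only) are fitted by the
same FIML machinery. χ² = 2(loglik_sat − loglik_model) with df = parameter
difference; CFI = 1 − max(χ²m−dfm,0)/max(χ²b−dfb, χ²m−dfm, 0);
TLI = ((χ²b/dfb)−(χ²m/dfm))/((χ²b/dfb)−1); RMSEA = sqrt(max(χ²m−dfm,0)/(dfm(n−1))).
CFI/TLI are clamped to [0,1]; a saturated model has RMSEA 0 and undefined
TLI. Note the single-equation models with a free exogenous block are
exactly saturated (df = 0).

**Uncertainty.** Analytic SEs from the observed information (central-
difference Hessian of the FIML log-likelihood). Percentile bootstrap
(default 1000 replicates; children resampled with replacement; refits
warm-started at the full-sample estimates with the polish disabled for
speed; failed replicates dropped and counted, >10% failures is an error;
fully reproducible under a fixed seed). BCa was not used — plain
percentile, as the analysis protocol says only "bootstrapping". No
multiple-testing correction anywhere, matching the analysis being mirrored.

**Correlation matrix.** Pairwise-complete Pearson correlations with
two-sided t-test p-values, starred at 0.05/0.01/0.001.

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
the cohort's field operations:

* Newborn weights from the population cubic (intercept 3241.442 g, linear
  −9.378 g/h, quadratic 0.119, cubic −0.0004) with measurement times
  uniform on [6.3, 96] h. The source reports a mean time of 45.3 h; the
  uniform's 51.2 h mean is accepted for simplicity and the distribution is
  a config choice, not a fact.
* Variance components are not published anywhere. Defaults: random
  intercept SD 400 g, random slope SD 1 g/h, correlation −0.2, residual SD
  50 g. Under these, realized NWC SD is ≈1.7–1.8%, somewhat below the
  reported 2.32%; the defaults are fixed design choices, not tuned.
  Weights are rounded to the gram (the scale's resolution); a flag disables
  rounding for exactness tests.
* Childhood traits are generated on the z-scale from the same structural
  equations the analysis fits: age-4 trait from NWC and confounders
  (defaults: all null effects — the expected null pattern), age-7 trait
  adding the tracking edge (defaults 0.235/0.655/0.281/0.725/0.369/0.153
  for glucose/LDL/TG/waist/SBP/DBP). Cross-trait residual correlations
  default to the reported within-age correlation blocks (verified positive
  semi-definite). Residual SDs are set so marginal variances stay ≈1 (the
  structural variance is subtracted; empirically for the natural-scale
  tables, analytically for the z-scale recovery generator).
* Natural-scale traits use the reported means/SDs at each age; TG's SD is
  derived from its IQR (IQR/1.349), and TG is generated normal although the
  real distribution is right-skewed — a deliberately non-emulated feature.
  Raw components are emitted so the derivation stage has work to do: total
  cholesterol is constructed as LDL + HDL + TG/5 (so Friedewald recovers
  LDL exactly), and BP comes as two rounded readings plus a third when the
  first two differ by ≥5 mmHg.
* Maternal education, pre-pregnancy BMI and gestational age come from
  plausible full-term distributions (N(11.9, 4.1) years, N(24.4, 4.3)
  kg/m², N(39.3, 1.2) weeks, clipped); the source gives no distributions.
* Missingness: MCAR, or MAR with the rate varying 0.5/1.0/1.5-fold across
  tertiles of a fully-observed conditioning column.
* All randomness flows from a single master seed through named
  `SeedSequence` substreams; identical seeds give identical tables.

Because the generator meets the analysis's assumptions by construction
(normality, linearity, MAR), passing recovery tests demonstrates the
estimators are correct and unbiased under those assumptions — not that the
assumptions hold in any real cohort.

One known consequence of the design: the *subject-level* mean of true NWC
sits ~0.1 points below the population-curve value (−6.95 vs −6.855),
because the birthweight denominator varies across subjects (Jensen's
inequality); the package's estimates are compared against the appropriate
quantity in each test.

## Problem sizes in the shipped experiments

The recovery experiments use the analysis's own scales: 100 replicates of
1500 newborns for the growth-model recovery (200 in the test suite, where a
coverage check benefits from the extra replicates) and 200 replicates of
312 children for the tracking-coefficient recovery. Bootstrap examples use
200 replicates; production runs default to 1000.

## Known limitations

* No LMS (skewness-adjusted) z-scores; plain mean/SD cells as specified.
* No spline or gestational-age-specific growth standards.
* The pediatric normative BP table is a pluggable input, not shipped.
* FIML assumes joint normality; no robust (sandwich) standard errors.
* The joint mediation model's exact total-effect identity holds when both
  equations condition on the same covariates; the printed model variants
  differ by gestational age, so the identity is exact only for the aligned
  specification (available as a config choice).
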