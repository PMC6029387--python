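# nadirpath

Neonatal weight-change estimation from a cubic random-effects growth curve,
and path-analysis of its association with childhood cardio-metabolic
traits — a reusable, tested pipeline with a synthetic-cohort generator.

## The problem

Newborns lose weight in the first days of life, reaching a *nadir* around
the second or third day before regaining. Whether this very early weight
change (NWC) has medium-term consequences for cardio-metabolic health is an
epidemiological question that requires (a) estimating each newborn's
minimum weight from sparse, irregularly-timed measurements, and (b)
relating it to traits measured years later — waist circumference, fasting
glucose, LDL-cholesterol, triglycerides and blood pressure at ages 4 and
7 — while handling confounding, mediation and missing data. The cohort data
behind such analyses are typically not public, so this package pairs every
analysis stage with a generator that simulates data with the same
statistical structure, making the whole pipeline testable end to end.

## The models

**Growth / NWC.** Weight in the first 96 h follows a population cubic with
subject random effects,

```
weight_i(t) = b0 + b1 t + b2 t^2 + b3 t^3 + u0_i + u1_i t + eps,
```

fitted by profiled maximum likelihood (each newborn contributes birthweight
at t = 0 and one later weight; the per-subject 2×2 marginal covariance is
closed-form, so the likelihood over the four variance parameters is one
vectorised pass). The nadir is the interior minimum of the fixed cubic,
solved in closed form, and

```
NWC(%) = (predicted weight at nadir − birthweight) / birthweight × 100.
```

Sample selection follows an explicit exclusion cascade (missing time →
measured after 96 h → Tukey-fence outliers on the hourly change rate →
incomplete covariates) with conserved counts and a text flow chart.

**Outcomes.** Friedewald LDL-C, a two/three-reading blood-pressure
averaging protocol, age- and sex-specific (height-specific for BP) z-scores
against cohort reference tables, and >P90 "high" flags.

**Association.** Recursive path models per trait, estimated by
full-information maximum likelihood over missingness patterns
(missing-at-random), with percentile-bootstrap confidence intervals,
CFI/TLI/RMSEA fit indices and a direct/indirect/total decomposition of the
NWC effect through the age-4 trait (tracking edge).

## A worked example

```python
from nadirpath import (GrowthSimParams, generate_newborns,
                       apply_exclusion_cascade, fit_cubic_lmm,
                       population_nadir, nwc_table)

newborns, _ = generate_newborns(GrowthSimParams(n_newborns=1500, seed=2))
kept, cascade = apply_exclusion_cascade(newborns)
fit = fit_cubic_lmm(kept)
print([round(float(b), 3) for b in fit.beta])
print(round(population_nadir(fit), 1))
nwc = nwc_table(fit, kept)
print(round(nwc["nwc"].mean(), 2), round(nwc["nwc"].std(ddof=1), 2))
```

prints

```
[3243.903, -8.607, 0.092, -0.0]
56.2
-6.99 1.87
```

— the refitted population curve (generating intercept 3241.442 g, linear
term −9.378 g/h), the nadir at 56.2 h of life, and a mean weight change of
−7.0% of birthweight (SD 1.9), i.e. the expected physiological postnatal
loss. Single-cohort estimates scatter around the generating curve; averaged
over replicates they centre on it (see the acceptance script below). The `examples/` directory has one short script per capability
(simulation, growth/NWC, clinical derivations, mediation models, full
pipeline); each prints what it computes and what the numbers mean.

The same pipeline runs from a shell:

```sh
nadirpath run --seed 11 --out-dir run1   # full simulated analysis + report
nadirpath growth --in newborns.csv --out fit.yaml --nwc-out nwc.csv
nadirpath path --model model2_age7 --trait waist --data merged.csv --boot 1000 --seed 7
```

## Layout

```
src/nadirpath/
  simulate.py    synthetic cohort generator (+ truth tables)
  growth.py      cubic mixed model, nadir, NWC, exclusion cascade
  clinical.py    Friedewald, BP protocol, references, z-scores, high flags
  pathmodel.py   path models, FIML, bootstrap, fit indices, correlations
  pipeline.py    config-driven end-to-end run with persisted intermediates
  cli.py         thin command-line interface
docs/methods.md  models, defaults, numerical choices, limitations
examples/        narrative scripts, one per capability
```
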