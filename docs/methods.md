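# Methods

## Survival model

The analysis unit is the person-period **episode**: from one survey
interview to the earlier of the death date or the next interview (the final
follow-up date for survivors).  Within an episode the hazard is constant at
`h = exp(x'β)` per day, with covariates frozen at the episode's starting
wave.  This gives the weighted log-likelihood

```
ll(β) = Σᵢ wᵢ [ dᵢ xᵢ'β − tᵢ exp(xᵢ'β) ]
```

(`d` event indicator, `t` exposure in days, `w` analytic weight), the same
kernel as a weighted Poisson regression of events with log-exposure offset.
It is globally concave; `carespan.hazard.fit` maximises it with safeguarded
Newton steps (step-halving on the likelihood), relative tolerance 1e-8,
at most 100 iterations, starting from β = 0 except the intercept at
`log(Σwd / Σwt)` — the closed-form intercept-only MLE.  The tests
cross-check the maximiser against statsmodels' Poisson GLM on identical
design matrices (agreement to 1e-6) and against closed-form
occurrence/exposure ratios.

Age enters as a continuous covariate centred at 65 (a single log-linear
slope); a categorical 5-year-band coding (`age_coding="banded"`) is
available for sensitivity because log-linearity in age is an assumption,
not a fact.  Episodes are not split at birthdays: age is a covariate, not
the timescale, so entry age is used for the whole episode.  Sampling
weights are always applied; weighted pseudo-likelihoods make the
model-based (inverse information) covariance optimistic, so a sandwich
estimator is available via `variance="robust"` (model-based remains the
default so that reported intervals are comparable across the two variance
conventions only when explicitly requested).

Degenerate inputs: zero events, rank-deficient designs and non-convergence
raise immediately; complete separation is detected when a coefficient
passes |β| > 30 and the offending column (constant on the event set,
varying overall) is named in the error.

## Rates, life tables, contrasts

Annual death rates use the day-scale convention `m(a) = 365 · exp(x'β)` —
exactly 365, matching the per-day analytic unit, not 365.25.  For a
stratified schedule the access indicator and the stratifying variable are
set to their levels, the other of {sex, residence} and all remaining
covariates sit at their weighted means, and interaction terms are always
the product of their parents' set-or-mean values.  Weighted means are
exposure-weighted (`w·t`) over the estimation episodes, so the standard
population is the same sample that identified the coefficients.  With the
continuous age coding the linear predictor is evaluated at the interval
midpoint `a + 0.5`, so `m(a)` represents `[a, a+1)`; integer-age evaluation
is a flag away.

Life tables run on single years of age 65–100 with an open final interval
(`q = 1`, `L = l/m`).  The default `mx → qx` conversion is
exponential-within-interval (`qx = 1 − exp(−mx)`, `Lx = dx/mx`), which is
exact under the fitted model's piecewise-constant hazard and makes a
constant-rate schedule return `ex = 1/m` exactly — a sharp closed-form test
anchor.  The Chiang conversion (`qx = mx/(1 + 0.5mx)`, `ax = 0.5`) is
provided since printed life tables often use it; results differ only in the
third decimal at these mortality levels.  A fine-grid quadrature oracle
(midpoint integration of piecewise-constant-hazard survival, analytic open
tail) bounds the life-table error below 5e-3 years in the tests.

Contrasts report `Δ = e_A − e_I` and `%Δ = 100Δ/e_I` per age.  Confidence
intervals are parametric Monte-Carlo: coefficient vectors drawn from
N(β̂, Σ̂), each pushed through rates → life table → contrast (vectorised
over draws), 2.5th/97.5th percentiles reported.  Percentile rather than
normal-theory intervals because LE is a nonlinear functional of β.  The
draw seed is mandatory in pipeline configs; identical seeds give identical
intervals.  A subject-level bootstrap (`bootstrap_ci`) exists for
comparison but is orders of magnitude slower; simulation shows the two give
intervals of the same width to within sampling noise.  These intervals
reflect coefficient uncertainty only — a deliberate scope choice, since
they are not claimed to reproduce any published interval endpoints.

## Synthetic cohort generator

`carespan.cohort` emulates the structure of a five-wave ageing survey
(2002/2005/2008/2011 recruitment, 2014 final follow-up):

* **Ages.** Target population density ∝ exp(−0.147·(age−65)) on [65, 110]
  (weighted mean age ≈ 71.8); the sampler inflates ages 80+ threefold and
  post-stratification weights over age-band × sex × residence cells undo
  it.  Weights are normalised to mean 1 over the analytic sample so the
  weighted likelihood keeps the unweighted scale.
* **Prevalences.** Binary covariates are drawn at the weighted prevalences
  of the emulated survey's descriptive table (49.6% men, 32% urban, ~92%
  adequate access — 91.0% rural vs 95.3% urban — 27.2% smoking, 6.1% ADL
  disability, …).  Covariates are drawn independently given residence; real
  data have richer cross-correlations (e.g. schooling × sex), so passing
  recovery tests here does not certify behaviour under strong covariate
  dependence.
* **Mortality truth.** Deaths are exponential waiting times at the per-day
  hazard `exp(β₀ + x'β_true)` held piecewise-constant within inter-wave
  intervals, with baseline annual rate 0.02 at the reference profile and an
  age slope of 0.085/yr (mortality doubling roughly every 8 years).  The
  access coefficient defaults to −0.25 (hazard ratio 0.78), which implies
  an LE advantage of ≈2.1 years at 65 and ≈1.2 at 85 — the magnitude
  reported for this exposure among older adults.
* **Dynamics and attrition.** Time-varying covariates (access, marital
  status, health measures, …) are kept with probability 0.9 per wave, else
  redrawn from their marginal — the persistence value is a free parameter,
  not an estimate, since wave-to-wave transition rates are not published.
  Loss to follow-up is an independent 6% per interval (≈15% cumulative
  under the recruitment mix, matching the emulated survey's ~16%);
  a covariate-linked attrition option supports robustness checks.
  Residence and the proxy-response indicator are held fixed / not
  simulated.

What the generator does **not** emulate: multi-stage cluster sampling and
design effects, covariate-dependent attrition by default, measurement error
in self-reported access, and non-proportional (age-varying) access effects.
Green tests therefore validate the estimation machinery, not robustness to
those real-data features.

## Problem sizes and seeds

Marginal and recovery tests run at n = 20 000 subjects (weighted-marginal
tolerance 3 Monte-Carlo SEs; every coefficient within 3 SEs of truth);
interval-coverage checks use 200 replicate cohorts of n = 5 000 with
1 000-draw intervals, judged against 95% ± 3 binomial SEs.  All simulation
seeds are fixed in the tests; the acceptance script threads a single
`--seed` through every random stage.

## Known limitations

* The exponential (constant-baseline) hazard pushes all age structure into
  the age covariate; if log-mortality is not linear in age, rate schedules
  inherit that misfit (the banded coding is the built-in probe).
* Covariates-at-means standardisation answers a "marginal at the mean
  profile" question, not a population-averaged (g-computation) one.
* Monte-Carlo intervals ignore uncertainty in the weighted covariate means
  (treated as fixed standardisation constants).
* The life table treats the cohort's period rates as a synthetic cohort
  experience; no cohort-vs-period correction is attempted.
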