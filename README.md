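# carespan

How many extra years of life expectancy come with *adequate access to
healthcare* at older ages?  `carespan` implements the full estimation
pipeline used to answer that question from wave-based longitudinal survey
cohorts of adults 65+ (CLHLS-style designs with oversampled oldest-old and
post-stratification weights): survey-weighted exponential-hazard survival
models, model-based age-specific death rates, period life tables, and
life-expectancy contrasts between access groups with Monte-Carlo confidence
intervals.  It is written for epidemiologists and demographers who want the
whole chain — or any single stage — as a tested, importable Python library.

## The model

Mortality is modelled on person-period episodes (interview to death or next
interview) with a constant per-day hazard

    h(x) = exp(β₀ + β₁·access + β₂·age + β₃·sex + β₄·residence + Σᵢ γᵢ zᵢ)

fitted by maximising the weighted exponential log-likelihood
`Σ wᵢ [dᵢ xᵢ'β − tᵢ exp(xᵢ'β)]` (events `d`, exposure days `t`, sampling
weights `w`).  Three covariate ladders mirror standard adjustment practice:
Model I (access + demographics), Model II (+ socioeconomic status and survey
wave), Model III (+ family/social support, health practices, health
conditions), each with access × sex and access × residence interactions.

Age-specific annual death rates follow as `m(a) = 365 · h(x)` with the
access indicator and the stratifying variable (sex or residence) set to
their levels and everything else held at its weighted mean.  A period life
table (`qx = 1 − exp(−mx)`, open age 100) converts each rate schedule into
remaining life expectancy `ex`, and the headline contrast at age *a* is

    Δ(a) = e_adequate(a) − e_inadequate(a),    %Δ(a) = 100 · Δ(a) / e_inadequate(a)

with percentile confidence intervals from multivariate-normal resampling of
the fitted coefficients.

Because the underlying survey microdata are restricted-access, the package
ships a synthetic cohort generator (`carespan.cohort`) that emulates the
survey's structure — recruitment waves, oversampled oldest-old with
post-stratification weights, realistic covariate prevalences, wave-to-wave
covariate dynamics, ~15% loss to follow-up — with *known* ground-truth
hazard coefficients, so every downstream stage is testable end to end.

## Worked example

```python
import carespan as cs

params = cs.CohortParams(n_subjects=20000, seed=7)
episodes = cs.build_episodes(cs.generate_cohort(params))
model = cs.fit(episodes, cs.model_spec("I"))
rows = cs.monte_carlo_ci(model, "women", ages_of_interest=(65, 85),
                         n_draws=1000, seed=11)
print(cs.format_contrast_table(rows))
```

prints

```
Model I - age 65
  [women]
    Inadequate access (I) (years)   16.48 (15.42 to 17.53)
    Adequate access (A) (years)     18.88 (18.50 to 19.25)
    Difference (A-I) (years)         2.40 (1.30 to 3.48)
    % difference (A-I)/I            14.54 (7.42 to 22.63)
Model I - age 85
  [women]
    Inadequate access (I) (years)    6.37 (5.78 to 7.00)
    Adequate access (A) (years)      7.76 (7.44 to 8.09)
    Difference (A-I) (years)         1.39 (0.77 to 1.99)
    % difference (A-I)/I            21.79 (11.02 to 34.00)
```

Women of this synthetic cohort who report adequate access to healthcare
have 2.4 more expected years of life at 65 (and 1.4 at 85) than otherwise
similar women reporting inadequate access — close to the generator's truth
(2.14 years at 65), and matching the well-known pattern that absolute gains
shrink with age while relative gains grow.  The scripts in `examples/` walk
through each capability: cohort simulation and weighted descriptives,
model fitting across the covariate ladders, rate schedules and life tables,
the one-call `run_analysis` pipeline, and contrast arithmetic on published
life-expectancy pairs.

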