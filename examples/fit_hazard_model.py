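"""Fit the weighted exponential hazard models (covariate ladders I-III).

Builds person-period episodes from a synthetic cohort, fits the three
standard covariate ladders by weighted maximum likelihood, and prints
hazard ratios for the healthcare-access exposure.
"""

import numpy as np

import carespan as cs

params = cs.CohortParams(n_subjects=20000, seed=7)
records = cs.generate_cohort(params)
episodes = cs.build_episodes(records)  # drops subjects lost to follow-up
print(f"{len(episodes)} episodes, {int(episodes['event'].sum())} deaths, "
      f"{episodes['exposure_days'].sum() / 365.25:,.0f} person-years\n")

for level in ("I", "II", "III"):
    model = cs.fit(episodes, cs.model_spec(level))
    j = model.term_order.index("adequate_access")
    hr = np.exp(model.coefficients["adequate_access"])
    se = np.sqrt(model.covariance[j, j])
    lo, hi = (np.exp(model.coefficients["adequate_access"] + s * se)
              for s in (-1.96, 1.96))
    print(f"Model {level:>3}: adequate-access hazard ratio "
          f"{hr:.3f} (95% CI {lo:.3f}-{hi:.3f}), "
          f"log-likelihood {model.log_likelihood:,.1f}")

# A hazard ratio below 1 means adequate access is protective: the per-day
# death hazard of those reporting adequate access is ~20-25% lower at the
# same age, sex, residence and covariate profile.  The generator's true
# value is exp(-0.25) = 0.779, so each ladder should recover roughly that.
print(f"\ngenerator truth: {np.exp(params.true_coefficients['adequate_access']):.3f}")
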