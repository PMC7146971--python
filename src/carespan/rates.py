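"""Model-based age-specific annual death rates, standardised at covariate means.

A fitted hazard model gives a per-day hazard ``h = exp(x . beta)``.  For a
given healthcare-access group within a sex or residence stratum, the annual
death rate at age ``a`` is

    m(a) = 365 * exp(linear predictor)

with the access indicator set to its level, age set to ``a`` (by default the
interval midpoint ``a + 0.5``), the stratifying variable set to its level, the
other of {sex, residence} set to its weighted mean, and all remaining
covariates at their weighted means.  The factor is exactly 365 because the
analytic time unit of the hazard model is the day.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hazard import FittedHazardModel, age_term_values

#: days per year used to annualise the per-day hazard
ANNUAL_DAYS = 365.0

ACCESS_LEVELS = {"adequate": 1.0, "inadequate": 0.0}
STRATUM_SETTINGS: dict[str, dict[str, float]] = {
    "women": {"male": 0.0},
    "men": {"male": 1.0},
    "rural": {"urban": 0.0},
    "urban": {"urban": 1.0},
    "all": {},
}


@dataclass
class RateSchedule:
    """Annual death rates m(a) on an integer age grid for one analysis cell."""

    ages: np.ndarray
    m: np.ndarray
    access: str
    stratum: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.m = np.asarray(self.m, dtype=float)
        if len(self.ages) != len(self.m):
            raise ValueError("ages and m must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.m <= 0):
            raise ValueError("all rates must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "m": self.m,
             "access": self.access, "stratum": self.stratum}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RateSchedule":
        df = pd.read_csv(path)
        return cls(
            ages=df["age"].to_numpy(),
            m=df["m"].to_numpy(),
            access=str(df["access"].iloc[0]),
            stratum=str(df["stratum"].iloc[0]),
        )


def _setting_for(
    model: FittedHazardModel, access: str, stratum: str, age_years: float
) -> dict[str, float]:
    if access not in ACCESS_LEVELS:
        raise ValueError(f"access must be one of {sorted(ACCESS_LEVELS)}")
    if stratum not in STRATUM_SETTINGS:
        raise ValueError(f"stratum must be one of {sorted(STRATUM_SETTINGS)}")
    setting = {"adequate_access": ACCESS_LEVELS[access]}
    setting.update(STRATUM_SETTINGS[stratum])
    setting.update(age_term_values(age_years, model.spec.age_coding))
    # baseline-only models have no access term
    base = {p for t in model.term_order if t != "intercept" for p in t.split(":")}
    return {k: v for k, v in setting.items() if k in base}


def prediction_matrix(
    model: FittedHazardModel,
    access: str,
    stratum: str,
    ages: np.ndarray,
    age_midpoint: bool = True,
) -> np.ndarray:
    """Design rows (one per age, columns in model term order incl. intercept).

    Shared by point prediction and the Monte-Carlo CI machinery so both use
    exactly the same covariate settings.
    """
    ages = np.asarray(ages, float)
    rows = []
    for a in ages:
        age_value = a + 0.5 if age_midpoint else a
        setting = _setting_for(model, access, stratum, age_value)

        def base_value(term: str) -> float:
            if term in setting:
                return setting[term]
            return model.weighted_covariate_means[term]

        row = [1.0]
        for term in model.term_order:
            if term == "intercept":
                continue
            value = 1.0
            for part in term.split(":"):
                value *= base_value(part)
            row.append(value)
        rows.append(row)
    return np.asarray(rows, float)


def predict_rates(
    model: FittedHazardModel,
    access: str,
    stratum: str,
    ages=None,
    age_midpoint: bool = True,
) -> RateSchedule:
    """Annual death rate schedule for one access group within one stratum.

    ``m(a)`` represents the rate over the single-year interval ``[a, a+1)``;
    with the continuous age coding the linear predictor is evaluated at the
    interval midpoint ``a + 0.5`` (configurable via ``age_midpoint``).
    """
    if ages is None:
        ages = np.arange(65, 101)
    ages = np.asarray(ages, int)
    lo, hi = model.entry_age_range
    if np.isfinite(lo) and (ages.min() < lo - 1 or ages.max() > hi + 1):
        warnings.warn(
            f"predicting rates outside the fitted age range [{lo:.0f}, {hi:.0f}]; "
            "extrapolating the linear predictor",
            stacklevel=2,
        )
    X = prediction_matrix(model, access, stratum, ages, age_midpoint)
    m = ANNUAL_DAYS * np.exp(X @ model.beta)
    if np.any(m >= 1.0):
        worst = int(ages[np.argmax(m)])
        warnings.warn(
            f"annual death rate reaches {m.max():.3f} at age {worst}; "
            "m is a rate, not a probability, but check the model scale",
            stacklevel=2,
        )
    return RateSchedule(
        ages=ages,
        m=m,
        access=access,
        stratum=stratum,
        provenance={
            "model_level": model.spec.model_level,
            "age_midpoint": age_midpoint,
            "age_coding": model.spec.age_coding,
        },
    )
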