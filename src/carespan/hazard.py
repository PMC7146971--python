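"""Weighted exponential parametric hazard regression on person-period episodes.

The hazard for an episode with covariate row ``x`` is constant over the episode
and equal to ``h = exp(x . beta)`` per day.  With event indicator ``d``,
exposure ``t`` (days) and analytic weight ``w``, the weighted log-likelihood is

    ll(beta) = sum_i w_i * ( d_i * (x_i . beta) - t_i * exp(x_i . beta) )

which is globally concave, so a safeguarded Newton iteration converges from
any start.  The intercept is the per-day log baseline hazard; covariate
coefficients are log hazard ratios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: age bands used by the optional categorical age coding (reference 65-69)
AGE_BANDS: tuple[tuple[int, int | None], ...] = (
    (70, 74), (75, 79), (80, 84), (85, 89), (90, None),
)

ACCESS_TERM = "adequate_access"
DEMOGRAPHIC_TERMS = ("male", "urban")
SES_TERMS = (
    "han_ethnicity", "school_1_6", "school_7plus", "white_collar",
    "economic_independence", "insured",
)
FAMILY_TERMS = ("married", "child_proximity")
BEHAVIOR_TERMS = ("exercise", "smoking")
HEALTH_TERMS = ("adl_disabled", "cognitively_impaired", "chronic_disease")
INTERACTION_TERMS = ("adequate_access:male", "adequate_access:urban")


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


class SeparationError(RuntimeError):
    """A term (nearly) perfectly predicts events; the MLE diverges."""


def age_term_names(age_coding: str) -> tuple[str, ...]:
    if age_coding == "continuous":
        return ("age_c",)
    if age_coding == "banded":
        names = []
        for lo, hi in AGE_BANDS:
            names.append(f"age_{lo}_{hi}" if hi is not None else f"age_{lo}plus")
        return tuple(names)
    raise ValueError(f"unknown age_coding {age_coding!r}")


def age_term_values(age_years: float, age_coding: str) -> dict[str, float]:
    """Values of the age terms for a subject of exact age ``age_years``.

    Continuous coding centres age at 65 so the intercept refers to a
    65-year-old.
    """
    if age_coding == "continuous":
        return {"age_c": age_years - 65.0}
    values = {}
    for name, (lo, hi) in zip(age_term_names("banded"), AGE_BANDS):
        in_band = age_years >= lo and (hi is None or age_years < hi + 1)
        values[name] = 1.0 if in_band else 0.0
    return values


@dataclass(frozen=True)
class ModelSpec:
    """Ordered term list for one hazard model.

    ``terms`` name episode columns or derived columns (``age_c``, ``wave_k``
    survey-wave indicators, age-band dummies) and may contain ``a:b``
    product interactions.  Use :func:`model_spec` for the standard
    Model I/II/III covariate ladders.
    """

    terms: tuple[str, ...]
    model_level: str | None = None
    include_interactions: bool = True
    age_coding: str = "continuous"

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model specification")


def wave_term_names(n_waves: int = 4) -> tuple[str, ...]:
    """Survey-wave indicator names, reference = first recruitment wave."""
    return tuple(f"wave_{k}" for k in range(1, n_waves))


def model_spec(
    level: str = "I",
    include_interactions: bool = True,
    age_coding: str = "continuous",
    n_waves: int = 4,
    extra_terms: tuple[str, ...] = (),
) -> ModelSpec:
    """Build the covariate ladder for Models I, II and III.

    Model I: healthcare access plus age, sex and urban-rural residence.
    Model II: adds socioeconomic status and survey-wave indicators.
    Model III: adds family/social support, health practices and health
    conditions.  ``extra_terms`` appends custom columns (e.g. for
    supplementary covariate sets added to Model I).
    """
    terms: list[str] = [ACCESS_TERM, *age_term_names(age_coding), *DEMOGRAPHIC_TERMS]
    if level not in ("I", "II", "III"):
        raise ValueError(f"unknown model level {level!r}")
    if level in ("II", "III"):
        terms += [*SES_TERMS, *wave_term_names(n_waves)]
    if level == "III":
        terms += [*FAMILY_TERMS, *BEHAVIOR_TERMS, *HEALTH_TERMS]
    terms += [t for t in extra_terms if t not in terms]
    if include_interactions:
        terms += list(INTERACTION_TERMS)
    return ModelSpec(
        terms=tuple(terms),
        model_level=level,
        include_interactions=include_interactions,
        age_coding=age_coding,
    )


def baseline_spec(age_coding: str = "continuous") -> ModelSpec:
    """Age, sex and residence only (no access) — overall-LE reference model."""
    return ModelSpec(
        terms=(*age_term_names(age_coding), *DEMOGRAPHIC_TERMS),
        model_level="baseline",
        include_interactions=False,
        age_coding=age_coding,
    )


def _base_terms(terms: tuple[str, ...]) -> list[str]:
    out: list[str] = []
    for term in terms:
        for part in term.split(":"):
            if part not in out:
                out.append(part)
    return out


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve a single (non-interaction) term to a numeric column."""
    if term == "age_c":
        return (df["entry_age"].to_numpy(float)) - 65.0
    if term.startswith("wave_"):
        k = int(term.split("_", 1)[1])
        return (df["wave_index"].to_numpy() == k).astype(float)
    if term.startswith("age_") and term != "age_c":
        body = term[4:]
        if body.endswith("plus"):
            lo, hi = int(body[:-4]), None
        else:
            lo_s, hi_s = body.split("_")
            lo, hi = int(lo_s), int(hi_s)
        age = df["entry_age"].to_numpy(float)
        ok = age >= lo if hi is None else (age >= lo) & (age < hi + 1)
        return ok.astype(float)
    if term not in df.columns:
        raise KeyError(f"episode data has no column for term {term!r}")
    return df[term].to_numpy(float)


def design_matrix(
    episodes: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray, np.ndarray, int]:
    """Build (X with intercept, names, events d, exposure t, weights w, n_dropped).

    Episodes with a missing value in any required column are dropped
    (mirroring the complete-case handling of the analysis).
    """
    cols = {}
    for term in spec.terms:
        parts = term.split(":")
        col = _term_column(episodes, parts[0])
        for part in parts[1:]:
            col = col * _term_column(episodes, part)
        cols[term] = col
    X = np.column_stack([np.ones(len(episodes)), *cols.values()])
    names = ["intercept", *cols.keys()]
    d = episodes["event"].to_numpy(float)
    t = episodes["exposure_days"].to_numpy(float)
    w = episodes["weight"].to_numpy(float)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(d) & np.isfinite(t) & np.isfinite(w)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("design_matrix: dropped %d episodes with missing values", n_dropped)
        X, d, t, w = X[keep], d[keep], t[keep], w[keep]
    return X, names, d, t, w, n_dropped


@dataclass
class FittedHazardModel:
    """A fitted weighted exponential hazard model.

    ``coefficients`` maps term name (including ``intercept``) to the
    estimate; ``covariance`` is ordered like ``term_order``.
    ``weighted_covariate_means`` are exposure-and-weight weighted means of
    the design columns, used to standardise rate predictions.
    """

    coefficients: dict[str, float]
    covariance: np.ndarray
    term_order: list[str]
    log_likelihood: float
    n_episodes: int
    n_events: int
    total_exposure_days: float
    weighted_covariate_means: dict[str, float]
    spec: ModelSpec
    entry_age_range: tuple[float, float] = (65.0, 110.0)
    variance_kind: str = "model"
    n_dropped: int = 0
    fit_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in self.term_order])

    @classmethod
    def from_coefficients(
        cls,
        coefficients: dict[str, float],
        weighted_covariate_means: dict[str, float],
        spec: ModelSpec,
        covariance: np.ndarray | None = None,
    ) -> "FittedHazardModel":
        """Assemble a model from known coefficients (zero covariance).

        Used to express a simulation's ground-truth hazard in the same form
        as a fitted model, so that truth-implied rate schedules and life
        expectancies can be computed with the identical downstream code.
        """
        order = ["intercept", *[t for t in coefficients if t != "intercept"]]
        coefs = {t: float(coefficients.get(t, 0.0)) for t in order}
        p = len(order)
        cov = np.zeros((p, p)) if covariance is None else np.asarray(covariance, float)
        return cls(
            coefficients=coefs,
            covariance=cov,
            term_order=order,
            log_likelihood=float("nan"),
            n_episodes=0,
            n_events=0,
            total_exposure_days=0.0,
            weighted_covariate_means=dict(weighted_covariate_means),
            spec=spec,
        )

    def predict_log_hazard(self, covariate_setting: dict[str, float]) -> float:
        """Per-day log hazard at a covariate setting.

        Terms absent from the setting default to their stored weighted mean;
        interaction terms are always evaluated as the product of their
        parents' (set or mean) values.
        """
        base = _base_terms(tuple(t for t in self.term_order if t != "intercept"))
        unknown = set(covariate_setting) - set(base)
        if unknown:
            raise KeyError(f"unknown term(s) in covariate setting: {sorted(unknown)}")

        def base_value(term: str) -> float:
            if term in covariate_setting:
                return float(covariate_setting[term])
            if term in self.weighted_covariate_means:
                return float(self.weighted_covariate_means[term])
            raise KeyError(f"no value or stored mean for term {term!r}")

        lp = self.coefficients["intercept"]
        for term in self.term_order:
            if term == "intercept":
                continue
            value = 1.0
            for part in term.split(":"):
                value *= base_value(part)
            lp += self.coefficients[term] * value
        return float(lp)

    def to_json(self) -> str:
        doc = {
            "coefficients": self.coefficients,
            "covariance": self.covariance.tolist(),
            "term_order": self.term_order,
            "log_likelihood": self.log_likelihood,
            "n_episodes": self.n_episodes,
            "n_events": self.n_events,
            "total_exposure_days": self.total_exposure_days,
            "weighted_covariate_means": self.weighted_covariate_means,
            "entry_age_range": list(self.entry_age_range),
            "variance_kind": self.variance_kind,
            "spec": {
                "terms": list(self.spec.terms),
                "model_level": self.spec.model_level,
                "include_interactions": self.spec.include_interactions,
                "age_coding": self.spec.age_coding,
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedHazardModel":
        doc = json.loads(text)
        spec = ModelSpec(
            terms=tuple(doc["spec"]["terms"]),
            model_level=doc["spec"]["model_level"],
            include_interactions=doc["spec"]["include_interactions"],
            age_coding=doc["spec"]["age_coding"],
        )
        return cls(
            coefficients=doc["coefficients"],
            covariance=np.array(doc["covariance"]),
            term_order=doc["term_order"],
            log_likelihood=doc["log_likelihood"],
            n_episodes=doc["n_episodes"],
            n_events=doc["n_events"],
            total_exposure_days=doc["total_exposure_days"],
            weighted_covariate_means=doc["weighted_covariate_means"],
            spec=spec,
            entry_age_range=tuple(doc["entry_age_range"]),
            variance_kind=doc["variance_kind"],
        )


def _log_likelihood(beta, X, d, t, w):
    eta = X @ beta
    return float(np.sum(w * (d * eta - t * np.exp(eta))))


def fit(
    episodes: pd.DataFrame,
    spec: ModelSpec,
    variance: str = "model",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedHazardModel:
    """Maximise the weighted exponential log-likelihood by safeguarded Newton.

    Parameters
    ----------
    episodes
        Person-period episodes with ``event``, ``exposure_days``, ``weight``,
        ``entry_age``, ``wave_index`` and the covariate columns named by
        ``spec.terms``.
    variance
        ``"model"`` uses the inverse observed information; ``"robust"`` uses
        the sandwich estimator (recommended when weights are survey weights,
        since the weighted pseudo-likelihood understates model-based
        variance).
    """
    if variance not in ("model", "robust"):
        raise ValueError(f"unknown variance kind {variance!r}")
    X, names, d, t, w, n_dropped = design_matrix(episodes, spec)
    if X.shape[0] == 0:
        raise ValueError("no usable episodes")
    n_events = int(round(d.sum()))
    if n_events == 0:
        raise ValueError("cannot fit: zero events in the episode data")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    sum_wd = float(np.sum(w * d))
    sum_wt = float(np.sum(w * t))
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(sum_wd / sum_wt)

    ll = _log_likelihood(beta, X, d, t, w)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = t * np.exp(eta)  # expected events per episode
        grad = X.T @ (w * (d - mu))
        info = (X * (w * mu)[:, None]).T @ X  # observed information (= -Hessian)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "singular information matrix during Newton iteration"
            ) from err
        # step-halving safeguard: the likelihood is concave, so a short
        # enough Newton step always improves it
        scale = 1.0
        for _half in range(30):
            candidate = beta + scale * step
            ll_new = _log_likelihood(candidate, X, d, t, w)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll = ll_new
        trace.append(ll)
        if np.max(np.abs(beta)) > 30.0:
            # diagnose the culprit: a column whose value is constant on the
            # event set but not overall separates events from non-events
            culprit = None
            events = d > 0
            for j in range(1, X.shape[1]):
                col = X[:, j]
                if np.ptp(col[events]) == 0.0 and np.ptp(col) > 0.0:
                    culprit = names[j]
                    break
            if culprit is None:
                j = int(np.argmax(np.abs(beta[1:]))) + 1
                culprit = names[j]
            raise SeparationError(
                f"coefficient for {culprit!r} diverged; the term (nearly) "
                "perfectly separates events from non-events"
            )
        if np.max(np.abs(scale * step) / (1.0 + np.abs(beta))) < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton iteration did not converge in {max_iter} iterations", trace
        )

    eta = X @ beta
    mu = t * np.exp(eta)
    info = (X * (w * mu)[:, None]).T @ X
    bread = np.linalg.inv(info)
    if variance == "model":
        cov = bread
    else:
        score = X * (w * (d - mu))[:, None]
        meat = score.T @ score
        cov = bread @ meat @ bread
    cov = 0.5 * (cov + cov.T)

    wt = w * t
    means = (X[:, 1:].T @ wt) / wt.sum()
    entry_age = episodes["entry_age"].to_numpy(float)
    return FittedHazardModel(
        coefficients=dict(zip(names, beta.tolist())),
        covariance=cov,
        term_order=names,
        log_likelihood=ll,
        n_episodes=X.shape[0],
        n_events=n_events,
        total_exposure_days=float(t.sum()),
        weighted_covariate_means=dict(zip(names[1:], means.tolist())),
        spec=spec,
        entry_age_range=(float(np.nanmin(entry_age)), float(np.nanmax(entry_age))),
        variance_kind=variance,
        n_dropped=n_dropped,
        fit_trace=trace,
    )


def predict_log_hazard(
    model: FittedHazardModel, covariate_setting: dict[str, float]
) -> float:
    """Functional form of :meth:`FittedHazardModel.predict_log_hazard`."""
    return model.predict_log_hazard(covariate_setting)
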