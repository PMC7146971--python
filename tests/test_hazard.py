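"""Weighted exponential hazard MLE: closed forms, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

import carespan as cs
from carespan.hazard import ModelSpec


def episodes_frame(event, exposure, weight=None, **covariates):
    n = len(event)
    df = pd.DataFrame({
        "subject_id": np.arange(n),
        "wave_index": np.zeros(n, int),
        "entry_age": np.full(n, 70.0),
        "exposure_days": np.asarray(exposure, float),
        "event": np.asarray(event, int),
        "weight": np.ones(n) if weight is None else np.asarray(weight, float),
    })
    for name, col in covariates.items():
        df[name] = np.asarray(col, float)
    return df


def test_intercept_only_closed_form():
    """beta0_hat = log(sum(w d) / sum(w t)) exactly."""
    rng = np.random.default_rng(0)
    ep = episodes_frame(
        event=rng.integers(0, 2, 50),
        exposure=rng.uniform(10, 1000, 50),
        weight=rng.uniform(0.2, 3.0, 50),
    )
    model = cs.fit(ep, ModelSpec(terms=()))
    w, d, t = ep["weight"], ep["event"], ep["exposure_days"]
    expected = np.log((w * d).sum() / (w * t).sum())
    assert model.coefficients["intercept"] == pytest.approx(expected, abs=1e-10)


def test_single_binary_covariate_rate_ratio_oracle():
    """exp(beta_g) equals the stratified occurrence/exposure rate ratio."""
    rng = np.random.default_rng(1)
    g = rng.integers(0, 2, 200)
    ep = episodes_frame(
        event=rng.integers(0, 2, 200),
        exposure=rng.uniform(10, 2000, 200),
        weight=rng.uniform(0.5, 2.0, 200),
        group=g,
    )
    model = cs.fit(ep, ModelSpec(terms=("group",)))
    w, d, t = (ep[c].to_numpy() for c in ("weight", "event", "exposure_days"))
    rate1 = (w * d)[g == 1].sum() / (w * t)[g == 1].sum()
    rate0 = (w * d)[g == 0].sum() / (w * t)[g == 0].sum()
    assert np.exp(model.coefficients["group"]) == pytest.approx(
        rate1 / rate0, rel=1e-8)
    assert np.exp(model.coefficients["intercept"]) == pytest.approx(
        rate0, rel=1e-8)


def test_agrees_with_poisson_occurrence_exposure_glm(default_episodes):
    """Independent cross-check: the same estimates from a weighted Poisson
    GLM with log-exposure offset (statsmodels), coefficients within 1e-6."""
    sm = pytest.importorskip("statsmodels.api")
    spec = cs.model_spec("I")
    model = cs.fit(default_episodes, spec)
    X, names, d, t, w, _ = cs.hazard.design_matrix(default_episodes, spec)
    glm = sm.GLM(d, X, family=sm.families.Poisson(),
                 offset=np.log(t), freq_weights=w)
    res = glm.fit()
    assert np.allclose(res.params, model.beta, atol=1e-6)


def test_parameter_recovery_small():
    """Fitted coefficients land within 3 SE of the generator's truth."""
    params = cs.CohortParams(n_subjects=8000, seed=42)
    episodes = cs.build_episodes(cs.generate_cohort(params))
    model = cs.fit(episodes, cs.model_spec("I", include_interactions=False))
    for term in ("adequate_access", "age_c", "male", "urban"):
        true = params.true_coefficients[term]
        j = model.term_order.index(term)
        se = np.sqrt(model.covariance[j, j])
        assert abs(model.coefficients[term] - true) < 3 * se, term


def test_zero_events_raises():
    ep = episodes_frame(event=[0, 0, 0], exposure=[100, 200, 300])
    with pytest.raises(ValueError, match="zero events"):
        cs.fit(ep, ModelSpec(terms=()))


def test_rank_deficiency_raises():
    ep = episodes_frame(event=[1, 0, 1, 0], exposure=[100, 200, 300, 400],
                        a=[1, 0, 1, 0], b=[2, 0, 2, 0])
    with pytest.raises(np.linalg.LinAlgError):
        cs.fit(ep, ModelSpec(terms=("a", "b")))


def test_separation_raises_naming_term():
    # all events in g=1, none in g=0 -> beta_g diverges
    rng = np.random.default_rng(3)
    g = np.repeat([0, 1], 50)
    event = g.copy()
    ep = episodes_frame(event=event, exposure=rng.uniform(100, 300, 100), g=g)
    with pytest.raises(cs.SeparationError, match="'g'"):
        cs.fit(ep, ModelSpec(terms=("g",)))


def test_weight_scaling_invariance(default_episodes):
    spec = cs.model_spec("I")
    a = cs.fit(default_episodes, spec)
    scaled = default_episodes.copy()
    scaled["weight"] = scaled["weight"] * 7.3
    b = cs.fit(scaled, spec)
    assert np.allclose(a.beta, b.beta, atol=1e-8)


def test_nested_model_likelihood_ratio_nonnegative(default_episodes):
    m1 = cs.fit(default_episodes, cs.model_spec("I"))
    m2 = cs.fit(default_episodes, cs.model_spec("II"))
    assert m2.log_likelihood >= m1.log_likelihood - 1e-6


def test_model_ladder_nesting():
    t1 = set(cs.model_spec("I").terms)
    t2 = set(cs.model_spec("II").terms)
    t3 = set(cs.model_spec("III").terms)
    assert t1 < t2 < t3


def test_predict_log_hazard_properties(model_I):
    # all terms at zero -> intercept
    zeros = {p for t in model_I.term_order if t != "intercept"
             for p in t.split(":")}
    at_zero = model_I.predict_log_hazard({term: 0.0 for term in zeros})
    assert at_zero == pytest.approx(model_I.coefficients["intercept"])
    # linearity in age: lp(age+1) - lp(age) = beta_age exactly
    s70 = model_I.predict_log_hazard({"age_c": 5.0})
    s71 = model_I.predict_log_hazard({"age_c": 6.0})
    assert s71 - s70 == pytest.approx(model_I.coefficients["age_c"], abs=1e-12)
    with pytest.raises(KeyError):
        model_I.predict_log_hazard({"no_such_term": 1.0})


def test_predict_log_hazard_dot_product_oracle():
    """Hand-computed dot product on a 5-term model, to 1e-12."""
    coefs = {"intercept": -9.1, "adequate_access": -0.3, "age_c": 0.08,
             "male": 0.4, "urban": -0.1, "smoking": 0.2}
    means = {"adequate_access": 0.9, "age_c": 7.0, "male": 0.5,
             "urban": 0.3, "smoking": 0.25}
    model = cs.FittedHazardModel.from_coefficients(
        coefs, means, ModelSpec(terms=tuple(means), model_level=None))
    setting = {"adequate_access": 1.0, "age_c": 10.0, "male": 0.0}
    # urban and smoking fall back to their means
    expected = (-9.1 - 0.3 * 1.0 + 0.08 * 10.0 + 0.4 * 0.0
                - 0.1 * 0.3 + 0.2 * 0.25)
    assert model.predict_log_hazard(setting) == pytest.approx(expected,
                                                              abs=1e-12)


def test_interaction_uses_parent_values():
    coefs = {"intercept": -9.0, "adequate_access": -0.3, "male": 0.4,
             "adequate_access:male": 0.1}
    means = {"adequate_access": 0.9, "male": 0.5}
    model = cs.FittedHazardModel.from_coefficients(
        coefs, means,
        ModelSpec(terms=("adequate_access", "male", "adequate_access:male")))
    lp = model.predict_log_hazard({"adequate_access": 1.0})
    # male defaults to its mean 0.5; interaction = 1.0 * 0.5
    assert lp == pytest.approx(-9.0 - 0.3 + 0.4 * 0.5 + 0.1 * 0.5, abs=1e-12)


def test_robust_variance_differs_and_is_psd(default_episodes):
    spec = cs.model_spec("I")
    m_model = cs.fit(default_episodes, spec, variance="model")
    m_robust = cs.fit(default_episodes, spec, variance="robust")
    assert np.allclose(m_model.beta, m_robust.beta)
    assert not np.allclose(m_model.covariance, m_robust.covariance)
    assert np.all(np.linalg.eigvalsh(m_robust.covariance) > -1e-10)


def test_model_json_roundtrip(model_I):
    text = model_I.to_json()
    back = cs.FittedHazardModel.from_json(text)
    assert np.allclose(back.beta, model_I.beta)
    assert np.allclose(back.covariance, model_I.covariance)
    assert back.spec.terms == model_I.spec.terms
    assert back.weighted_covariate_means == pytest.approx(
        model_I.weighted_covariate_means)


def test_banded_age_coding_fits(default_episodes):
    model = cs.fit(default_episodes,
                   cs.model_spec("I", age_coding="banded"))
    assert "age_80_84" in model.coefficients
    # banded coding still shows mortality rising with age
    assert model.coefficients["age_90plus"] > model.coefficients["age_70_74"]
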