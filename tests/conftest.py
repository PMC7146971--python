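import datetime as dt

import numpy as np
import pandas as pd
import pytest

import carespan as cs


@pytest.fixture(scope="session")
def default_params():
    return cs.CohortParams(n_subjects=8000, seed=20240901)


@pytest.fixture(scope="session")
def default_records(default_params):
    return cs.generate_cohort(default_params)


@pytest.fixture(scope="session")
def default_episodes(default_records):
    return cs.build_episodes(default_records)


@pytest.fixture(scope="session")
def model_I(default_episodes):
    return cs.fit(default_episodes, cs.model_spec("I"))


def make_records(rows):
    """Hand-built subject-wave records for episode-construction tests.

    ``rows``: list of dicts with subject_id, wave_index, interview_date (str),
    outcome, event_date (str or None) and optional covariate overrides.
    """
    covariates = {name: 0 for name in cs.cohort.COVARIATE_COLUMNS}
    out = []
    for row in rows:
        rec = {
            "age_years": 70.0, "weight": 1.0, **covariates,
            "event_date": None, **row,
        }
        out.append(rec)
    df = pd.DataFrame(out)
    df["interview_date"] = pd.to_datetime(df["interview_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


@pytest.fixture
def single_subject_dies_400d():
    return make_records([
        {"subject_id": 0, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2003-07-06"},  # 400 days later
    ])


def quadrature_ex(m, step_years=0.001, horizon_years=80.0):
    """Independent life-expectancy oracle for consecutive single-year ages:
    fine-grid midpoint integration of survival under a piecewise-constant
    hazard, with the analytic tail ``S(horizon)/m_open`` beyond the horizon.
    """
    m = np.asarray(m, float)
    n_ages = len(m)
    t = np.arange(0.0, horizon_years, step_years) + step_years / 2.0
    idx = np.clip(t.astype(int), 0, n_ages - 1)
    H_int = np.concatenate([[0.0], np.cumsum(m)])  # cumulative hazard at integers
    H = H_int[idx] + m[idx] * (t - idx)
    S = np.exp(-H)
    H_horizon = H_int[n_ages - 1] + m[-1] * (horizon_years - (n_ages - 1))
    tail = np.exp(-H_horizon) / m[-1]
    out = np.empty(n_ages)
    for j in range(n_ages):
        out[j] = (S[t >= j].sum() * step_years + tail) / np.exp(-H_int[j])
    return out
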