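"""Synthetic cohort generator: determinism, marginals, survival law."""

import datetime as dt
import io

import numpy as np
import pandas as pd
import pytest

import carespan as cs
from carespan.cohort import COVARIATE_COLUMNS


def test_empty_cohort():
    params = cs.CohortParams(n_subjects=0, seed=1)
    records = cs.generate_cohort(params)
    assert len(records) == 0
    assert "subject_id" in records.columns


@pytest.mark.parametrize("bad", [
    dict(prevalence={**cs.cohort._DEFAULT_PREVALENCE, "male": 1.3}),
    dict(wave_dates=(dt.date(2005, 1, 1), dt.date(2002, 1, 1))),
    dict(wave_dates=(dt.date(2002, 1, 1),)),
    dict(n_subjects=-1),
    dict(attrition_prob=1.5),
])
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        cs.generate_cohort(cs.CohortParams(seed=0, **bad))


def test_determinism_byte_identical(default_params):
    a = cs.generate_cohort(default_params)
    b = cs.generate_cohort(default_params)
    bufs = []
    for df in (a, b):
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        bufs.append(buf.getvalue())
    assert bufs[0] == bufs[1]


def test_subjects_present_every_wave_until_exit(default_records):
    by_subject = default_records.groupby("subject_id")["wave_index"]
    gaps = by_subject.apply(lambda s: np.any(np.diff(np.sort(s.to_numpy())) != 1))
    assert not gaps.any(), "waves must be consecutive from recruitment to exit"


def test_record_invariants(default_records):
    rec = default_records
    assert (rec["age_years"] >= 65).all()
    assert (rec["weight"] > 0).all()
    last = rec.sort_values("wave_index").groupby("subject_id").last()
    ended = last[last["outcome"].isin(["died", "censored"])]
    assert (pd.to_datetime(ended["event_date"])
            > pd.to_datetime(ended["interview_date"])).all()


def test_constant_hazard_survival_matches_closed_form():
    """With all coefficients zero the death fraction over a single 3-year
    interval must match 1 - exp(-lambda * t) of the exponential law."""
    lam = 0.0005  # per day
    days = 1095
    params = cs.CohortParams(
        n_subjects=20000,
        wave_dates=(dt.date(2002, 6, 1),
                    dt.date(2002, 6, 1) + dt.timedelta(days=days)),
        true_coefficients={},
        baseline_log_hazard=float(np.log(lam)),
        attrition_prob=0.0,
        seed=77,
    )
    records = cs.generate_cohort(params)
    base = records.groupby("subject_id").first()
    died = (base["outcome"] == "died").to_numpy(float)
    w = base["weight"].to_numpy(float)
    p_hat = float((died * w).sum() / w.sum())
    p_true = -np.expm1(-lam * days)
    n_eff = w.sum() ** 2 / (w ** 2).sum()
    mc_se = np.sqrt(p_true * (1 - p_true) / n_eff)
    assert abs(p_hat - p_true) <= 3 * mc_se


def test_weighted_marginals_match_targets():
    """At n = 20000 the weighted descriptive table reproduces the configured
    prevalences: ~92-95% adequate access, ~32% urban, ~49.6% men, mean age
    ~71.8 years."""
    params = cs.CohortParams(n_subjects=20000, seed=13)
    records = cs.generate_cohort(params)
    table = cs.summarize_cohort(records)
    assert 91.0 <= table.loc["pct_adequate_access", "total"] <= 95.0
    assert table.loc["pct_urban", "total"] == pytest.approx(32.0, abs=1.5)
    assert table.loc["pct_male", "total"] == pytest.approx(49.6, abs=1.5)
    assert table.loc["mean_age", "total"] == pytest.approx(71.8, abs=0.4)
    # access differs by residence in the configured direction
    assert (table.loc["pct_adequate_access", "urban"]
            > table.loc["pct_adequate_access", "rural"])


def test_weights_mean_one_over_analytic_sample(default_records):
    base = default_records.groupby("subject_id").first()
    analytic = base[base["outcome"] != "lost_to_followup"]
    assert analytic["weight"].mean() == pytest.approx(1.0, abs=1e-9)


def test_attrition_rate_near_target(default_records):
    base = default_records.groupby("subject_id").first()
    lost = (base["outcome"] == "lost_to_followup").mean()
    assert 0.10 < lost < 0.22


def test_summary_single_record_trivial():
    records = cs.generate_cohort(cs.CohortParams(n_subjects=1, seed=5))
    records = records.iloc[[0]].copy()
    records["male"] = 1
    records["urban"] = 0
    records["adequate_access"] = 1
    records["outcome"] = "censored"
    table = cs.summarize_cohort(records)
    assert table.loc["pct_male", "men"] == 100.0
    assert table.loc["pct_adequate_access", "adequate"] == 100.0
    assert np.isnan(table.loc["pct_male", "women"])  # empty stratum flagged


def test_wald_z_zero_for_equal_proportions():
    x = np.array([1.0, 0.0, 1.0, 0.0])
    w = np.ones(4)
    z = cs.cohort._wald_z(x[:2], w[:2], x[2:], w[2:])
    assert z == pytest.approx(0.0)


def test_cohort_roundtrip_csv_yaml(tmp_path, default_params):
    records = cs.generate_cohort(cs.CohortParams(n_subjects=50, seed=3))
    csv = tmp_path / "cohort.csv"
    yml = tmp_path / "params.yaml"
    cs.write_cohort(records, csv, cs.CohortParams(n_subjects=50, seed=3), yml)
    back = cs.read_cohort(csv)
    assert len(back) == len(records)
    assert list(back["subject_id"]) == list(records["subject_id"])
    params = cs.read_params(yml)
    assert params.n_subjects == 50
    assert params.seed == 3
    assert params.wave_dates == cs.CohortParams().wave_dates


def test_time_varying_covariates_change_static_do_not(default_records):
    multi = default_records.groupby("subject_id").filter(lambda g: len(g) >= 3)
    changed = multi.groupby("subject_id").agg(
        {c: "nunique" for c in COVARIATE_COLUMNS})
    for static in ("male", "urban", "han_ethnicity", "school_1_6",
                   "school_7plus", "white_collar"):
        assert (changed[static] == 1).all()
    tv_any = sum((changed[c] > 1).sum() for c in cs.cohort.TIME_VARYING)
    assert tv_any > 0
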