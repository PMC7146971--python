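"""Episode construction: date arithmetic, exposure conservation, dropping rules."""

import numpy as np
import pandas as pd
import pytest

import carespan as cs
from conftest import make_records


def test_single_interview_death_400_days(single_subject_dies_400d):
    episodes = cs.build_episodes(single_subject_dies_400d)
    assert len(episodes) == 1
    assert episodes.loc[0, "exposure_days"] == pytest.approx(400.0)
    assert episodes.loc[0, "event"] == 1


def test_two_waves_death_between_splits_exposure():
    """Interviews at day 0 and day 1095, death at day 1500: two episodes of
    1095 (no event) and 405 days (event)."""
    records = make_records([
        {"subject_id": 1, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2006-07-10"},
        {"subject_id": 1, "wave_index": 1, "interview_date": "2005-05-31",
         "outcome": "died", "event_date": "2006-07-10"},
    ])
    # date oracle: 2002-06-01 + 1095 d = 2005-05-31; + 405 d = 2006-07-10
    assert (pd.Timestamp("2005-05-31") - pd.Timestamp("2002-06-01")).days == 1095
    assert (pd.Timestamp("2006-07-10") - pd.Timestamp("2005-05-31")).days == 405
    episodes = cs.build_episodes(records)
    assert list(episodes["exposure_days"]) == [1095.0, 405.0]
    assert list(episodes["event"]) == [0, 1]


def test_exposure_conservation_no_deaths():
    records = make_records([
        {"subject_id": s, "wave_index": k,
         "interview_date": f"{2002 + 3 * k}-06-01",
         "outcome": "censored", "event_date": "2014-06-01"}
        for s in range(5) for k in range(3)
    ])
    episodes = cs.build_episodes(records)
    assert episodes["event"].sum() == 0
    total_days = (pd.Timestamp("2014-06-01") - pd.Timestamp("2002-06-01")).days
    assert episodes.groupby("subject_id")["exposure_days"].sum().eq(total_days).all()


def test_exposure_conservation_on_synthetic(default_records, default_episodes):
    """Total episode-days equal observed person-days for retained subjects,
    and each deceased retained subject has exactly one event."""
    retained = default_records[default_records["outcome"] != "lost_to_followup"]
    first = retained.groupby("subject_id")["interview_date"].min()
    end = retained.groupby("subject_id")["event_date"].first()
    observed_days = (pd.to_datetime(end) - pd.to_datetime(first)
                     ).dt.total_seconds() / 86_400.0
    total = default_episodes.groupby("subject_id")["exposure_days"].sum()
    assert np.allclose(total.sort_index(), observed_days.sort_index())
    events = default_episodes.groupby("subject_id")["event"].sum()
    outcome = retained.groupby("subject_id")["outcome"].first()
    assert (events[outcome == "died"] == 1).all()
    assert (events[outcome == "censored"] == 0).all()


def test_lost_subjects_dropped_by_default(default_records, default_episodes):
    lost_ids = set(default_records.loc[
        default_records["outcome"] == "lost_to_followup", "subject_id"])
    assert lost_ids, "fixture should contain lost subjects"
    assert not (set(default_episodes["subject_id"]) & lost_ids)
    kept = cs.build_episodes(default_records, drop_lost=False)
    assert set(kept["subject_id"]) & lost_ids
    # lost subjects never contribute events
    lost_rows = kept[kept["subject_id"].isin(lost_ids)]
    assert (lost_rows["event"] == 0).all()


def test_death_on_interview_day_gets_half_day():
    records = make_records([
        {"subject_id": 0, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2002-06-01"},
    ])
    episodes = cs.build_episodes(records)
    assert episodes.loc[0, "exposure_days"] == 0.5
    assert episodes.loc[0, "event"] == 1


def test_death_before_interview_rejected_with_diagnostic(caplog):
    records = make_records([
        {"subject_id": 0, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2001-01-01"},
        {"subject_id": 1, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2003-01-01"},
    ])
    with caplog.at_level("WARNING"):
        episodes = cs.build_episodes(records)
    assert list(episodes["subject_id"]) == [1]
    assert episodes.attrs["report"]["n_bad_dates"] == 1


def test_overlapping_interviews_raise():
    records = make_records([
        {"subject_id": 0, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "censored", "event_date": "2014-06-01"},
        {"subject_id": 0, "wave_index": 1, "interview_date": "2002-06-01",
         "outcome": "censored", "event_date": "2014-06-01"},
    ])
    with pytest.raises(ValueError, match="overlapping"):
        cs.build_episodes(records)


def test_missing_covariate_episode_dropped():
    records = make_records([
        {"subject_id": 0, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2003-01-01", "smoking": np.nan},
        {"subject_id": 1, "wave_index": 0, "interview_date": "2002-06-01",
         "outcome": "died", "event_date": "2003-01-01"},
    ])
    episodes = cs.build_episodes(records)
    assert list(episodes["subject_id"]) == [1]
    assert episodes.attrs["report"]["n_missing_covariates"] == 1


def test_episode_roundtrip_csv(tmp_path, default_episodes):
    path = tmp_path / "episodes.csv"
    cs.write_episodes(default_episodes.head(20), path)
    back = cs.read_episodes(path)
    assert np.allclose(back["exposure_days"],
                       default_episodes.head(20)["exposure_days"])
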