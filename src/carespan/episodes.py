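"""Person-period exposure episodes from subject-wave records.

Each subject contributes one episode per inter-wave interval: from an
interview date to the earlier of the death date or the next interview (or,
for the last interview, the death/censoring date).  The event indicator is 1
only on the interval containing the death.  Covariates, entry age and the
analytic weight are frozen at the episode's starting wave, matching a
pooled-waves risk structure in which those interviewed at each wave are at
risk of dying by the next.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cohort import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)

EPISODE_COLUMNS = (
    "subject_id", "wave_index", "entry_age", "exposure_days", "event",
    "weight", *COVARIATE_COLUMNS,
)


def build_episodes(
    records: pd.DataFrame,
    drop_lost: bool = True,
    zero_length_exposure: float = 0.5,
) -> pd.DataFrame:
    """Convert subject-wave records into exposure episodes.

    Parameters
    ----------
    records
        One row per subject-wave interview with ``interview_date``,
        ``outcome`` (``died``/``censored``/``lost_to_followup``),
        ``event_date`` and the covariate columns.
    drop_lost
        Drop subjects lost to follow-up entirely (the main-analysis
        convention).  When ``False``, lost subjects contribute only their
        observed inter-interview intervals (event-free).
    zero_length_exposure
        Exposure (days) assigned when death falls on the interview day, so
        no episode has zero exposure.

    Raises
    ------
    ValueError
        If a subject has overlapping/duplicated interview dates.

    Notes
    -----
    Records whose death or censoring date precedes the interview date are
    rejected with a logged diagnostic rather than raising; rows with missing
    covariate values are dropped and counted the same way.
    """
    df = records.sort_values(["subject_id", "wave_index"]).copy()
    report = {"n_records": len(df), "n_lost_dropped": 0,
              "n_bad_dates": 0, "n_missing_covariates": 0}

    lost_mask = df["outcome"] == "lost_to_followup"
    if drop_lost:
        report["n_lost_dropped"] = int(df.loc[lost_mask, "subject_id"].nunique())
        df = df[~lost_mask].copy()

    df["interview_date"] = pd.to_datetime(df["interview_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])

    gap = df.groupby("subject_id")["interview_date"].diff()
    if (gap <= pd.Timedelta(0)).any():
        bad = df.loc[gap <= pd.Timedelta(0), "subject_id"].unique()
        raise ValueError(
            f"overlapping or duplicated interview dates for subjects {bad[:5]}")

    next_interview = df.groupby("subject_id")["interview_date"].shift(-1)
    is_last = next_interview.isna()

    end = next_interview.copy()
    died = df["outcome"] == "died"
    censored = df["outcome"] == "censored"
    end[is_last & (died | censored)] = df.loc[is_last & (died | censored),
                                              "event_date"]
    # a death date can precede the next scheduled interview only on the
    # final observed interval; clip the terminal end to the event date
    terminal_event = is_last & died

    bad_dates = end.notna() & (end < df["interview_date"])
    if bad_dates.any():
        report["n_bad_dates"] = int(bad_dates.sum())
        logger.warning("rejected %d record(s) whose end date precedes the "
                       "interview date", report["n_bad_dates"])
    valid = end.notna() & ~bad_dates

    out = df[valid].copy()
    exposure = (end[valid] - out["interview_date"]).dt.total_seconds() / 86_400.0
    exposure = exposure.to_numpy(float)
    exposure[exposure == 0.0] = zero_length_exposure
    out["exposure_days"] = exposure
    out["event"] = terminal_event[valid].astype(int).to_numpy()
    out["entry_age"] = out["age_years"].astype(float)

    missing = out[list(COVARIATE_COLUMNS) + ["weight"]].isna().any(axis=1)
    if missing.any():
        report["n_missing_covariates"] = int(missing.sum())
        out = out[~missing]

    out = out[list(EPISODE_COLUMNS)].reset_index(drop=True)
    report["n_episodes"] = len(out)
    report["n_events"] = int(out["event"].sum())
    out.attrs["report"] = report
    logger.info(
        "build_episodes: %(n_records)d records -> %(n_episodes)d episodes, "
        "%(n_events)d events; dropped %(n_lost_dropped)d lost subjects, "
        "%(n_bad_dates)d bad-date records, %(n_missing_covariates)d with "
        "missing covariates", report)
    return out


def write_episodes(episodes: pd.DataFrame, path) -> None:
    episodes.to_csv(path, index=False)


def read_episodes(path) -> pd.DataFrame:
    return pd.read_csv(path)
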