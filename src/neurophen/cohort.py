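"""Birth-cohort construction and the nested primary-school cohort.

The birth cohort covers singleton children born in a configurable window
(default 1 Sep 2003 – 31 Aug 2009), followed from birth until death or the
11th birthday.  The nested school cohort keeps children enrolled in Year 1
(the first compulsory school year), applying the exclusion cascade in order:
died before the start of Year 1, no linked school record, not enrolled in
Year 1.  Singleton status is assumed established upstream.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from ._dates import (
    academic_year_start,
    academic_year_start_series,
    anniversary_series,
    _as_date,
)

logger = logging.getLogger("neurophen.cohort")

DEFAULT_BIRTH_WINDOW = (dt.date(2003, 9, 1), dt.date(2009, 8, 31))

EXCLUSION_REASONS = (
    "none",
    "died_before_year1",
    "no_linked_school_record",
    "not_enrolled_year1",
)


def build_birth_cohort(
    patients: pd.DataFrame,
    deaths: pd.DataFrame,
    birth_window: tuple[dt.date, dt.date] = DEFAULT_BIRTH_WINDOW,
) -> pd.DataFrame:
    """One row per cohort member with follow-up window.

    ``followup_end`` is the earlier of the death date and the 11th birthday
    (calendar anniversary; 29 Feb births roll forward to 1 Mar).
    Children born outside ``birth_window`` are dropped.  A death recorded
    before birth is rejected naming the patient.
    """
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient ids: {dupes[:5]}")
    if deaths["patient_id"].duplicated().any():
        raise ValueError("multiple death records for one patient")

    df = patients[["patient_id", "birth_date"]].copy()
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    start, end = pd.Timestamp(birth_window[0]), pd.Timestamp(birth_window[1])
    in_window = (df["birth_date"] >= start) & (df["birth_date"] <= end)
    if (~in_window).any():
        logger.info("dropping %d births outside the cohort window", int((~in_window).sum()))
    df = df[in_window].copy()

    d = deaths[["patient_id", "death_date"]].copy()
    d["death_date"] = pd.to_datetime(d["death_date"])
    df = df.merge(d, on="patient_id", how="left")

    bad = df["death_date"].notna() & (df["death_date"] < df["birth_date"])
    if bad.any():
        raise ValueError(
            f"death before birth for patients: {df.loc[bad, 'patient_id'].tolist()[:5]}"
        )

    df["eleventh_birthday"] = anniversary_series(df["birth_date"], 11)
    df["followup_end"] = df[["death_date", "eleventh_birthday"]].min(axis=1)
    df["in_school_cohort"] = False
    df["school_exclusion_reason"] = "none"
    return df.reset_index(drop=True)


def year1_start_date(birth_date) -> dt.date:
    """1 September of the academic year in which the child turns 6.

    A child born between 1 Sep Y and 31 Aug Y+1 starts Year 1 on 1 Sep Y+6
    (the academic year during which their 6th birthday falls).
    """
    y = academic_year_start(_as_date(birth_date))
    return dt.date(y + 6, 9, 1)


def year1_start_series(birth_dates: pd.Series) -> pd.Series:
    y = academic_year_start_series(birth_dates) + 6
    out = pd.to_datetime({"year": y, "month": 9, "day": 1})
    out.index = birth_dates.index
    return out


def build_school_cohort(
    cohort: pd.DataFrame,
    school_records: pd.DataFrame,
    enrolment_rule: str = "expected_year",
) -> pd.DataFrame:
    """Apply the school-cohort exclusion cascade, in order.

    1. died before the start of Year 1;
    2. no linked school record at all;
    3. not enrolled in Year 1 (under ``enrolment_rule``: "expected_year"
       requires a Year-1 record in the child's expected academic year,
       "any_year" accepts a Year-1 record in any academic year).

    Each excluded child carries the first applicable reason.
    """
    if enrolment_rule not in ("expected_year", "any_year"):
        raise ValueError(f"unknown enrolment rule: {enrolment_rule!r}")
    df = cohort.copy()
    df["year1_start"] = year1_start_series(df["birth_date"])

    died_before = df["death_date"].notna() & (df["death_date"] < df["year1_start"])

    linked_ids = set(school_records["patient_id"].unique())
    has_link = df["patient_id"].isin(linked_ids)

    y1 = school_records[school_records["year_group"].astype(str) == "1"]
    if enrolment_rule == "any_year":
        enrolled_ids = set(y1["patient_id"].unique())
        enrolled = df["patient_id"].isin(enrolled_ids)
    else:
        y1 = y1.copy()
        y1["ay_start"] = y1["academic_year"].str.slice(0, 4).astype(int)
        expected = pd.Series(
            df["year1_start"].dt.year.values, index=df["patient_id"].values
        )
        key = set(zip(y1["patient_id"], y1["ay_start"]))
        enrolled = pd.Series(
            [(pid, ay) in key for pid, ay in zip(df["patient_id"], expected[df["patient_id"]].values)],
            index=df.index,
        )

    reason = np.where(
        died_before,
        "died_before_year1",
        np.where(~has_link, "no_linked_school_record", np.where(~enrolled, "not_enrolled_year1", "none")),
    )
    df["school_exclusion_reason"] = reason
    df["in_school_cohort"] = df["school_exclusion_reason"] == "none"
    counts = df["school_exclusion_reason"].value_counts().to_dict()
    logger.info("school-cohort exclusion cascade: %s", counts)
    return df
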