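"""Hospital-record neurodisability phenotyping.

A child is flagged as having hospital-recorded neurodisability when a
code-list diagnosis or procedure code appears in any diagnosis position of
any hospital admission starting before their 11th birthday, in any
contributory cause of death (death before age 11), or when structured birth
fields indicate gestational age < 27 completed weeks or birthweight
< 1000 g (dated at birth).  Each subgroup carries its own first-record
date; the overall first record is the earliest of these.

Age is always the completed-calendar-years (birthday-anniversary) age; the
age-at-first-record band is ``under5`` when the first record falls strictly
before the 5th birthday and ``five_to_ten`` otherwise (first records are by
construction before the 11th birthday).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._dates import age_in_years, age_in_years_series, anniversary_series
from .codelist import (
    ICD10,
    OPCS4,
    CodeList,
    SUBGROUP_ELBW,
    SUBGROUP_EXTREME_PREMATURITY,
)

__all__ = [
    "PhenotypeResult",
    "PhenotypeFrames",
    "phenotype_cohort",
    "phenotype_child",
    "age_in_years",
]

SOURCES = ("admission_diagnosis", "admission_procedure", "birth_characteristic", "death_cause")
_SOURCE_RANK = {s: i for i, s in enumerate(SOURCES)}

GESTATION_TRIGGER_WEEKS = 27  # < 27 completed weeks
BIRTHWEIGHT_TRIGGER_G = 1000  # < 1000 g


@dataclass
class PhenotypeResult:
    """Per-child phenotyping outcome."""

    patient_id: str
    flagged: bool
    first_record_date: dt.date | None
    age_at_first_record_days: int | None
    source: str | None
    subgroups: dict[str, dt.date] = field(default_factory=dict)
    age_band: str = "none"  # under5 | five_to_ten | none


class PhenotypeFrames(NamedTuple):
    """Wide per-child results plus long per-(child, subgroup) first records."""

    results: pd.DataFrame
    subgroup_records: pd.DataFrame


def _clean_codes(s: pd.Series) -> pd.Series:
    return s.fillna("").astype(str).str.strip().str.upper().str.replace(".", "", regex=False)


def _explode_codes(df: pd.DataFrame, col: str, date_col: str) -> pd.DataFrame:
    sub = df.loc[df[col].notna() & (df[col] != ""), ["patient_id", date_col, col]].copy()
    sub[col] = sub[col].astype(str).str.split(";")
    sub = sub.explode(col)
    sub[col] = _clean_codes(sub[col])
    sub = sub[sub[col] != ""]
    return sub.rename(columns={col: "code", date_col: "event_date"})


def _match_events(frame: pd.DataFrame, system: str, codelist: CodeList, source: str) -> pd.DataFrame:
    if frame.empty:
        return pd.DataFrame(columns=["patient_id", "event_date", "subgroup", "source"])
    matched = codelist.match_series(frame["code"], system)
    frame = frame.assign(subgroup=matched)
    frame = frame[frame["subgroup"].map(len) > 0]
    frame = frame.explode("subgroup")
    frame["source"] = source
    return frame[["patient_id", "event_date", "subgroup", "source"]]


def _event_table(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    deaths: pd.DataFrame,
    patients: pd.DataFrame,
    codelist: CodeList,
    death_cause_dating: str = "death_date",
) -> pd.DataFrame:
    """All (patient, date, subgroup, source) qualifying events before age 11."""
    if death_cause_dating not in ("death_date", "exclude"):
        raise ValueError(f"unknown death_cause_dating: {death_cause_dating!r}")

    known = set(patients["patient_id"])
    unknown = set(admissions["patient_id"]) - known
    if unknown:
        raise ValueError(f"admissions for unknown patients: {sorted(unknown)[:5]}")

    windows = cohort[["patient_id", "birth_date", "eleventh_birthday"]]

    adm = admissions.merge(windows, on="patient_id", how="inner")
    adm = adm[pd.to_datetime(adm["admission_date"]) < adm["eleventh_birthday"]]
    adm = adm.assign(admission_date=pd.to_datetime(adm["admission_date"]))

    parts = [
        _match_events(_explode_codes(adm, "diagnosis_codes", "admission_date"), ICD10, codelist, "admission_diagnosis"),
        _match_events(_explode_codes(adm, "procedure_codes", "admission_date"), OPCS4, codelist, "admission_procedure"),
    ]

    if death_cause_dating != "exclude" and not deaths.empty:
        dth = deaths.merge(windows, on="patient_id", how="inner")
        dth = dth.assign(death_date=pd.to_datetime(dth["death_date"]))
        dth = dth[dth["death_date"] < dth["eleventh_birthday"]]
        parts.append(
            _match_events(_explode_codes(dth, "cause_codes", "death_date"), ICD10, codelist, "death_cause")
        )

    # Structured birth-field triggers; only active while the code list carries
    # the corresponding perinatal subgroup (the code list defines the taxonomy).
    listed = codelist.subgroups
    pts = patients.merge(windows[["patient_id", "birth_date"]], on="patient_id", how="inner", suffixes=("", "_c"))
    birth_col = "birth_date" if "birth_date" in pts.columns else "birth_date_c"
    if SUBGROUP_EXTREME_PREMATURITY in listed and "gestational_age_weeks" in pts.columns:
        ga = pd.to_numeric(pts["gestational_age_weeks"], errors="coerce")
        hit = pts[ga.notna() & (ga < GESTATION_TRIGGER_WEEKS)]
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": hit["patient_id"],
                    "event_date": pd.to_datetime(hit[birth_col]),
                    "subgroup": SUBGROUP_EXTREME_PREMATURITY,
                    "source": "birth_characteristic",
                }
            )
        )
    if SUBGROUP_ELBW in listed and "birthweight_g" in pts.columns:
        bw = pd.to_numeric(pts["birthweight_g"], errors="coerce")
        hit = pts[bw.notna() & (bw < BIRTHWEIGHT_TRIGGER_G)]
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": hit["patient_id"],
                    "event_date": pd.to_datetime(hit[birth_col]),
                    "subgroup": SUBGROUP_ELBW,
                    "source": "birth_characteristic",
                }
            )
        )

    parts = [p for p in parts if not p.empty]
    events = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    if events.empty:
        return pd.DataFrame(columns=["patient_id", "event_date", "subgroup", "source"])
    events["event_date"] = pd.to_datetime(events["event_date"])
    return events


def phenotype_cohort(
    cohort: pd.DataFrame,
    admissions: pd.DataFrame,
    deaths: pd.DataFrame,
    patients: pd.DataFrame,
    codelist: CodeList,
    death_cause_dating: str = "death_date",
) -> PhenotypeFrames:
    """Phenotype every cohort member.

    Returns wide per-child ``results`` (one row per cohort member, flagged or
    not) and long ``subgroup_records`` (one row per child x subgroup with its
    first-record date and source).
    """
    events = _event_table(cohort, admissions, deaths, patients, codelist, death_cause_dating)

    if events.empty:
        sub = pd.DataFrame(columns=["patient_id", "subgroup", "first_record_date", "source"])
    else:
        events = events.assign(source_rank=events["source"].map(_SOURCE_RANK))
        events = events.sort_values(["patient_id", "subgroup", "event_date", "source_rank"])
        sub = (
            events.groupby(["patient_id", "subgroup"], as_index=False)
            .first()
            .rename(columns={"event_date": "first_record_date"})
            [["patient_id", "subgroup", "first_record_date", "source"]]
        )

    res = cohort[["patient_id", "birth_date", "eleventh_birthday"]].copy()
    if sub.empty:
        agg = pd.DataFrame(columns=["patient_id", "first_record_date", "source", "subgroups", "subgroup_first_dates"])
    else:
        s = sub.sort_values(["patient_id", "first_record_date", "subgroup"])
        firsts = s.groupby("patient_id", as_index=False).first()
        bysub = sub.sort_values(["patient_id", "subgroup"])
        lists = bysub.groupby("patient_id").agg(
            subgroups=("subgroup", lambda x: ";".join(x)),
            subgroup_first_dates=("first_record_date", lambda x: ";".join(d.strftime("%Y-%m-%d") for d in x)),
        )
        agg = firsts.merge(lists, on="patient_id")

    res = res.merge(agg, on="patient_id", how="left")
    res["flagged"] = res["subgroups"].notna()
    res["age_at_first_record_days"] = (
        (pd.to_datetime(res["first_record_date"]) - res["birth_date"]).dt.days
    )
    flagged = res["flagged"]
    ages = pd.Series(np.nan, index=res.index)
    if flagged.any():
        ages[flagged] = age_in_years_series(
            res.loc[flagged, "birth_date"], res.loc[flagged, "first_record_date"]
        )
    res["age_at_first_record_years"] = ages
    res["age_band"] = np.where(~flagged, "none", np.where(ages < 5, "under5", "five_to_ten"))
    res = res.drop(columns=["eleventh_birthday"])
    return PhenotypeFrames(results=res, subgroup_records=sub)


def phenotype_child(
    member,
    admissions: pd.DataFrame | None,
    death: pd.Series | dict | None,
    birth_fields: dict | None,
    codelist: CodeList,
    death_cause_dating: str = "death_date",
) -> PhenotypeResult:
    """Phenotype a single cohort member (thin wrapper over the cohort path).

    ``member`` needs ``patient_id`` and ``birth_date`` (and optionally a
    precomputed ``eleventh_birthday``).  All supplied admissions must belong
    to the member.
    """
    member = dict(member)
    pid = member["patient_id"]
    birth = pd.Timestamp(member["birth_date"])
    cohort = pd.DataFrame({"patient_id": [pid], "birth_date": [birth]})
    cohort["eleventh_birthday"] = member.get("eleventh_birthday") or anniversary_series(cohort["birth_date"], 11)

    if admissions is None or len(admissions) == 0:
        admissions = pd.DataFrame(columns=["patient_id", "admission_date", "diagnosis_codes", "procedure_codes"])
    else:
        foreign = set(admissions["patient_id"]) - {pid}
        if foreign:
            raise ValueError(f"admissions for unknown patients: {sorted(foreign)}")

    deaths = pd.DataFrame(columns=["patient_id", "death_date", "cause_codes"])
    if death is not None:
        deaths = pd.DataFrame([{"patient_id": pid, **dict(death)}])

    patients = pd.DataFrame([{"patient_id": pid, "birth_date": birth, **(birth_fields or {})}])

    frames = phenotype_cohort(cohort, admissions, deaths, patients, codelist, death_cause_dating)
    row = frames.results.iloc[0]
    subgroups = {}
    if row["flagged"]:
        for sg, d in zip(row["subgroups"].split(";"), row["subgroup_first_dates"].split(";")):
            subgroups[sg] = pd.Timestamp(d).date()
    return PhenotypeResult(
        patient_id=pid,
        flagged=bool(row["flagged"]),
        first_record_date=None if pd.isna(row["first_record_date"]) else pd.Timestamp(row["first_record_date"]).date(),
        age_at_first_record_days=None if pd.isna(row["age_at_first_record_days"]) else int(row["age_at_first_record_days"]),
        source=None if pd.isna(row.get("source")) else row["source"],
        subgroups=subgroups,
        age_band=row["age_band"],
    )
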