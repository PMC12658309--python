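"""Hospital outcomes: spell linkage, person-time, incidence and admission rates.

Admissions starting on the day of a previous discharge (hospital transfers),
or nested within another admission, are linked transitively into continuous
inpatient spells.  Person-time at risk runs from birth to death or the 11th
birthday and, for admission-rate denominators, excludes days spent in
hospital.  Day counting is date-difference (discharge - admission), so a
same-day admission contributes one spell but zero hospital days.

Comparison groups follow the phenotype: children with no hospital-recorded
neurodisability ("none", the reference), any, and the first-record-age split
(under5 / five_to_ten).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import age_in_years_series, anniversary_series

logger = logging.getLogger("neurophen.hospital")

DAYS_PER_YEAR = 365.25

GROUPS = ("none", "any", "under5", "five_to_ten")
AGE_BANDS = ("<1", "1-4", "5-10")
AGE_BANDS_ALL = AGE_BANDS + ("<11",)


@dataclass
class AdmissionMethodMap:
    """HES-style two-character admission-method vocabulary."""

    elective: frozenset = frozenset({"11", "12", "13"})
    emergency: frozenset = frozenset({"21", "22", "23", "24", "25", "28", "2A", "2B", "2C", "2D"})
    birth: frozenset = frozenset({"82", "83"})

    def classify(self, code: str, is_birth_admission: bool = False) -> str:
        if is_birth_admission or code in self.birth:
            return "birth"
        if code in self.elective:
            return "planned"
        if code in self.emergency:
            return "unplanned"
        return "other"


DEFAULT_METHOD_MAP = AdmissionMethodMap()


def group_membership(results: pd.DataFrame, group: str) -> pd.Series:
    """Boolean membership in a comparison group, indexed by patient_id."""
    band = results.set_index("patient_id")["age_band"]
    if group == "none":
        return band == "none"
    if group == "any":
        return band != "none"
    if group in ("under5", "five_to_ten"):
        return band == group
    raise ValueError(f"unknown group: {group!r}")


# ---------------------------------------------------------------------------
# Spell linkage
# ---------------------------------------------------------------------------

def link_spells(
    admissions: pd.DataFrame, method_map: AdmissionMethodMap = DEFAULT_METHOD_MAP
) -> pd.DataFrame:
    """Link admissions into continuous inpatient spells (all patients at once).

    Admission B joins A's spell iff B starts on or before A's (running)
    discharge date: same-day transfer, nesting, or dirty overlap (the latter
    merged with a logged warning).  Spell type comes from the earliest
    constituent admission's method code.
    """
    cols = ["spell_id", "patient_id", "start_date", "end_date", "spell_type", "admission_ids", "n_admissions"]
    if admissions.empty:
        return pd.DataFrame(columns=cols)
    adm = admissions.copy()
    adm["admission_date"] = pd.to_datetime(adm["admission_date"])
    adm["discharge_date"] = pd.to_datetime(adm["discharge_date"])
    if (adm["discharge_date"] < adm["admission_date"]).any():
        raise ValueError("discharge before admission")
    adm = adm.sort_values(
        ["patient_id", "admission_date", "discharge_date"], kind="mergesort"
    ).reset_index(drop=True)

    grp = adm.groupby("patient_id", sort=False)
    run_end = grp["discharge_date"].cummax()
    prev_end = run_end.groupby(adm["patient_id"]).shift(1)
    new_spell = prev_end.isna() | (adm["admission_date"] > prev_end)

    dirty = (~new_spell) & (adm["admission_date"] < prev_end) & (adm["discharge_date"] > prev_end)
    if dirty.any():
        logger.warning("merged %d overlapping admissions that are neither nested nor same-day transfers", int(dirty.sum()))

    adm["spell_id"] = new_spell.cumsum()
    if "is_birth_admission" not in adm.columns:
        adm["is_birth_admission"] = False
    if "admission_method_code" not in adm.columns:
        adm["admission_method_code"] = ""
    if "admission_id" not in adm.columns:
        adm["admission_id"] = adm.index.astype(str)

    first = adm.groupby("spell_id", sort=True).first()
    spells = pd.DataFrame(
        {
            "patient_id": first["patient_id"],
            "start_date": adm.groupby("spell_id")["admission_date"].min(),
            "end_date": adm.groupby("spell_id")["discharge_date"].max(),
            "spell_type": [
                method_map.classify(str(c), bool(b))
                for c, b in zip(first["admission_method_code"], first["is_birth_admission"])
            ],
            "admission_ids": adm.groupby("spell_id")["admission_id"].agg(lambda x: ";".join(map(str, x))),
            "n_admissions": adm.groupby("spell_id")["admission_id"].size(),
        }
    ).reset_index()
    return spells[cols]


# ---------------------------------------------------------------------------
# Person-time
# ---------------------------------------------------------------------------

def compute_person_time(cohort: pd.DataFrame, spells: pd.DataFrame) -> pd.DataFrame:
    """Per-child, per-age-band days of follow-up, hospital days and at-risk days.

    Long output: one row per (patient_id, age_band) for bands <1, 1-4, 5-10
    and the <11 aggregate.  Bands split at exact birthday anniversaries;
    everything is clipped at death.  Linked spells are disjoint, so hospital
    days are never double counted.
    """
    c = cohort[["patient_id", "birth_date", "followup_end"]].copy()
    bounds = {
        0: pd.to_datetime(c["birth_date"]),
        1: anniversary_series(c["birth_date"], 1),
        2: anniversary_series(c["birth_date"], 5),
        3: anniversary_series(c["birth_date"], 11),
    }
    end = pd.to_datetime(c["followup_end"])

    rows = []
    for i, band in enumerate(AGE_BANDS):
        lo = np.minimum(bounds[i], end)
        hi = np.minimum(bounds[i + 1], end)
        days = (hi - lo).dt.days.clip(lower=0)
        rows.append(pd.DataFrame({"patient_id": c["patient_id"], "age_band": band, "days_total": days}))
    total = pd.concat(rows, ignore_index=True)

    hosp = pd.DataFrame({"patient_id": c["patient_id"], "<1": 0, "1-4": 0, "5-10": 0})
    if not spells.empty:
        s = spells.merge(
            pd.DataFrame(
                {
                    "patient_id": c["patient_id"],
                    "b0": bounds[0], "b1": bounds[1], "b2": bounds[2], "b3": bounds[3],
                    "end": end,
                }
            ),
            on="patient_id",
            how="inner",
        )
        start = pd.to_datetime(s["start_date"])
        stop = pd.to_datetime(s["end_date"])
        for i, band in enumerate(AGE_BANDS):
            lo = np.maximum(start, s[f"b{i}"])
            hi = np.minimum(np.minimum(stop, s[f"b{i+1}"]), s["end"])
            s[band] = (hi - lo).dt.days.clip(lower=0)
        hosp = s.groupby("patient_id", as_index=False)[list(AGE_BANDS)].sum()

    hosp_long = hosp.melt(id_vars="patient_id", var_name="age_band", value_name="days_in_hospital")
    pt = total.merge(hosp_long, on=["patient_id", "age_band"], how="left")
    pt["days_in_hospital"] = pt["days_in_hospital"].fillna(0).astype(int)
    agg = pt.groupby("patient_id", as_index=False)[["days_total", "days_in_hospital"]].sum()
    agg["age_band"] = "<11"
    pt = pd.concat([pt, agg[["patient_id", "age_band", "days_total", "days_in_hospital"]]], ignore_index=True)
    pt["days_at_risk"] = pt["days_total"] - pt["days_in_hospital"]
    if (pt["days_at_risk"] < 0).any():
        raise AssertionError("negative days at risk: hospital days exceed follow-up days")
    return pt


# ---------------------------------------------------------------------------
# Cumulative incidence
# ---------------------------------------------------------------------------

def cumulative_incidence(
    cohort: pd.DataFrame,
    results: pd.DataFrame,
    age_thresholds: tuple[int, ...] = (1, 5, 11),
) -> pd.DataFrame:
    """Cumulative incidence of the phenotype by each age threshold.

    Reports both the proportion of children (cases with first record before
    the threshold birthday / cohort size) and the rate per 100 person-years,
    with person-years accruing from birth to the first record, death or the
    threshold birthday, whichever is earliest.
    """
    for t in age_thresholds:
        if t > 11:
            raise ValueError(f"age threshold {t} exceeds follow-up (11 years)")
    m = cohort[["patient_id", "birth_date", "death_date"]].merge(
        results[["patient_id", "first_record_date"]], on="patient_id"
    )
    out = []
    n = len(m)
    for t in age_thresholds:
        ann = anniversary_series(m["birth_date"], t)
        first = pd.to_datetime(m["first_record_date"])
        case = first.notna() & (first < ann)
        stop = np.minimum(ann, first.fillna(pd.Timestamp.max))
        death = pd.to_datetime(m["death_date"]).fillna(pd.Timestamp.max)
        stop = np.minimum(stop, death)
        py = (stop - pd.to_datetime(m["birth_date"])).dt.days.sum() / DAYS_PER_YEAR
        out.append(
            {
                "age_threshold": t,
                "n_children": n,
                "n_cases": int(case.sum()),
                "proportion": case.sum() / n if n else np.nan,
                "person_years": py,
                "rate_per_100py": 100 * case.sum() / py if py > 0 else np.nan,
            }
        )
    return pd.DataFrame(out)


def subgroup_cumulative_incidence(
    cohort: pd.DataFrame,
    subgroup_records: pd.DataFrame,
    age_thresholds: tuple[int, ...] = (1, 5, 11),
) -> pd.DataFrame:
    """Proportion of the cohort with each subgroup first recorded before each
    threshold birthday (the figure-style subgroup incidence export)."""
    n = len(cohort)
    sub = subgroup_records.merge(cohort[["patient_id", "birth_date"]], on="patient_id")
    out = []
    for t in age_thresholds:
        if t > 11:
            raise ValueError(f"age threshold {t} exceeds follow-up (11 years)")
        ann = anniversary_series(sub["birth_date"], t)
        hit = sub[pd.to_datetime(sub["first_record_date"]) < ann]
        counts = hit.groupby("subgroup")["patient_id"].nunique()
        for sg, k in counts.items():
            out.append({"subgroup": sg, "age_threshold": t, "n_cases": int(k), "proportion": k / n})
    return pd.DataFrame(out, columns=["subgroup", "age_threshold", "n_cases", "proportion"])


# ---------------------------------------------------------------------------
# Admission rates
# ---------------------------------------------------------------------------

def admission_rates(
    spells: pd.DataFrame,
    person_time: pd.DataFrame,
    results: pd.DataFrame,
    cohort: pd.DataFrame,
    unit: str = "spell",
    include_birth: bool = False,
) -> pd.DataFrame:
    """Planned/unplanned admission rates per 100 person-years at risk.

    Spells are the counted unit by default (``unit="admission"`` counts raw
    constituent admissions instead); a spell belongs to the age band of its
    start date; birth spells are excluded unless ``include_birth``.
    Rate ratios use the no-phenotype group as reference.
    """
    if unit not in ("spell", "admission"):
        raise ValueError(f"unknown rate unit: {unit!r}")
    types = ("planned", "unplanned") + (("birth",) if include_birth else ())
    s = spells[spells["spell_type"].isin(types)].copy()
    s = s.merge(cohort[["patient_id", "birth_date"]], on="patient_id")
    age = age_in_years_series(s["birth_date"], s["start_date"])
    s = s[age < 11]
    age = age[age < 11]
    s["age_band"] = np.where(age < 1, "<1", np.where(age < 5, "1-4", "5-10"))
    s["weight"] = 1 if unit == "spell" else s["n_admissions"]

    rows = []
    for group in GROUPS:
        members = group_membership(results, group)
        member_ids = set(members[members].index)
        sg = s[s["patient_id"].isin(member_ids)]
        pt = person_time[person_time["patient_id"].isin(member_ids)]
        py = pt.groupby("age_band")["days_at_risk"].sum() / DAYS_PER_YEAR
        for adm_type in types:
            st = sg[sg["spell_type"] == adm_type]
            counts = st.groupby("age_band")["weight"].sum()
            for band in AGE_BANDS_ALL:
                if band == "<11":
                    n_adm = int(counts.sum())
                    pyv = float(py.get("<11", np.nan))
                else:
                    n_adm = int(counts.get(band, 0))
                    pyv = float(py.get(band, np.nan))
                if not pyv or np.isnan(pyv) or pyv <= 0:
                    logger.warning("zero person-years for group=%s type=%s band=%s", group, adm_type, band)
                    rate = np.nan
                else:
                    rate = 100 * n_adm / pyv
                rows.append(
                    {
                        "group": group,
                        "admission_type": adm_type,
                        "age_band": band,
                        "n_admissions": n_adm,
                        "person_years": pyv,
                        "rate_per_100py": rate,
                    }
                )
    out = pd.DataFrame(rows)
    ref = out[out["group"] == "none"].set_index(["admission_type", "age_band"])["rate_per_100py"]

    def _ratio(r, t, b):
        rv = ref.get((t, b), np.nan)
        return r / rv if not (np.isnan(r) or np.isnan(rv) or rv == 0) else np.nan

    out["rate_ratio"] = [
        _ratio(r, t, b)
        for r, t, b in zip(out["rate_per_100py"], out["admission_type"], out["age_band"])
    ]
    # share of all admissions (none + any partition the cohort)
    totals = (
        out[out["group"].isin(["none", "any"])]
        .groupby(["admission_type", "age_band"])["n_admissions"]
        .sum()
    )
    out["pct_of_all_admissions"] = [
        100 * n / totals.get((t, b)) if totals.get((t, b)) else np.nan
        for n, t, b in zip(out["n_admissions"], out["admission_type"], out["age_band"])
    ]
    return out


# ---------------------------------------------------------------------------
# Mortality and birth-admission length
# ---------------------------------------------------------------------------

def mortality_summary(cohort: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Deaths and death proportions by age band (<1, 1-4, 5-10, 0-10) per group.

    Denominator is group size; band membership by completed age at death.
    """
    m = cohort[["patient_id", "birth_date", "death_date"]].copy()
    died = m["death_date"].notna()
    band = pd.Series("none", index=m.index, dtype=object)
    if died.any():
        age = age_in_years_series(m.loc[died, "birth_date"], m.loc[died, "death_date"])
        band[died] = np.where(age < 1, "<1", np.where(age < 5, "1-4", np.where(age < 11, "5-10", "11+")))
    m["death_band"] = band

    rows = []
    for group in GROUPS:
        members = group_membership(results, group)
        member_ids = set(members[members].index)
        gm = m[m["patient_id"].isin(member_ids)]
        n = len(gm)
        for b in ("<1", "1-4", "5-10", "0-10"):
            if b == "0-10":
                k = int(gm["death_band"].isin(["<1", "1-4", "5-10"]).sum())
            else:
                k = int((gm["death_band"] == b).sum())
            rows.append(
                {
                    "group": group,
                    "age_band": b,
                    "n": n,
                    "n_deaths": k,
                    "proportion": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def birth_admission_length(cohort: pd.DataFrame, spells: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/median/IQR of birth-spell length (days) per comparison group.

    Length is spell end minus start in days; children with no birth spell are
    excluded from the statistic with a logged count.
    """
    birth = spells[spells["spell_type"] == "birth"].copy()
    birth["length_days"] = (pd.to_datetime(birth["end_date"]) - pd.to_datetime(birth["start_date"])).dt.days
    birth = birth.sort_values("start_date").groupby("patient_id", as_index=False).first()
    n_missing = len(cohort) - birth["patient_id"].nunique()
    if n_missing:
        logger.info("%d cohort members have no birth admission; excluded from birth-length statistic", n_missing)
    rows = []
    for group in GROUPS:
        members = group_membership(results, group)
        member_ids = set(members[members].index)
        x = birth.loc[birth["patient_id"].isin(member_ids), "length_days"]
        rows.append(
            {
                "group": group,
                "n": len(x),
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "median": x.median(),
                "q1": x.quantile(0.25),
                "q3": x.quantile(0.75),
            }
        )
    return pd.DataFrame(rows)
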