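"""School-recorded special educational needs (SEN) outcomes.

Within the nested school cohort (children enrolled in Year 1), SEN provision
is summarised three ways:

* ever during primary school (Reception to Year 6), with the hierarchical
  highest-ever level (EHCP > SEN support > none) and the overlapping
  ever-support / ever-EHCP measures, using Year-1 enrolment as denominator;
* per school year (Reception, Years 1, 3, 6 by default), each year using its
  own enrolment count as denominator;
* concordance between hospital-recorded subgroups and school-recorded
  primary needs.
"""

from __future__ import annotations

import logging

import pandas as pd

from .hospital import GROUPS, group_membership

logger = logging.getLogger("neurophen.sen")

YEAR_GROUPS = ("R", "1", "2", "3", "4", "5", "6")
SEN_LEVELS = ("none", "support", "ehcp")

NEED_CATEGORIES = (
    "speech-language-communication",
    "moderate learning difficulty",
    "learning disability",
    "physical disability",
    "visual impairment",
    "hearing impairment",
    "autistic spectrum disorder",
    "other",
    "none",
)

# Raw school-census need labels folded into the analysis categories.
NEED_GROUPING = {
    "severe learning difficulty": "learning disability",
    "profound and multiple learning difficulty": "learning disability",
}

# Hospital subgroup -> expected school-recorded need, for concordance.
NEED_BY_SUBGROUP = {
    "autistic spectrum disorders": "autistic spectrum disorder",
    "learning disability": "learning disability",
    "chromosomal anomalies": "learning disability",
    "cerebral palsy": "physical disability",
    "neuromuscular disorders": "physical disability",
    "degenerative cns disorders": "physical disability",
    "congenital anomalies of cns": "physical disability",
    "developmental disorders": "speech-language-communication",
    "hearing impairment diagnosis": "hearing impairment",
    "cochlear implant": "hearing impairment",
    "hearing device": "hearing impairment",
    "bilateral visual impairment": "visual impairment",
    "high-risk eye conditions": "visual impairment",
}


def _primary_records(school_records: pd.DataFrame) -> pd.DataFrame:
    rec = school_records.copy()
    rec["year_group"] = rec["year_group"].astype(str)
    rec = rec[rec["year_group"].isin(YEAR_GROUPS)]
    rec["sen_level"] = rec["sen_level"].fillna("none").replace("", "none")
    rec["primary_need"] = (
        rec["primary_need"].fillna("none").replace("", "none").replace(NEED_GROUPING)
    )
    return rec


def build_sen_history(school_records: pd.DataFrame) -> pd.DataFrame:
    """Per-pupil SEN history over observed primary-school records.

    ``highest_ever`` is hierarchical: ehcp if EHCP ever recorded, else
    support if SEN support ever recorded, else none.  ``primary_needs_ever``
    is the ;-joined set of recorded need categories (excluding "none").
    """
    rec = _primary_records(school_records)
    if rec.empty:
        return pd.DataFrame(
            columns=["patient_id", "ever_support", "ever_ehcp", "any_provision", "highest_ever", "primary_needs_ever"]
        )
    g = rec.groupby("patient_id")
    hist = pd.DataFrame(
        {
            "ever_support": g["sen_level"].agg(lambda s: bool((s == "support").any())),
            "ever_ehcp": g["sen_level"].agg(lambda s: bool((s == "ehcp").any())),
            "primary_needs_ever": g["primary_need"].agg(
                lambda s: ";".join(sorted(set(s) - {"none"}))
            ),
        }
    ).reset_index()
    hist["any_provision"] = hist["ever_support"] | hist["ever_ehcp"]
    hist["highest_ever"] = "none"
    hist.loc[hist["ever_support"], "highest_ever"] = "support"
    hist.loc[hist["ever_ehcp"], "highest_ever"] = "ehcp"
    return hist


def sen_ever_summary(
    school_cohort: pd.DataFrame,
    school_records: pd.DataFrame,
    results: pd.DataFrame,
) -> pd.DataFrame:
    """Ever-during-primary-school SEN measures per comparison group.

    Denominator is the number of Year-1-enrolled children in the group (the
    school cohort).  "Ever support" and "ever EHCP" may overlap; the
    highest-ever hierarchy partitions each group.
    """
    members = school_cohort[school_cohort["in_school_cohort"]]
    hist = build_sen_history(school_records)
    m = members[["patient_id"]].merge(hist, on="patient_id", how="left")
    for c in ("ever_support", "ever_ehcp", "any_provision"):
        m[c] = m[c].fillna(False).astype(bool)
    m["highest_ever"] = m["highest_ever"].fillna("none")

    rows = []
    for group in GROUPS:
        member_mask = group_membership(results, group)
        ids = set(member_mask[member_mask].index)
        gm = m[m["patient_id"].isin(ids)]
        denom = len(gm)
        measures = {
            "any_provision": gm["any_provision"].sum(),
            "ever_support": gm["ever_support"].sum(),
            "ever_ehcp": gm["ever_ehcp"].sum(),
            "highest_none": (gm["highest_ever"] == "none").sum(),
            "highest_support": (gm["highest_ever"] == "support").sum(),
            "highest_ehcp": (gm["highest_ever"] == "ehcp").sum(),
        }
        for measure, k in measures.items():
            rows.append(
                {
                    "group": group,
                    "measure": measure,
                    "n": int(k),
                    "denominator": denom,
                    "proportion": k / denom if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def sen_by_year(
    school_cohort: pd.DataFrame,
    school_records: pd.DataFrame,
    results: pd.DataFrame,
    year_groups: tuple[str, ...] = ("R", "1", "3", "6"),
) -> pd.DataFrame:
    """Per-school-year SEN proportions, denominated by that year's enrolment."""
    for yg in year_groups:
        if str(yg) not in YEAR_GROUPS:
            raise ValueError(f"year group {yg!r} outside Reception..Year 6")
    members = set(school_cohort.loc[school_cohort["in_school_cohort"], "patient_id"])
    rec = _primary_records(school_records)
    rec = rec[rec["patient_id"].isin(members)]

    rows = []
    for group in GROUPS:
        member_mask = group_membership(results, group)
        ids = set(member_mask[member_mask].index) & members
        for yg in year_groups:
            yr = rec[(rec["year_group"] == str(yg)) & rec["patient_id"].isin(ids)]
            denom = yr["patient_id"].nunique()
            for level, mask in (
                ("support", yr["sen_level"] == "support"),
                ("ehcp", yr["sen_level"] == "ehcp"),
                ("any", yr["sen_level"].isin(["support", "ehcp"])),
            ):
                k = yr.loc[mask, "patient_id"].nunique()
                rows.append(
                    {
                        "group": group,
                        "year_group": str(yg),
                        "level": level,
                        "n": int(k),
                        "denominator": int(denom),
                        "proportion": k / denom if denom else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def concordance(
    subgroup_records: pd.DataFrame,
    school_cohort: pd.DataFrame,
    school_records: pd.DataFrame,
    mapping: dict[str, str] = NEED_BY_SUBGROUP,
) -> pd.DataFrame:
    """Hospital-subgroup vs school-need concordance.

    For each (hospital subgroup, mapped school need): the proportion of
    school-cohort children with that hospital subgroup who ever had the need
    recorded at school.  Subgroups absent from the school cohort yield a
    missing proportion.
    """
    members = set(school_cohort.loc[school_cohort["in_school_cohort"], "patient_id"])
    hist = build_sen_history(school_records)
    needs = {
        pid: set(n.split(";")) if n else set()
        for pid, n in zip(hist["patient_id"], hist["primary_needs_ever"])
    }
    rows = []
    for subgroup, need in mapping.items():
        ids = set(subgroup_records.loc[subgroup_records["subgroup"] == subgroup, "patient_id"]) & members
        denom = len(ids)
        if denom == 0:
            logger.info("subgroup %r absent from school cohort; concordance undefined", subgroup)
            rows.append(
                {"subgroup": subgroup, "school_need": need, "n": 0, "denominator": 0, "proportion": float("nan")}
            )
            continue
        k = sum(1 for pid in ids if need in needs.get(pid, set()))
        rows.append(
            {"subgroup": subgroup, "school_need": need, "n": k, "denominator": denom, "proportion": k / denom}
        )
    return pd.DataFrame(rows)
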