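"""Seedable synthetic linked health/education records.

Generates the four linked tables the pipeline consumes — patients, hospital
admissions, deaths, school-census records — with the statistical structure
the analysis assumes: configurable subgroup prevalence (independent across
subgroups), planned/unplanned admission processes whose per-at-risk-day
intensity reproduces the configured baseline rates and phenotype rate
multipliers, geometric lengths of stay (longer birth admissions for
phenotype-positive children), status-conditional death risks with an
age-at-death distribution, transfer admissions that start on a prior
discharge date, and status-conditional SEN provision and school-need
assignment.

Admissions per child are drawn as a renewal process in at-risk days, so a
child is never admitted while already in hospital and the estimated rates
per 100 at-risk person-years recover the configured values.  Every
phenotype-positive child carries a code from each assigned subgroup on an
admission (an existing one in the target age band where possible) or on the
death record; evidence age follows a two-component age-at-first-record
distribution (before age 5 vs ages 5-10).  The perinatal birth-weight and
prematurity subgroups are dated at birth and mirrored in the structured
gestational-age/birth-weight fields.

Exact birth dates are generated (real hospital records carry month of birth
only) and all children are singletons; see the methods note for the other
simplifications.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq

from ._dates import academic_year_label, academic_year_start_series, anniversary_series
from .codelist import (
    ICD10,
    CodeList,
    SUBGROUP_ELBW,
    SUBGROUP_EXTREME_PREMATURITY,
    default_codelist,
)
from .sen import NEED_BY_SUBGROUP

logger = logging.getLogger("neurophen.synthetic")

MATERNAL_AGE_BANDS = ("<20", "20-24", "25-29", "30-34", "35-39")

_NOISE_ICD = ["J069", "A099", "R509", "J459", "K529", "B349", "L209", "N390", "R104"]
_NOISE_OPCS = ["X292", "E851", "W903", "U051"]
_DEATH_NOISE_ICD = ["R99", "J189", "A419"]
_BIRTH_EPISODE_CODE = "Z380"

_ELECTIVE = ["11", "12", "13"]
_EMERGENCY = ["21", "22", "23", "24", "25", "2A", "2B"]

#: subgroups whose first record is inherently the birth admission
_BIRTH_DATED_SUBGROUPS = {SUBGROUP_ELBW, SUBGROUP_EXTREME_PREMATURITY}

#: relative weights used to build the default prevalence map (echoing the
#: relative frequency of subgroups in hospital records)
_DEFAULT_SUBGROUP_WEIGHTS = {
    "autistic spectrum disorders": 0.0080,
    "developmental disorders": 0.0075,
    "epilepsy": 0.0052,
    "perinatal brain damage": 0.0040,
    "congenital anomalies of cns": 0.0035,
    "hyperkinetic disorders": 0.0026,
    "cerebral palsy": 0.0020,
    "chromosomal anomalies": 0.0020,
    "learning disability": 0.0020,
    "severe birth asphyxia": 0.0015,
    "extreme prematurity": 0.0012,
    "hearing impairment diagnosis": 0.0010,
    "inflammatory brain conditions": 0.0010,
    "extremely low birth weight": 0.0008,
    "neuromuscular disorders": 0.0006,
    "hydrocephalus": 0.0006,
    "bilateral visual impairment": 0.0004,
    "cns tumours": 0.0004,
}


def default_subgroup_prevalence(total: float = 0.036) -> dict[str, float]:
    """Scale the default subgroup weights so their independent union equals
    ``total`` (the configured overall phenotype prevalence)."""
    w = np.array(list(_DEFAULT_SUBGROUP_WEIGHTS.values()))

    def union_minus_target(s):
        return 1.0 - np.prod(1.0 - s * w) - total

    scale = brentq(union_minus_target, 0.0, 1.0 / w.max() - 1e-9)
    return {k: float(scale * v) for k, v in _DEFAULT_SUBGROUP_WEIGHTS.items()}


class GeneratorConfig(BaseModel):
    """All the dials of the synthetic world; defaults are the study conditions."""

    n_children: int = Field(gt=0)
    seed: int = 0
    birth_window: tuple[dt.date, dt.date] = (dt.date(2003, 9, 1), dt.date(2009, 8, 31))
    subgroup_prevalence: dict[str, float] = Field(default_factory=default_subgroup_prevalence)
    admission_rate_baseline: dict[str, float] = Field(
        default_factory=lambda: {"planned": 3.42, "unplanned": 6.48}
    )
    admission_rate_multiplier: dict[str, float] = Field(
        default_factory=lambda: {"planned": 10.0, "unplanned": 4.8}
    )
    mortality_risk: dict[str, float] = Field(
        default_factory=lambda: {"phenotype": 0.061, "none": 0.003}
    )
    death_age_weights: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {"phenotype": (0.70, 0.17, 0.13), "none": (0.86, 0.10, 0.04)}
    )
    age_at_first_record_weights: tuple[float, float] = (2 / 3, 1 / 3)
    sen_probability: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "phenotype": {"any": 0.755, "support": 0.552, "ehcp": 0.395},
            "none": {"any": 0.303, "support": 0.298, "ehcp": 0.024},
        }
    )
    sen_need_concordance: float = 0.7
    sen_base_need_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "speech-language-communication": 0.35,
            "moderate learning difficulty": 0.25,
            "other": 0.15,
            "autistic spectrum disorder": 0.08,
            "learning disability": 0.05,
            "physical disability": 0.05,
            "hearing impairment": 0.03,
            "visual impairment": 0.02,
        }
    )
    p_school_linked: float = 0.86
    p_enrolled: float = 0.97
    p_reception: float = 0.95
    p_birth_admission: float = 0.98
    birth_los_mean: dict[str, float] = Field(
        default_factory=lambda: {"phenotype": 11.0, "none": 2.5}
    )
    los_mean_days: float = 2.0
    p_transfer: float = 0.08
    p_death_cause_only: float = 0.05
    missingness: dict[str, float] = Field(
        default_factory=lambda: {
            "sex": 0.003,
            "gestational_age_weeks": 0.306,
            "birthweight_g": 0.215,
            "maternal_age_band": 0.033,
        }
    )

    @field_validator("subgroup_prevalence", "missingness")
    @classmethod
    def _probs_in_unit_interval(cls, v):
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {k!r} outside [0, 1]: {p}")
        return v

    @field_validator("admission_rate_baseline", "admission_rate_multiplier")
    @classmethod
    def _rates_nonnegative(cls, v):
        for k, r in v.items():
            if r < 0:
                raise ValueError(f"negative rate for {k!r}: {r}")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.birth_window[0] >= self.birth_window[1]:
            raise ValueError("birth_window start must precede end")
        for status, p in self.sen_probability.items():
            overlap = p["support"] + p["ehcp"] - p["any"]
            if overlap < 0 or p["ehcp"] - overlap < 0 or p["any"] - p["ehcp"] < 0:
                raise ValueError(f"inconsistent SEN probabilities for {status!r}")
        return self

    def expected_prevalence(self) -> float:
        """Phenotype prevalence implied by independent subgroup assignment."""
        return float(1.0 - np.prod([1.0 - p for p in self.subgroup_prevalence.values()]))


def _geometric_days(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Geometric (number of failures) lengths of stay with the given mean."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    p = 1.0 / (1.0 + mean)
    return (rng.geometric(p, size=size) - 1).astype(np.int64)


def _sample_subgroup_code(rng: np.random.Generator, codelist: CodeList, subgroup: str) -> tuple[str, str]:
    """(system, observed code) for one subgroup; 3-char list entries gain a
    random final digit, as recorded hospital codes are 4-character."""
    entries = codelist.entries_for(subgroup)
    e = entries[int(rng.integers(len(entries)))]
    code = e.code
    if e.match_mode == "prefix" and len(code) == 3:
        code = code + str(int(rng.integers(10)))
    return e.system, code


def _sample_subgroup_icd(rng: np.random.Generator, codelist: CodeList, subgroup: str) -> str | None:
    icd = [e for e in codelist.entries_for(subgroup) if e.system == ICD10]
    if not icd:
        return None
    e = icd[int(rng.integers(len(icd)))]
    return e.code + str(int(rng.integers(10))) if len(e.code) == 3 else e.code


def _ga_weights() -> np.ndarray:
    """Gestational-age distribution for children without extreme prematurity
    (weeks 27..42)."""
    w = np.array(
        [0.001, 0.001, 0.001, 0.001, 0.002,  # 27-31
         0.004, 0.005, 0.008, 0.012, 0.020,  # 32-36
         0.06, 0.16, 0.30, 0.28, 0.10, 0.045]  # 37-42
    )
    return w / w.sum()


def generate(config: GeneratorConfig, codelist: CodeList | None = None) -> dict[str, pd.DataFrame]:
    """Generate the four linked tables; deterministic for a fixed seed."""
    codelist = codelist or default_codelist()
    unknown = set(config.subgroup_prevalence) - codelist.subgroups
    if unknown:
        raise ValueError(f"subgroups not in the code list: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    n = config.n_children
    pid = np.array([f"P{i:07d}" for i in range(n)])

    # --- births -----------------------------------------------------------
    start = pd.Timestamp(config.birth_window[0])
    span = (pd.Timestamp(config.birth_window[1]) - start).days + 1
    birth = pd.Series(start + pd.to_timedelta(rng.integers(0, span, size=n), unit="D"))
    d1 = (anniversary_series(birth, 1) - birth).dt.days.to_numpy()
    d5 = (anniversary_series(birth, 5) - birth).dt.days.to_numpy()
    d11 = (anniversary_series(birth, 11) - birth).dt.days.to_numpy()

    # --- subgroup assignment ---------------------------------------------
    subgroups = sorted(config.subgroup_prevalence)
    prev = np.array([config.subgroup_prevalence[s] for s in subgroups])
    assigned = (
        rng.random((n, len(subgroups))) < prev
        if subgroups
        else np.zeros((n, 0), dtype=bool)
    )
    flagged = assigned.any(axis=1)
    idx_of = {s: j for j, s in enumerate(subgroups)}

    def _has(subgroup):
        j = idx_of.get(subgroup)
        return assigned[:, j] if j is not None else np.zeros(n, dtype=bool)

    is_ep = _has(SUBGROUP_EXTREME_PREMATURITY)
    is_elbw = _has(SUBGROUP_ELBW)

    # --- patient characteristics -----------------------------------------
    sex = pd.Series(np.where(rng.random(n) < 0.512, "male", "female"), dtype="string")
    sex[rng.random(n) < config.missingness["sex"]] = pd.NA

    ga = np.where(
        is_ep,
        rng.integers(23, 27, size=n),
        rng.choice(np.arange(27, 43), size=n, p=_ga_weights()),
    )
    ga = pd.array(ga, dtype="Int64")
    ga[rng.random(n) < config.missingness["gestational_age_weeks"]] = pd.NA

    bw = np.where(
        is_elbw,
        rng.integers(500, 1000, size=n),
        np.clip(rng.normal(3400, 500, size=n), 1000, 5500).astype(int),
    )
    bw = pd.array(bw, dtype="Int64")
    bw[rng.random(n) < config.missingness["birthweight_g"]] = pd.NA

    mat = pd.Series(
        rng.choice(MATERNAL_AGE_BANDS, size=n, p=[0.070, 0.201, 0.272, 0.290, 0.167]),
        dtype="string",
    )
    mat[rng.random(n) < config.missingness["maternal_age_band"]] = pd.NA

    patients = pd.DataFrame(
        {
            "patient_id": pd.array(pid, dtype="string"),
            "birth_date": birth,
            "sex": sex,
            "gestational_age_weeks": ga,
            "birthweight_g": bw,
            "maternal_age_band": mat,
        }
    )

    # --- deaths (timing first; admissions stop at death) ------------------
    p_death = np.where(flagged, config.mortality_risk["phenotype"], config.mortality_risk["none"])
    died = rng.random(n) < p_death
    death_day = np.full(n, -1, dtype=np.int64)
    for status, mask in (("phenotype", died & flagged), ("none", died & ~flagged)):
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            continue
        band = rng.choice(3, size=rows.size, p=np.array(config.death_age_weights[status]))
        lo = np.select([band == 0, band == 1, band == 2], [np.zeros(rows.size), d1[rows], d5[rows]])
        hi = np.select([band == 0, band == 1, band == 2], [d1[rows], d5[rows], d11[rows]])
        death_day[rows] = (lo + np.floor(rng.random(rows.size) * (hi - lo))).astype(np.int64)
    end_day = np.where(died, death_day, d11)

    # --- birth admissions -------------------------------------------------
    has_birth_adm = rng.random(n) < config.p_birth_admission
    birth_rows = np.flatnonzero(has_birth_adm)
    birth_los = np.where(
        flagged[birth_rows],
        _geometric_days(rng, config.birth_los_mean["phenotype"], birth_rows.size),
        _geometric_days(rng, config.birth_los_mean["none"], birth_rows.size),
    ).astype(np.int64)
    birth_diag: dict[int, list[str]] = {int(i): [_BIRTH_EPISODE_CODE] for i in birth_rows}
    birth_proc: dict[int, list[str]] = {int(i): [] for i in birth_rows}

    # renewal start: the day after birth-spell discharge (no admission can
    # begin while the child is still in their birth admission)
    pos0 = np.zeros(n, dtype=np.int64)
    pos0[birth_rows] = birth_los + 1

    # --- background admissions: renewal process in at-risk days -----------
    # Per at-risk day the admission hazard is q, chosen so that the expected
    # number of admissions per at-risk day equals the configured rate
    # (baseline x multiplier), accounting for days removed by the geometric
    # stays themselves.
    p0_los = 1.0 / (1.0 + config.los_mean_days)  # P(length of stay = 0)
    rate_p = config.admission_rate_baseline["planned"] / 100.0 / 365.25
    rate_u = config.admission_rate_baseline["unplanned"] / 100.0 / 365.25

    bg_child: list[np.ndarray] = []
    bg_day: list[np.ndarray] = []
    bg_los: list[np.ndarray] = []
    bg_planned: list[np.ndarray] = []
    for status, mask in (("phenotype", flagged), ("none", ~flagged)):
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            continue
        mult_p = config.admission_rate_multiplier["planned"] if status == "phenotype" else 1.0
        mult_u = config.admission_rate_multiplier["unplanned"] if status == "phenotype" else 1.0
        lam_p, lam_u = rate_p * mult_p, rate_u * mult_u
        lam = lam_p + lam_u
        if lam <= 0:
            continue
        q = lam / (1.0 + lam * (1.0 - p0_los))
        mean_events = lam * 11 * 365.25
        k_max = int(mean_events + 6 * np.sqrt(mean_events) + 10)
        gaps = (rng.geometric(q, size=(rows.size, k_max)) - 1).astype(np.int64)
        los = _geometric_days(rng, config.los_mean_days, rows.size * k_max).reshape(rows.size, k_max)
        occupy = gaps + np.maximum(los, 1)
        s = pos0[rows, None] + np.cumsum(occupy, axis=1) - np.maximum(los, 1)
        valid = s < end_day[rows, None]
        r_idx, k_idx = np.nonzero(valid)
        bg_child.append(rows[r_idx])
        bg_day.append(s[r_idx, k_idx])
        bg_los.append(los[r_idx, k_idx])
        bg_planned.append(rng.random(r_idx.size) < lam_p / lam)
    bg_child = np.concatenate(bg_child) if bg_child else np.zeros(0, dtype=np.int64)
    bg_day = np.concatenate(bg_day) if bg_day else np.zeros(0, dtype=np.int64)
    bg_los = np.concatenate(bg_los) if bg_los else np.zeros(0, dtype=np.int64)
    bg_planned = np.concatenate(bg_planned) if bg_planned else np.zeros(0, dtype=bool)

    # noise codes for background admissions
    bg_diag = [[c] for c in rng.choice(_NOISE_ICD, size=bg_child.size)]
    second = rng.random(bg_child.size) < 0.5
    extra = rng.choice(_NOISE_ICD, size=bg_child.size)
    for k in np.flatnonzero(second):
        bg_diag[k].append(extra[k])
    bg_proc: list[list[str]] = [[] for _ in range(bg_child.size)]
    has_proc = bg_planned & (rng.random(bg_child.size) < 0.3)
    proc_codes = rng.choice(_NOISE_OPCS, size=bg_child.size)
    for k in np.flatnonzero(has_proc):
        bg_proc[k].append(proc_codes[k])

    # --- plant phenotype evidence ----------------------------------------
    # indices of each child's background admissions, for carrier selection
    order = np.argsort(bg_child, kind="stable")
    bounds = np.searchsorted(bg_child[order], np.arange(n + 1))

    death_cause_only = flagged & died & (rng.random(n) < config.p_death_cause_only)
    deaths_cause: dict[int, list[str]] = {}

    ex_child: list[int] = []
    ex_day: list[int] = []
    ex_los: list[int] = []
    ex_planned: list[bool] = []
    ex_diag: list[list[str]] = []
    ex_proc: list[list[str]] = []

    w_under5 = config.age_at_first_record_weights[0]
    w_total = sum(config.age_at_first_record_weights)
    lam_share_planned = rate_p / (rate_p + rate_u) if (rate_p + rate_u) > 0 else 0.5

    for i in map(int, np.flatnonzero(flagged)):
        child_events = order[bounds[i]:bounds[i + 1]]
        for j in np.flatnonzero(assigned[i]):
            sg = subgroups[int(j)]
            if death_cause_only[i]:
                code = _sample_subgroup_icd(rng, codelist, sg)
                if code:
                    deaths_cause.setdefault(i, []).append(code)
                continue
            if sg in _BIRTH_DATED_SUBGROUPS:
                system, code = _sample_subgroup_code(rng, codelist, sg)
                if has_birth_adm[i]:
                    (birth_diag if system == ICD10 else birth_proc)[i].append(code)
                else:
                    ex_child.append(i); ex_day.append(0)
                    ex_los.append(int(_geometric_days(rng, config.los_mean_days, 1)[0]))
                    ex_planned.append(False)
                    diag, proc = [str(rng.choice(_NOISE_ICD))], []
                    (diag if system == ICD10 else proc).append(code)
                    ex_diag.append(diag); ex_proc.append(proc)
                continue
            under5 = rng.random() < w_under5 / w_total
            lo, hi = (0, min(d5[i], end_day[i])) if under5 else (d5[i], min(d11[i], end_day[i]))
            if hi <= lo:  # the child did not survive into the drawn band
                lo, hi = 0, end_day[i]
            if hi <= lo:  # died on day 0: evidence can only sit on the death record
                code = _sample_subgroup_icd(rng, codelist, sg)
                if code:
                    deaths_cause.setdefault(i, []).append(code)
                continue
            system, code = _sample_subgroup_code(rng, codelist, sg)
            in_band = child_events[(bg_day[child_events] >= lo) & (bg_day[child_events] < hi)]
            if in_band.size:
                k = int(in_band[int(rng.integers(in_band.size))])
                (bg_diag[k] if system == ICD10 else bg_proc[k]).append(code)
            elif lo == 0 and has_birth_adm[i] and rng.random() < 0.5:
                # no admissions in the window: occasionally record at birth
                (birth_diag if system == ICD10 else birth_proc)[i].append(code)
            else:
                ex_child.append(i)
                ex_day.append(int(lo + rng.integers(hi - lo)))
                ex_los.append(int(_geometric_days(rng, config.los_mean_days, 1)[0]))
                ex_planned.append(bool(rng.random() < lam_share_planned))
                diag, proc = [str(rng.choice(_NOISE_ICD))], []
                (diag if system == ICD10 else proc).append(code)
                ex_diag.append(diag); ex_proc.append(proc)

    # --- assemble admissions ---------------------------------------------
    all_child = np.concatenate([bg_child, np.array(ex_child, dtype=np.int64), birth_rows])
    all_day = np.concatenate([bg_day, np.array(ex_day, dtype=np.int64), np.zeros(birth_rows.size, dtype=np.int64)])
    all_los = np.concatenate([bg_los, np.array(ex_los, dtype=np.int64), birth_los])
    all_planned = np.concatenate([bg_planned, np.array(ex_planned, dtype=bool), np.zeros(birth_rows.size, dtype=bool)])
    all_birthflag = np.concatenate(
        [np.zeros(bg_child.size, bool), np.zeros(len(ex_child), bool), np.ones(birth_rows.size, bool)]
    )
    all_diag = bg_diag + ex_diag + [birth_diag[int(i)] for i in birth_rows]
    all_proc = bg_proc + ex_proc + [birth_proc[int(i)] for i in birth_rows]

    methods = np.where(
        all_birthflag,
        "82",
        np.where(
            all_planned,
            rng.choice(_ELECTIVE, size=all_child.size),
            rng.choice(_EMERGENCY, size=all_child.size),
        ),
    )

    adm = pd.DataFrame(
        {
            "child": all_child,
            "day": all_day,
            "los": all_los,
            "admission_method_code": methods,
            "diagnosis_codes": [";".join(d) for d in all_diag],
            "procedure_codes": [";".join(p) for p in all_proc],
            "is_birth_admission": all_birthflag,
        }
    )
    child_end = end_day[adm["child"].to_numpy()]
    child_died = died[adm["child"].to_numpy()]
    disch = (adm["day"] + adm["los"]).to_numpy()
    adm["disch"] = np.where(child_died, np.minimum(disch, child_end), disch)

    # transfers: split eligible stays so the second admission starts on the
    # first one's discharge date
    stay = (adm["disch"] - adm["day"]).to_numpy()
    split = (rng.random(len(adm)) < config.p_transfer) & (stay >= 2)
    cut_frac = rng.random(len(adm))
    keep = adm[~split].copy()
    s = adm[split].copy()
    if len(s):
        cut = (s["day"] + 1 + np.floor(cut_frac[split] * (s["disch"] - s["day"] - 1))).astype(np.int64)
        first_half = s.copy()
        first_half["disch"] = cut
        second_half = s.copy()
        second_half["day"] = cut
        second_half["admission_method_code"] = "81"
        second_half["is_birth_admission"] = False
        adm = pd.concat([keep, first_half, second_half], ignore_index=True)
    else:
        adm = keep

    adm = adm.sort_values(["child", "day", "disch"], kind="mergesort").reset_index(drop=True)
    child = adm["child"].to_numpy()
    adm_birth_ts = pd.to_datetime(birth.to_numpy()[child])
    admissions = pd.DataFrame(
        {
            "admission_id": pd.array([f"A{i:08d}" for i in range(len(adm))], dtype="string"),
            "patient_id": pd.array(pid[child], dtype="string"),
            "admission_date": adm_birth_ts + pd.to_timedelta(adm["day"].to_numpy(), unit="D"),
            "discharge_date": adm_birth_ts + pd.to_timedelta(adm["disch"].to_numpy(), unit="D"),
            "admission_method_code": pd.array(adm["admission_method_code"], dtype="string"),
            "diagnosis_codes": pd.array(adm["diagnosis_codes"], dtype="string"),
            "procedure_codes": pd.array(adm["procedure_codes"], dtype="string"),
            "is_birth_admission": adm["is_birth_admission"].astype(bool),
        }
    )
    death_ts = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")
    death_rows = np.flatnonzero(died)
    death_ts[death_rows] = birth.to_numpy()[death_rows] + death_day[death_rows] * np.timedelta64(1, "D").astype("timedelta64[ns]")
    adm_death = death_ts[child]
    admissions["died_in_hospital"] = (
        died[child]
        & (admissions["admission_date"].to_numpy() <= adm_death)
        & (admissions["discharge_date"].to_numpy() >= adm_death)
    )

    # --- death records ----------------------------------------------------
    causes = []
    for i in map(int, death_rows):
        cc = [_DEATH_NOISE_ICD[int(rng.integers(len(_DEATH_NOISE_ICD)))]]
        cc += deaths_cause.get(i, [])
        if flagged[i] and i not in deaths_cause and rng.random() < 0.5:
            js = np.flatnonzero(assigned[i])
            sg = subgroups[int(js[int(rng.integers(js.size))])]
            code = _sample_subgroup_icd(rng, codelist, sg)
            if code:
                cc.append(code)
        causes.append(";".join(cc))
    deaths = pd.DataFrame(
        {
            "patient_id": pd.array(pid[death_rows], dtype="string"),
            "death_date": pd.to_datetime(death_ts[death_rows]),
            "cause_codes": pd.array(causes, dtype="string"),
        }
    )

    # --- school records ---------------------------------------------------
    school = _generate_school(config, rng, pid, birth, death_ts, flagged, assigned, subgroups)

    return {"patients": patients, "admissions": admissions, "deaths": deaths, "school": school}


def _generate_school(config, rng, pid, birth, death_ts, flagged, assigned, subgroups):
    n = len(pid)
    linked = rng.random(n) < config.p_school_linked

    # ever-SEN category per child
    cat = np.full(n, "none", dtype=object)
    s1 = np.zeros(n, dtype=np.int64)
    s2 = np.full(n, 7, dtype=np.int64)
    for status, mask in (("phenotype", flagged), ("none", ~flagged)):
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            continue
        p = config.sen_probability[status]
        overlap = p["support"] + p["ehcp"] - p["any"]
        probs = np.array([1 - p["any"], p["any"] - p["ehcp"], overlap, p["ehcp"] - overlap])
        probs = np.clip(probs, 0, None)
        probs = probs / probs.sum()
        draw = rng.choice(4, size=rows.size, p=probs)
        cat[rows] = np.array(["none", "support_only", "ehcp_with_support", "ehcp_only"], dtype=object)[draw]
    rows = np.flatnonzero(cat == "support_only")
    s1[rows] = rng.integers(0, 4, size=rows.size)
    rows = np.flatnonzero(cat == "ehcp_with_support")
    s1[rows] = rng.integers(0, 3, size=rows.size)
    s2[rows] = s1[rows] + 1 + rng.integers(0, np.maximum(1, 4 - s1[rows]))
    rows = np.flatnonzero(cat == "ehcp_only")
    s1[rows] = 7
    s2[rows] = rng.integers(0, 5, size=rows.size)

    # school-recorded need per child (used in provision years)
    base_needs = sorted(config.sen_base_need_weights)
    base_w = np.array([config.sen_base_need_weights[k] for k in base_needs])
    base_w = base_w / base_w.sum()
    need = np.array(rng.choice(base_needs, size=n, p=base_w), dtype=object)
    mapped_cols = [j for j, sg in enumerate(subgroups) if sg in NEED_BY_SUBGROUP]
    for i in np.flatnonzero(flagged):
        hits = [j for j in mapped_cols if assigned[i, j]]
        if hits and rng.random() < config.sen_need_concordance:
            need[i] = NEED_BY_SUBGROUP[subgroups[int(hits[0])]]

    ay_birth = academic_year_start_series(birth).to_numpy()
    rows_out = []
    for g, label in enumerate(["R", "1", "2", "3", "4", "5", "6"]):
        start_year = ay_birth + 5 + g
        start = pd.to_datetime(pd.DataFrame({"year": start_year, "month": 9, "day": 1})).to_numpy()
        alive = pd.isna(death_ts) | (death_ts > start)
        p_enrol = config.p_reception if g == 0 else config.p_enrolled
        enrolled = linked & alive & (rng.random(n) < p_enrol)
        idx = np.flatnonzero(enrolled)
        if idx.size == 0:
            continue
        level = np.full(idx.size, "none", dtype=object)
        c = cat[idx]
        level[(c == "support_only") & (g >= s1[idx])] = "support"
        level[(c == "ehcp_with_support") & (g >= s1[idx]) & (g < s2[idx])] = "support"
        level[(c == "ehcp_with_support") & (g >= s2[idx])] = "ehcp"
        level[(c == "ehcp_only") & (g >= s2[idx])] = "ehcp"
        year_need = np.where(level == "none", "none", need[idx])
        rows_out.append(
            pd.DataFrame(
                {
                    "patient_id": pid[idx],
                    "academic_year": [academic_year_label(y) for y in start_year[idx]],
                    "year_group": label,
                    "sen_level": level,
                    "primary_need": year_need,
                }
            )
        )
    if not rows_out:
        return pd.DataFrame(
            columns=["patient_id", "academic_year", "year_group", "sen_level", "primary_need"]
        ).astype("string")
    school = pd.concat(rows_out, ignore_index=True)
    school = school.sort_values(["patient_id", "year_group"], kind="mergesort").reset_index(drop=True)
    for c in ("patient_id", "academic_year", "year_group", "sen_level", "primary_need"):
        school[c] = school[c].astype("string")
    return school


# ---------------------------------------------------------------------------
# Dataset round-trip
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "patients": ["patient_id", "birth_date", "sex", "gestational_age_weeks", "birthweight_g", "maternal_age_band"],
    "admissions": [
        "admission_id", "patient_id", "admission_date", "discharge_date",
        "admission_method_code", "diagnosis_codes", "procedure_codes",
        "is_birth_admission", "died_in_hospital",
    ],
    "deaths": ["patient_id", "death_date", "cause_codes"],
    "school": ["patient_id", "academic_year", "year_group", "sen_level", "primary_need"],
}
_DATE_COLS = {"birth_date", "admission_date", "discharge_date", "death_date"}
_INT_COLS = {"gestational_age_weeks", "birthweight_g"}
_BOOL_COLS = {"is_birth_admission", "died_in_hospital"}
# code-list columns keep "" for "no codes" (distinct from a missing value)
_CODE_COLS = {"diagnosis_codes", "procedure_codes", "cause_codes"}


def write_datasets(datasets: dict[str, pd.DataFrame], directory: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV (ISO dates, empty string = missing)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, schema in _SCHEMAS.items():
        df = datasets[name][schema].copy()
        for c in schema:
            if c in _DATE_COLS:
                df[c] = pd.to_datetime(df[c]).dt.strftime("%Y-%m-%d")
            elif c in _BOOL_COLS:
                df[c] = df[c].map({True: "true", False: "false"})
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_datasets(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the four tables back; inverse of :func:`write_datasets`."""
    directory = Path(directory)
    out = {}
    for name, schema in _SCHEMAS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing dataset file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for c in schema:
            if c not in df.columns:
                raise ValueError(f"{path}: missing column {c!r}")
            if c in _DATE_COLS:
                df[c] = pd.to_datetime(df[c].replace("", pd.NA), format="%Y-%m-%d")
            elif c in _INT_COLS:
                df[c] = pd.array([int(x) if x != "" else None for x in df[c]], dtype="Int64")
            elif c in _BOOL_COLS:
                bad = ~df[c].isin(["true", "false"])
                if bad.any():
                    raise ValueError(f"{path}: column {c!r} has non-boolean values")
                df[c] = df[c] == "true"
            elif c in _CODE_COLS:
                df[c] = df[c].astype("string")
            else:
                df[c] = df[c].replace("", pd.NA).astype("string")
        out[name] = df[schema]
    return out
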