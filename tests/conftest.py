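import numpy as np
import pandas as pd
import pytest

import neurophen as nc


@pytest.fixture(scope="session")
def codelist():
    return nc.default_codelist()


@pytest.fixture(scope="session")
def small_config():
    return nc.GeneratorConfig(n_children=2000, seed=11)


@pytest.fixture(scope="session")
def small_data(small_config):
    return nc.generate(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_data, codelist):
    """Cohort, phenotype and spells for the shared small synthetic dataset."""
    cohort = nc.build_birth_cohort(small_data["patients"], small_data["deaths"])
    cohort = nc.build_school_cohort(cohort, small_data["school"])
    frames = nc.phenotype_cohort(
        cohort, small_data["admissions"], small_data["deaths"], small_data["patients"], codelist
    )
    spells = nc.link_spells(small_data["admissions"])
    person_time = nc.compute_person_time(cohort, spells)
    return {
        "cohort": cohort,
        "results": frames.results,
        "subgroup_records": frames.subgroup_records,
        "spells": spells,
        "person_time": person_time,
    }


def make_admissions(rows):
    """Admission frame from (patient_id, admission, discharge, method, diag, proc) tuples."""
    recs = []
    for i, r in enumerate(rows):
        recs.append(
            {
                "admission_id": f"A{i}",
                "patient_id": r[0],
                "admission_date": pd.Timestamp(r[1]),
                "discharge_date": pd.Timestamp(r[2]),
                "admission_method_code": r[3] if len(r) > 3 else "21",
                "diagnosis_codes": r[4] if len(r) > 4 else "J069",
                "procedure_codes": r[5] if len(r) > 5 else "",
                "is_birth_admission": r[6] if len(r) > 6 else False,
                "died_in_hospital": False,
            }
        )
    return pd.DataFrame(recs)


def spell_oracle(intervals):
    """Brute-force spell linkage: sort intervals, merge while the next start
    falls on or inside the running interval; returns merged (start, end)."""
    ivs = sorted(intervals)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def person_time_oracle(birth, followup_end, b1, b5, b11, spans):
    """Day-by-day person-time enumeration for one child.

    ``spans`` are (start, end) spell dates; a hospital day is any day d with
    start <= d < end for some spell (date-difference convention).
    Returns {band: (days_total, days_in_hospital)}.
    """
    out = {}
    hosp_days = set()
    for s, e in spans:
        d = s
        while d < e:
            hosp_days.add(d)
            d += pd.Timedelta(days=1)
    for band, lo, hi in (("<1", birth, b1), ("1-4", b1, b5), ("5-10", b5, b11)):
        hi = min(hi, followup_end)
        total = 0
        hosp = 0
        d = lo
        while d < hi:
            total += 1
            if d in hosp_days:
                hosp += 1
            d += pd.Timedelta(days=1)
        out[band] = (total, hosp)
    return out


def random_admission_set(rng, n_admissions, horizon=400):
    """Random (possibly overlapping/contiguous) admission intervals as day offsets."""
    starts = rng.integers(0, horizon, size=n_admissions)
    lengths = rng.integers(0, 15, size=n_admissions)
    return sorted(zip(starts.tolist(), (starts + lengths).tolist()))
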