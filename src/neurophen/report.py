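"""Paper-style output tables, disclosure control and run orchestration.

Produces the characteristics cross-tabulation (by phenotype group, with
explicit Missing categories), the outcome tables, the per-year SEN and
subgroup-incidence figure data, and applies small-cell suppression (counts
below a threshold masked, plus complementary cells that would allow
back-calculation from margins).  Percentages are rounded half-up to 1
decimal place and rates to 2, matching the conventions of the printed
tables.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from ._dates import academic_year_label, academic_year_start_series
from .codelist import default_codelist, load_codelist
from .cohort import DEFAULT_BIRTH_WINDOW, build_birth_cohort, build_school_cohort
from .hospital import (
    GROUPS,
    admission_rates,
    birth_admission_length,
    compute_person_time,
    cumulative_incidence,
    group_membership,
    link_spells,
    mortality_summary,
    subgroup_cumulative_incidence,
)
from .phenotype import phenotype_cohort
from .sen import concordance, sen_by_year, sen_ever_summary
from .synthetic import read_datasets

logger = logging.getLogger("neurophen.report")


def round_half_up(x, decimals: int = 1):
    """Round half away from zero at the displayed precision (paper style)."""
    factor = 10.0 ** decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Within-column percentage as displayed in the output tables."""
    if denominator == 0:
        return float("nan")
    return float(round_half_up(100.0 * numerator / denominator, decimals))


def rate_ratio(rate: float, reference: float, decimals: int = 2) -> float:
    """Rate ratio against the reference group, at displayed precision."""
    if reference == 0:
        return float("nan")
    return float(round_half_up(rate / reference, decimals))


class SuppressionRule(BaseModel):
    """Small-cell disclosure control: counts below ``threshold`` are masked."""

    threshold: int = Field(default=10, ge=0)
    token: str = "<10"

    def model_post_init(self, __context):
        if self.token == "<10" and self.threshold != 10:
            object.__setattr__(self, "token", f"<{self.threshold}")


def apply_suppression(table: pd.DataFrame, rule: SuppressionRule | None = None) -> pd.DataFrame:
    """Mask small counts, then complementary cells.

    ``table`` is a counts table (rows = categories, columns = groups) whose
    row and column totals are considered public.  Primary suppression masks
    cells with 0 < n < threshold; secondary suppression masks the smallest
    remaining cell in any row or column left with exactly one masked cell,
    iterating until no masked cell is recoverable from margins.
    """
    rule = rule or SuppressionRule()
    values = table.to_numpy(dtype=float)
    mask = (values > 0) & (values < rule.threshold)
    changed = True
    while changed:
        changed = False
        for axis in (0, 1):
            n_masked = mask.sum(axis=axis)
            for j in np.flatnonzero(n_masked == 1):
                line = values[:, j] if axis == 0 else values[j, :]
                line_mask = mask[:, j] if axis == 0 else mask[j, :]
                if line_mask.all() or len(line) < 2:
                    continue
                candidates = np.flatnonzero(~line_mask)
                pick = candidates[np.argmin(line[candidates])]
                if axis == 0:
                    mask[pick, j] = True
                else:
                    mask[j, pick] = True
                changed = True
    out = table.astype(object).copy()
    out[pd.DataFrame(mask, index=table.index, columns=table.columns)] = rule.token
    return out


# ---------------------------------------------------------------------------
# Characteristics table
# ---------------------------------------------------------------------------

_MONTH_PAIRS = [
    ((9, 10), "Sep-Oct"), ((11, 12), "Nov-Dec"), ((1, 2), "Jan-Feb"),
    ((3, 4), "Mar-Apr"), ((5, 6), "May-Jun"), ((7, 8), "Jul-Aug"),
]
_GESTATION_BANDS = [(23, 26, "23-26"), (27, 31, "27-31"), (32, 36, "32-36"), (37, 40, "37-40"), (41, 99, ">=41")]
_BIRTHWEIGHT_BANDS = [(0, 999, "<1000"), (1000, 2499, "1000-2499"), (2500, 3499, "2500-3499"), (3500, 4499, "3500-4499"), (4500, 99999, ">=4500")]


def _band(series: pd.Series, bands) -> pd.Series:
    out = pd.Series("Missing", index=series.index, dtype=object)
    x = pd.to_numeric(series, errors="coerce")
    for lo, hi, label in bands:
        out[(x >= lo) & (x <= hi)] = label
    return out


def characteristics_table(
    cohort: pd.DataFrame, results: pd.DataFrame, patients: pd.DataFrame
) -> pd.DataFrame:
    """Cross-tabulation of birth characteristics by phenotype group.

    Rows: sex, month-of-birth pairs, academic year of birth, gestational-age
    bands, birthweight bands, maternal-age bands — each with an explicit
    Missing category.  Columns: the four comparison groups.  Percentages are
    within-column, half-up to 1 dp.
    """
    df = cohort[["patient_id", "birth_date"]].merge(
        patients.drop(columns=["birth_date"], errors="ignore"), on="patient_id"
    )

    chars = {}
    sex = df["sex"].astype(object)
    chars["sex"] = sex.map({"male": "Boys", "female": "Girls"}).fillna("Missing")
    month = pd.to_datetime(df["birth_date"]).dt.month
    mp = pd.Series("Missing", index=df.index, dtype=object)
    for (m1, m2), label in _MONTH_PAIRS:
        mp[(month == m1) | (month == m2)] = label
    chars["month_of_birth"] = mp
    chars["year_of_birth"] = academic_year_start_series(df["birth_date"]).map(academic_year_label)
    chars["gestational_age"] = _band(df["gestational_age_weeks"], _GESTATION_BANDS)
    chars["birthweight"] = _band(df["birthweight_g"], _BIRTHWEIGHT_BANDS)
    mat = df["maternal_age_band"].astype(object)
    chars["maternal_age"] = mat.where(mat.notna() & (mat != ""), "Missing")

    rows = []
    for group in GROUPS:
        member = group_membership(results, group)
        ids = member[member].index
        in_group = df["patient_id"].isin(set(ids))
        denom = int(in_group.sum())
        for characteristic, values in chars.items():
            counts = values[in_group].value_counts()
            for category in values.unique():
                k = int(counts.get(category, 0))
                rows.append(
                    {
                        "characteristic": characteristic,
                        "category": category,
                        "group": group,
                        "n": k,
                        "pct": round_half_up(100 * k / denom, 1) if denom else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def characteristics_counts(table: pd.DataFrame, characteristic: str) -> pd.DataFrame:
    """Pivot one characteristic of :func:`characteristics_table` into a
    counts matrix (categories x groups), ready for suppression."""
    sub = table[table["characteristic"] == characteristic]
    return sub.pivot(index="category", columns="group", values="n").fillna(0).astype(int)


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

class RunConfig(BaseModel):
    """End-to-end pipeline configuration."""

    input_dir: Path
    output_dir: Path
    codelist_path: Path | None = None
    seed: int = 0
    birth_window: tuple[dt.date, dt.date] = DEFAULT_BIRTH_WINDOW
    enrolment_rule: str = "expected_year"
    rate_unit: str = "spell"
    death_cause_dating: str = "death_date"
    include_birth_spells: bool = False
    suppression: SuppressionRule = Field(default_factory=SuppressionRule)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write every output table plus a run log.

    Deterministic given the inputs; any stage failure propagates with the
    stage named.  Returns the output tables keyed by name.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("neurophen")
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    try:
        stage = "read_inputs"
        if not Path(config.input_dir).exists():
            raise FileNotFoundError(f"input directory not found: {config.input_dir}")
        data = read_datasets(config.input_dir)
        codelist = (
            load_codelist(config.codelist_path) if config.codelist_path else default_codelist()
        )
        log.info("inputs: %s", {k: len(v) for k, v in data.items()})

        stage = "cohort"
        cohort = build_birth_cohort(data["patients"], data["deaths"], config.birth_window)
        log.info("birth cohort: %d children", len(cohort))
        cohort = build_school_cohort(cohort, data["school"], config.enrolment_rule)
        log.info("school cohort: %d children", int(cohort["in_school_cohort"].sum()))

        stage = "phenotype"
        frames = phenotype_cohort(
            cohort, data["admissions"], data["deaths"], data["patients"], codelist,
            death_cause_dating=config.death_cause_dating,
        )
        results = frames.results
        log.info("phenotype: %d flagged of %d", int(results["flagged"].sum()), len(results))

        stage = "spells"
        spells = link_spells(data["admissions"])
        log.info("spells: %d from %d admissions", len(spells), len(data["admissions"]))

        stage = "person_time"
        person_time = compute_person_time(cohort, spells)

        stage = "incidence"
        incidence = cumulative_incidence(cohort, results)
        sub_incidence = subgroup_cumulative_incidence(cohort, frames.subgroup_records)

        stage = "rates"
        rates = admission_rates(
            spells, person_time, results, cohort,
            unit=config.rate_unit, include_birth=config.include_birth_spells,
        )
        mortality = mortality_summary(cohort, results)
        birth_len = birth_admission_length(cohort, spells, results)

        stage = "sen"
        sen_summary = sen_ever_summary(cohort, data["school"], results)
        sen_years = sen_by_year(cohort, data["school"], results)
        conc = concordance(frames.subgroup_records, cohort, data["school"])

        stage = "report"
        chars = characteristics_table(cohort, results, data["patients"])
        suppressed = {
            name: apply_suppression(characteristics_counts(chars, name), config.suppression)
            for name in chars["characteristic"].unique()
        }
        chars_suppressed = pd.concat(
            [m.assign(characteristic=name).reset_index() for name, m in suppressed.items()],
            ignore_index=True,
        )

        outputs = {
            "cohort": cohort,
            "phenotype": _phenotype_output(results),
            "subgroup_records": frames.subgroup_records,
            "spells": spells,
            "person_time": person_time,
            "incidence": incidence,
            "subgroup_incidence": sub_incidence,
            "rates": rates,
            "mortality": mortality,
            "birth_admission": birth_len,
            "sen_summary": sen_summary,
            "sen_by_year": sen_years,
            "concordance": conc,
            "characteristics": chars,
            "characteristics_suppressed": chars_suppressed,
        }
        for name, df in outputs.items():
            df.to_csv(out_dir / f"{name}.csv", index=False)
        log.info("wrote %d tables to %s", len(outputs), out_dir)
        return outputs
    except Exception as err:
        log.error("pipeline failed at stage %s: %s", stage, err)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()


def _phenotype_output(results: pd.DataFrame) -> pd.DataFrame:
    out = results.copy()
    for c in ("birth_date", "first_record_date"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    return out
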