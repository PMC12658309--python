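# neurophen

Phenotyping hospital-recorded neurodisability in linked child health and
education records.

Neurodisability — autism, learning disability, epilepsy, cerebral palsy,
chromosomal anomalies, severe perinatal conditions and related diagnoses —
affects a few percent of children, who carry disproportionately high rates of
hospital admission, mortality and special educational needs (SEN) provision.
`neurophen` implements an EHR phenotyping algorithm and its downstream cohort
analysis for English-style administrative data: HES-like hospital admission
records (ICD-10 diagnoses, OPCS-4 procedures), ONS-like mortality records and
NPD-like school-census records, linked by patient identifier. Because real
linked records of this kind cannot be redistributed, the package ships a
first-class synthetic-data generator that emulates their statistical
structure, so the entire pipeline is testable end to end.

It is intended for epidemiologists and health-data scientists who want a
tested, reusable reference implementation of this class of analysis, or a
harness for developing against realistic linked-data structure before
touching access-controlled data.

## What it computes

A child in a birth cohort (followed from birth to death or the 11th
birthday) is **phenotype-positive** if a code-list diagnosis or procedure
code appears in any diagnosis position of any admission starting before age
11, in any contributory cause of death, or if structured birth fields record
gestational age < 27 completed weeks or birthweight < 1000 g. Each code maps
to a condition subgroup (e.g. *autistic spectrum disorders* → the
neurodevelopmental category); 3-character list codes match their 4-character
coded children by prefix. The shipped code list is an illustrative
re-derivation of the subgroup taxonomy, not a clinically curated list.

Downstream, per comparison group g (no phenotype as reference; any; first
record at age < 5; at 5–10):

* **Cumulative incidence** by ages 1, 5, 11 — both cases/N and cases per 100
  person-years, with person-years from birth to min(first record, death,
  threshold birthday).
* **Continuous inpatient spells**: admissions starting on a prior discharge
  date (transfers) or nested in another admission are linked transitively;
  spell type (planned/unplanned/birth) comes from the earliest constituent
  admission's method code.
* **Admission rates** per 100 person-years at risk,
  rate = 100 · n_spells(g, band) / PY_at-risk(g, band), where at-risk
  person-time excludes days spent in hospital, and rate ratios vs the
  reference group.
* **Mortality** proportions by age band, **birth-admission length**
  (mean/SD/median/IQR), and the nested **school cohort** (enrolled in Year 1)
  with ever/per-year SEN provision under the hierarchy EHCP > SEN support >
  none, plus hospital-subgroup vs school-need concordance.
* Paper-style tables with small-cell disclosure control (counts < 10
  suppressed, plus complementary cells that margins would otherwise reveal).

## Worked example

```python
import neurophen as nc

cfg = nc.GeneratorConfig(n_children=20_000, seed=42)
data = nc.generate(cfg)

cohort = nc.build_birth_cohort(data["patients"], data["deaths"])
cohort = nc.build_school_cohort(cohort, data["school"])
frames = nc.phenotype_cohort(cohort, data["admissions"], data["deaths"],
                             data["patients"], nc.default_codelist())

inc = nc.cumulative_incidence(cohort, frames.results)
print(inc.round(4).to_string(index=False))

spells = nc.link_spells(data["admissions"])
pt = nc.compute_person_time(cohort, spells)
rates = nc.admission_rates(spells, pt, frames.results, cohort)
top = rates[(rates.age_band == "<11") & (rates.group.isin(["none", "any"]))]
print(top[["group", "admission_type", "rate_per_100py", "rate_ratio"]].round(2).to_string(index=False))
```

prints

```
 age_threshold  n_children  n_cases  proportion  person_years  rate_per_100py
             1       20000      168      0.0084    19854.8282          0.8461
             5       20000      536      0.0268    98209.1691          0.5458
            11       20000      728      0.0364   213961.7851          0.3402
group admission_type  rate_per_100py  rate_ratio
 none        planned            3.35        1.00
 none      unplanned            6.50        1.00
  any        planned           34.55       10.31
  any      unplanned           31.49        4.84
```

3.64 % of the synthetic children are phenotype-positive by age 11 (the
generator's default prevalence is 3.6 %), and their planned and unplanned
admission rates recover the configured rate multipliers of 10 and 4.8 within
Monte-Carlo error. The same objects feed the mortality, birth-admission and
SEN summaries.

The whole analysis also runs from the shell:

```bash
neurophen simulate --n 20000 --seed 42 --out data/
neurophen run --config run.yaml --out results/     # tables + run.log
neurophen codelist validate my_codes.csv
```

where `run.yaml` points at the input directory and sets the analysis
switches (enrolment rule, spell vs admission numerator, suppression
threshold, …).

## Layout

```
src/neurophen/
  codelist.py    # code-list loading, validation, prefix/exact matching
  synthetic.py   # seedable generator for linked patients/admissions/deaths/school
  cohort.py      # birth cohort, follow-up windows, school-cohort exclusions
  phenotype.py   # the phenotyping algorithm itself
  hospital.py    # spell linkage, person-time, incidence, rates, mortality
  sen.py         # SEN provision summaries and concordance
  report.py      # tables, suppression, YAML-driven orchestration
  cli.py         # `neurophen` command group
docs/methods.md  # modelling assumptions, conventions and limitations
```
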