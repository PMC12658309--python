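# Methods

This note records the modelling assumptions, conventions and deliberate
simplifications behind `neurophen`: what the phenotyping and outcome
estimators compute, what the synthetic-data generator does and does not
emulate, and which design choices were genuinely open.

## The phenotype

A child has *hospital-recorded neurodisability* if any of the following
occurs before their 11th birthday:

1. a code-list **diagnosis code** in any diagnosis position of any hospital
   admission (admissions are the unit; the admission start date is the
   record date);
2. a code-list **procedure code** on such an admission;
3. a code-list code among the **causes of death** (underlying or
   contributory), dated at death;
4. a structured birth field showing **gestational age < 27 completed weeks**
   or **birthweight < 1000 g**, dated at birth. Missing fields never
   trigger; the equivalent ICD-10 perinatal codes (P07.x) trigger through
   route 1 as well, whichever occurs.

Each matched code contributes to a condition *subgroup* (34 in the shipped
list) inside one of eight categories (neurodevelopmental, complex
neurologic, inherited/congenital, high-risk brain, visual impairment,
hearing impairment, motor function, perinatal). Per subgroup the earliest
qualifying date is kept; the overall first record is the minimum, and it
assigns the child to the age-at-first-record band **under 5** vs **5–10**
used throughout as the sensitivity split. Where an admission code and a
birth-field trigger tie on the same date, the admission source label wins
(an arbitrary but fixed tie-break; the date is what matters downstream).

Dating death-cause-only evidence at the death date is a choice, not a
necessity; `death_cause_dating="exclude"` drops death-record evidence
entirely for sensitivity work.

The code list is validated on load: closed subgroup/category vocabulary,
normalized codes (uppercase, undotted, 3–5 characters), one category per
subgroup, and collapse of entries shadowed by a shorter prefix entry of the
same subgroup. Prefix matching is the default because hospital records
carry 4-character ICD-10 codes while lists are often written at 3
characters. The shipped list is **illustrative**: it reproduces the
subgroup taxonomy from representative ICD-10 chapters (F70–F79, F80–F84,
F90/F91/F95, G40–G41, G80–G83, Q00–Q07, Q90–Q93, P07, …) and a few OPCS-4
procedures (cerebroventricular shunt, cochlear implant, hearing device),
not the clinically reviewed published list.

## Ages, calendars, person-time

All ages are completed calendar years by birthday anniversary; a 29
February birthday rolls forward to 1 March in non-leap years, so the age
bands < 1, 1–4, 5–10 split at exact anniversaries. Academic years run 1
September–31 August; a child born between 1 September Y and 31 August Y+1
starts Year 1 (first compulsory year) on 1 September Y+6 — the 1 September
of the academic year containing the 6th birthday — and Reception one year
earlier.

Day counting is date-difference: a spell from admission a to discharge d
contributes d − a hospital days, so same-day admissions count as a spell
with zero hospital days. Person-time runs from birth to min(death, 11th
birthday); the at-risk denominator for admission rates additionally
excludes hospital days. Person-years use 365.25 days.

Spell linkage merges an admission into the running spell when it starts on
or before the spell's current end (same-day transfer, nesting, or dirty
overlap — the last merged with a logged warning), transitively; the spell
type (planned / unplanned / birth / other) is classified from the earliest
constituent admission's HES-style method code ("11"–"13" elective,
"21"–"2D" emergency, "82"/"83" birth; configurable). Spells, not raw
admissions, are the rate numerator by default (`unit="admission"` switches),
a spell belongs to the age band of its start date, and birth spells are
excluded from planned/unplanned rates unless requested.

Cumulative incidence is reported twice on purpose: as a proportion of
children (the headline percentages) and as cases per person-years truncated
at the threshold, because the two conventions coexist in this literature.

## School cohort and SEN outcomes

The school cohort applies exclusions in a fixed order — died before the
Year-1 start, no linked school record, not enrolled in Year 1 — so the
reasons partition the excluded set. Enrolment in Year 1 defaults to a
Year-1 record in the child's *expected* academic year; `any_year` accepts
late entry, since administrative data do not distinguish repeaters cleanly.

SEN provision is hierarchical (EHCP > SEN support > none). "Ever" measures
are taken over observed Reception–Year 6 records with Year-1 enrolment as
the denominator; ever-support and ever-EHCP deliberately overlap, while the
highest-ever categories partition each group. Per-year proportions use that
year's enrolment as denominator, which legitimately differs between years.
Concordance maps hospital subgroups to school-recorded primary needs
(autism → autistic spectrum disorder, cerebral palsy → physical disability,
…), with the school categories "severe learning difficulty" and "profound
and multiple learning difficulty" folded into learning disability; the
denominator is subgroup children present in the school cohort, whether or
not they ever received provision.

## The synthetic generator

The generator produces the linked structure the estimators assume, under
configurable study conditions whose defaults echo the magnitudes of this
population: overall phenotype prevalence 0.036 (subgroup probabilities
independent, scaled so their union hits the total exactly), planned and
unplanned baseline rates 3.42 and 6.48 per 100 person-years with phenotype
multipliers 10 and 4.8, death risk by age 11 of 6.1 % vs 0.3 % (age-at-death
weights 0.70/0.17/0.13 vs 0.86/0.10/0.04 over < 1, 1–4, 5–10), SEN
probabilities any/support/EHCP of 0.755/0.552/0.395 vs 0.303/0.298/0.024,
school linkage 0.86 with per-year enrolment 0.97 (0.95 in Reception),
birth-admission probability 0.98 with geometric stays of mean 11 vs 2.5
days, other stays mean 2 days, transfer probability 0.08, missingness
0.3 %/30.6 %/21.5 %/3.3 % for sex, gestational age, birthweight and maternal
age.

Admissions are drawn per child as a **renewal process in at-risk days**: on
each day not spent in hospital the admission hazard is
q = λ/(1 + λ(1 − p₀)), where λ is the target daily rate (baseline ×
multiplier, planned and unplanned pooled and split per event) and p₀ the
probability of a zero-day stay; the correction accounts for the days the
geometric stays themselves remove from the at-risk denominator, so the
pipeline's rate estimator is calibrated to recover the configured rates
without overlap artefacts. Phenotype evidence is attached to an *existing*
admission in the drawn age band (two components: before age 5 with weight
2/3, 5–10 with weight 1/3), so planting evidence does not inflate admission
counts; only when no admission exists in the band is a carrier admission
created (a few percent of cases). The perinatal birth-weight/prematurity
subgroups are instead dated at birth, carried on the birth admission, and
mirrored in the structured fields (gestational age 23–26 weeks, birthweight
500–999 g). A configurable fraction (5 %) of phenotype-positive deaths carry
their evidence only on the death record.

What the generator does **not** emulate, and tests therefore cannot show:
linkage error and false matches; multiple births; migration; correlated
subgroup comorbidity (independence is assumed); children with gestational
age 23–26 weeks outside the prematurity subgroup; age- or period-varying
admission rates and coding depth; month-of-birth rather than exact birth
dates (exact dates are a stated simplification); any school-level variation
in SEN recording. Parameter-recovery results say the estimators invert the
generator, not that real data behave like the generator.

## Numerical and reporting conventions

* Rounding for display is half-up: percentages to 1 dp, rates and rate
  ratios to 2 dp. Internal tables keep full precision.
* Zero person-years in a rate cell yields a missing rate with a log entry;
  a zero reference rate yields a missing ratio.
* Small-cell suppression masks counts 0 < n < 10 (threshold configurable),
  then iteratively masks the smallest remaining cell in any row or column
  left with exactly one masked cell, treating row and column totals as
  public. Zeros are printed, matching the convention of the tables this
  mirrors. This complementary rule is adequate for tables of this size; it
  is not a general cell-suppression optimiser.
* End-to-end runs are deterministic given the input files and seed; the
  run log records row counts at every stage (the cohort flow diagram).

## Problem sizes

The shared unit-test dataset uses 2,000 children; the parameter-recovery
suite and the acceptance script use 50,000 children, at which the full
pipeline runs in well under a minute. Recovery tolerances are three
Monte-Carlo standard errors of the configured quantity (binomial for
proportions, 1/√n on the log scale for rate ratios), with seeds fixed in
the tests.
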