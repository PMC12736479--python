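# pimscreen

Screening of ATC-coded drug-dispensing claims for **potentially
inappropriate medications (PIMs)** in older adults, using an explicit,
machine-readable rendering of the 2019 American Geriatrics Society Beers
Criteria restricted to what dispensing data alone can decide.

It is aimed at pharmacoepidemiologists and health-authority pharmacists who
receive administrative dispensing extracts (one row per reimbursed
dispensation: patient id, birth date, sex, dispensation date, ATC code,
medication name, packages) and want reproducible answers to: *what share of
older adults received at least one PIM each year, which PIMs dominate, and
how large is the chronic anticholinergic burden?*

## What it computes

- **Rule catalog** (`pimscreen.catalog`): PIM rules keyed by ATC prefixes
  (level 1–5), each in a category — drugs to *avoid*, drugs to *use with
  caution* (largely SIADH/hyponatremia risks), and *strong
  anticholinergics* — with an applicability condition. Conditions are the
  operational simplifications claims data force:
  - duration > 8 weeks: consecutive dispensing dates of the drug more than
    56 days apart and within 180 days;
  - concomitant use: co-dispensing of two drug classes within 90 days;
  - chronic use: ≥ 5 dispensing events of one ingredient in a calendar
    year;
  - dose limits: unit dose (explicit column, or parsed from the medication
    name) as a proxy for the unknown daily dose;
  - route/form: keyword parsing of the medication name.
- **Cohort** (`pimscreen.cohort`): eligibility (age ≥ 65 completed years at
  the window end, ≥ 1 dispensation in the window, no death on or before
  the window end) and the 65–74 / 75–84 / ≥ 85 age strata.
- **Detection** (`pimscreen.engine`): at most one `PIMEvent` per
  (patient, rule, year), with deterministic ordering and the triggering
  dispensations attached.
- **Anticholinergic burden** (`pimscreen.burden`): chronic users of strong
  anticholinergics per year and their total Anticholinergic Cognitive
  Burden (ACB) score — every shipped agent scores 3, so two concurrent
  agents total 6 and three total 9.
- **Reports** (`pimscreen.reporting`): crude annual prevalences
  (patients with ≥ 1 PIM over patients with ≥ 1 dispensation), ranked PIM
  frequency tables per category-year, and descriptive sample summaries
  (median [IQR] age, PIM dispensations per patient), all with half-up
  one-decimal percentages.
- **Synthetic claims** (`pimscreen.simulate`): a seeded generator that
  emulates the claims schema and age/sex structure and *injects* dispensing
  patterns constructed to satisfy (or just miss) each rule condition, with
  exact ground-truth labels for end-to-end testing.

## Worked example

```sh
pimscreen simulate --seed 42 --n-patients 1000 --outdir sim
pimscreen run --claims sim/claims.csv --deaths sim/deaths.csv --outdir report
```

prints

```
26999 claims rows, 49 deaths, 645 labelled patient-years -> sim
cohort 951 patients, 828 PIM events -> report
```

`report/prevalence.csv` then starts

```
stratum,year,numerator,denominator,percent
all,2018,165,914,18.1
all,2019,167,908,18.4
all,2020,155,901,17.2
all,2021,158,884,17.9
all,total,534,951,56.2
```

i.e. 165 of the 914 older adults dispensed anything in 2018 received at
least one PIM that year (18.1%), and 56.2% of the cohort did at some point
in 2018–2021. `report/ranks.csv` gives the per-category league table —
with the default generator, long-term proton-pump-inhibitor use ranks
first among drugs to avoid:

```
year,category,rank,label,n_patients,percent
2018,AVOID,1,PPI,70,58.3
2018,AVOID,2,Paroxetine,26,21.7
```

and `report/chronic_anticholinergics.csv` lists each chronic
anticholinergic user with their agent set and summed ACB score.

The same analysis runs on real extracts: point `--claims`/`--deaths` at
your CSV files (column layout in `pimscreen.io`), optionally with
`--catalog` for a customized rule file (`pimscreen validate-catalog FILE`
checks one) and `--config` for dialect/window settings.

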