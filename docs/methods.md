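# Methods

## The screening model

The package implements explicit-criteria screening of dispensing claims:
a catalog of PIM rules, each a set of ATC prefixes plus an applicability
condition, is evaluated against every eligible patient's dispensing
history, one calendar year at a time. The unit of observation is the
reimbursed dispensation, not the prescription: indications, prescribed
doses and treatment durations are unknown, so every rule condition is an
operational proxy stated purely in terms of dispensation dates, ATC codes,
unit strengths and name text. The output is interpreted accordingly —
*potentially* inappropriate exposure, a prescriber-alert signal, not a
clinical judgment. Criteria that require diagnoses, laboratory values or
drug–drug interaction severity are deliberately absent from the shipped
catalog.

## Operational definitions and their parameters

| definition | default | meaning |
|---|---|---|
| duration > 8 weeks | gap > 56 d and ≤ 180 d | a pair of *consecutive* dispensing dates of the drug more than 56 days apart but within 180 days signals use extending beyond an 8-week course |
| co-dispensing window | 90 d | two drug classes dispensed within 3 months count as concomitant |
| chronic use | ≥ 5 events/calendar year | per ingredient (ATC level 5), distinct dates |
| dose limit | unit dose > threshold (mg) | the strength of one dose unit proxies the daily dose |
| eligibility age | 65 completed years at window end | patients turning 65 inside the window are included |
| study window | 2018-01-01 – 2021-12-31 | calendar years are the reporting unit |

Points where the definitions are deliberately literal:

- The duration screen is **pairwise on consecutive dates** — no episode
  construction with grace periods, which is the common alternative in
  drug-utilization research. Episode merging would count a chain of
  50-day refill gaps as long-term use; the pairwise screen does not.
  The brute-force oracle in the test suite pins exactly this semantics.
- Gap bounds are strict below (a 56-day gap does not qualify) and
  inclusive above (a 180-day gap does).
- Same-day duplicate rows of one ingredient collapse to a single
  dispensing *event* for gap and chronicity counting; pack-level
  duplication would otherwise inflate chronic-use counts. Raw rows are
  kept in the event's trigger list.
- Year attribution: a duration event belongs to the year of the **later**
  date of a qualifying pair; a co-dispensing event to the year of the
  **index** (rule-drug) date; chronic use to the year in which the count
  is reached. One event at most per (patient, rule, year).
- A missing unit dose makes a dose rule indeterminate for that row: the
  row is skipped and logged, never guessed.
- Age arithmetic is completed-years by birthday anniversary; a Feb-29
  birthday completes on Feb 28 in non-leap years (the `dateutil`
  convention).
- Yearly prevalence denominators include every eligible patient with a
  dispensation that calendar year, even if they turned 65 only later in
  the window; eligibility and age strata are fixed once, at the window
  end. This mirrors a single end-of-study age computation and avoids
  per-year re-stratification.

## The catalog

The shipped catalog (`data/default_catalog.yaml`,
`beers-2019-dispensing-v1`) renders the dispensing-decidable subset of the
2019 Beers Criteria: AVOID rules (long-term PPIs, paroxetine,
sulfonylureas, chronic NSAID use, NSAID + systemic corticosteroid
co-dispensing, amiodarone, tricyclic antidepressants, ticlopidine),
CAUTION rules (loop and minor diuretics and their potassium-sparing
associations, aldosterone antagonists, hydrochlorothiazide, tramadol,
mirtazapine, antipsychotics, aspirin above 325 mg unit dose) and eight
strong anticholinergics, all with ACB score 3. Ticlopidine is retained as
AVOID even though the 2019 US list dropped it: the removal reflected US
market withdrawal, and the drug remains marketed and reimbursed in Italy.
The NSAID + corticosteroid rule is this package's operationalization of
the concomitant-use qualifier on non-COX-selective NSAIDs; window and
thresholds are catalog parameters, so a site can swap its own rendering —
the catalog is data, not code, and `pimscreen validate-catalog` checks a
file against the schema (unique rule ids, ATC prefixes cut at level
boundaries, known condition variants).

ATC prefix matching encodes drug classes (e.g. `A10BB` covers all
sulfonylureas); the ACB lookup resolves by longest prefix so an ingredient
can override its class score. Reporting groups class rules at ATC level 4,
so rank tables aggregate drugs with the same mechanism of action.

"PIMs per patient" in the sample summary counts distinct trigger
dispensations (date × ingredient) across a patient's events, not distinct
rules — the convention that makes the statistic track dispensing volume
rather than catalog granularity.

Percentages print with half-up rounding at one decimal everywhere.
Quartiles use linear interpolation between order statistics (numpy's
default); Tukey hinges would differ on small samples, and the tests use
the interpolation convention throughout. One known irreproducibility in
published tables of this kind is a yearly percentage whose denominator is
neither the year's sample nor the stratum total; such cells are excluded
from the checks here.

## The synthetic-data generator

`pimscreen.simulate` emulates the structure the screen assumes in real
claims, with defaults chosen as the study conditions: ages triangular on
[65, 100] with mode 73 (median ≈ 77), 40% male, 5% in-window mortality,
a 2018–2021 window, chronic background therapy (statin, ACE inhibitor)
as 5–8 roughly monthly dispensations per year and sporadic background
drugs as Poisson counts — all background ingredients chosen outside the
catalog so they can never fire a rule. Injection patterns place dates
that satisfy a rule condition *by construction* (e.g. two PPI dates 60–170
days apart; 5–8 monthly paroxetine dates; an NSAID date within 60 days of
a corticosteroid date), or deliberately just miss it (two PPI dates ≤ 56
days apart; exactly 4 NSAID dates in a year). Injection probabilities
default to a PPI-dominant mix (0.30 PPI long-term, 0.20 furosemide, 0.10
chronic paroxetine, 0.05 each sulfonylureas and NSAID+corticosteroid,
0.02 each ticlopidine and multi-anticholinergic), which yields a total
PIM prevalence a little over half the cohort — the order of magnitude
real claims show. Patterns are mutually combinable per patient except
where a negative control would contaminate its positive counterpart
(short-gap PPI backs off when long-term PPI is drawn, sub-chronic NSAID
when the co-dispensing pair is drawn). Deceased patients still emit
claims but never ground-truth labels, so the eligibility path is
exercised.

Ground truth is derived from the injection construction itself — which
rules the placed dates entail, including cross-rule hits (amitriptyline
and clomipramine also fire the TCA rule; olanzapine also fires the
antipsychotics rule) — not by running the detector. The independent check
of the detector is a separate brute-force evaluator in the test suite
that re-implements every quantitative condition by exhaustive pair
enumeration and per-year counting, and must agree with the engine exactly
on 200 randomized micro-cohorts.

What the generator does **not** emulate: realistic drug-mix proportions
beyond the named headline drugs, seasonal dispensing patterns, switching
between ingredients within a class, multi-region structure, or data-entry
noise (malformed rows are covered by ingest unit tests instead). Passing
the end-to-end tests therefore shows the pipeline is *correct against its
definitions*, not that real-world prevalence estimates are unbiased —
with claims data those inherit the proxies' limitations regardless of
implementation.

Determinism: one `numpy` generator seeded from the config drives every
draw in a fixed order (per patient: sex, age, birth-day offset, death,
pattern Bernoullis in declaration order, pattern internals, background),
so outputs are reproducible to the byte for a given seed.

## Problem sizes

Randomized oracle comparisons use 200 micro-cohorts of ≤ 10 patients and
≤ 5 drugs; the end-to-end recovery test uses 2 000 patients (≈ 27 000
claims rows), sizes at which the brute-force oracle stays exact and the
whole suite runs in seconds.

## Known limitations

- The duration screen is blind to continuous monthly refills (gaps ≤ 56
  days never qualify) — faithful to the literal definition, but a
  long-term user refilling every 30 days is *not* flagged by the PPI
  rule. Sites wanting episode-based exposure should encode it as a new
  condition variant rather than reinterpret this one.
- Unit dose as daily-dose proxy misclassifies split-tablet and
  multiple-unit regimens in both directions.
- Route/form parsing is keyword-based and multilingual only to the extent
  of the shipped dictionary; unmatched names yield UNKNOWN, never a guess.
- Sex values outside M/F are retained as U: counted in totals, excluded
  from sex strata.
- The catalog covers the drugs and classes decidable from dispensing
  data; it is a starting point to extend per site, not a complete Beers
  rendering.
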