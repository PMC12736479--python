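# Default PIM catalog: 2019 AGS Beers Criteria restricted to rules decidable
# from dispensing claims alone (drug-disease, drug-drug interaction and
# renal-dose criteria need clinical data and are out of scope), keyed by ATC
# prefix. Ticlopidine is retained as AVOID: it left the 2019 US list only for
# market withdrawal and is still reimbursed in Italy.
version: beers-2019-dispensing-v1
rules:
  # --- drugs to avoid -------------------------------------------------------
  - id: ppi_long_term
    category: AVOID
    label: PPI
    atc: [A02BC]
    condition:
      type: DURATION_OVER_8_WEEKS
      min_gap_days: 56
      max_gap_days: 180
    rationale: >-
      Proton-pump inhibitors beyond 8 weeks without a documented indication:
      risk of C. difficile infection, fractures, B12/magnesium deficiency.
  - id: paroxetine
    category: AVOID
    label: Paroxetine
    atc: [N06AB05]
    rationale: Strongly anticholinergic SSRI; sedation, orthostatic hypotension.
  - id: sulfonylureas
    category: AVOID
    label: Sulfonylureas
    atc: [A10BB]
    rationale: Prolonged severe hypoglycemia and SIADH risk in older adults.
  - id: nsaid_chronic
    category: AVOID
    label: NSAID
    atc: [M01A]
    condition:
      type: CHRONIC_USE
      min_events: 5
    rationale: >-
      Chronic use of oral non-COX-selective NSAIDs: GI bleeding and peptic
      ulcer risk, especially without gastroprotection.
  - id: nsaid_corticosteroid
    category: AVOID
    label: NSAID + corticosteroid
    atc: [M01A]
    condition:
      type: CO_DISPENSED_WITH
      atc_patterns: [H02AB]
      window_days: 90
    rationale: >-
      Oral NSAID co-dispensed with a systemic corticosteroid within 3 months:
      strongly increased gastrointestinal bleeding risk.
  - id: amiodarone
    category: AVOID
    label: Amiodarone
    atc: [C01BD01]
    rationale: >-
      First-line rate/rhythm control alternatives preferred; pulmonary,
      thyroid and QT toxicity.
  - id: tca
    category: AVOID
    label: TCA
    atc: [N06AA]
    rationale: >-
      Tertiary-amine tricyclic antidepressants: highly anticholinergic,
      sedating, orthostatic hypotension.
  - id: ticlopidine
    category: AVOID
    label: Ticlopidine
    atc: [B01AC05]
    rationale: >-
      Safer, more effective antiplatelet alternatives exist (2015 Beers
      listing; removed in 2019 only because no longer marketed in the US).
  # --- drugs to be used with caution (SIADH / hyponatremia risk) ------------
  - id: furosemide
    category: CAUTION
    label: Furosemide
    atc: [C03CA]
    rationale: Loop diuretics (furosemide, torsemide) may exacerbate hyponatremia/SIADH.
  - id: aldosterone_antagonists
    category: CAUTION
    label: Aldosterone antagonists
    atc: [C03DA]
    rationale: Hyperkalemia and hyponatremia risk.
  - id: minor_diuretic_ksparing
    category: CAUTION
    label: Minor diuretics + potassium-sparing
    atc: [C03EA]
    rationale: Fixed associations of low-ceiling diuretics and potassium-sparing agents.
  - id: furosemide_ksparing
    category: CAUTION
    label: Furosemide + potassium-sparing
    atc: [C03EB]
    rationale: Fixed associations of high-ceiling diuretics and potassium-sparing agents.
  - id: minor_diuretics
    category: CAUTION
    label: Minor diuretics
    atc: [C03B]
    rationale: Low-ceiling diuretics; hyponatremia risk.
  - id: hydrochlorothiazide
    category: CAUTION
    label: Hydrochlorothiazide
    atc: [C03AA03]
    rationale: Thiazide diuretic; hyponatremia/SIADH risk.
  - id: tramadol
    category: CAUTION
    label: Tramadol
    atc: [N02AX02]
    rationale: SIADH/hyponatremia; lowers seizure threshold.
  - id: mirtazapine
    category: CAUTION
    label: Mirtazapine
    atc: [N06AX11]
    rationale: SIADH/hyponatremia risk.
  - id: antipsychotics
    category: CAUTION
    label: Antipsychotics
    atc: [N05A]
    rationale: SIADH/hyponatremia; stroke and mortality risk in dementia.
  - id: aspirin_high_dose
    category: CAUTION
    label: Aspirin >325 mg/day
    atc: [B01AC06, N02BA01]
    condition:
      type: UNIT_DOSE_EXCEEDS
      mg_per_day: 325
    rationale: Unit dose above 325 mg taken as a daily-dose proxy; GI bleeding risk.
  # --- strong anticholinergics (cognitive burden) ---------------------------
  - id: achol_paroxetine
    category: ANTICHOLINERGIC
    label: Paroxetine
    atc: [N06AB05]
  - id: achol_amitriptyline
    category: ANTICHOLINERGIC
    label: Amitriptyline
    atc: [N06AA09]
  - id: achol_olanzapine
    category: ANTICHOLINERGIC
    label: Olanzapine
    atc: [N05AH03]
  - id: achol_oxybutynin
    category: ANTICHOLINERGIC
    label: Oxybutynin
    atc: [G04BD04]
  - id: achol_clomipramine
    category: ANTICHOLINERGIC
    label: Clomipramine
    atc: [N06AA04]
  - id: achol_trihexyphenidyl
    category: ANTICHOLINERGIC
    label: Trihexyphenidyl
    atc: [N04AA01]
  - id: achol_disopyramide
    category: ANTICHOLINERGIC
    label: Disopyramide
    atc: [C01BA03]
  - id: achol_hydroxyzine
    category: ANTICHOLINERGIC
    label: Hydroxyzine
    atc: [N05BB01]
# Anticholinergic Cognitive Burden (ACB) scores; longest ATC prefix wins.
# Every strong anticholinergic retained above scores 3 on the ACB scale.
acb:
  - {atc: N06AB05, score: 3}
  - {atc: N06AA09, score: 3}
  - {atc: N05AH03, score: 3}
  - {atc: G04BD04, score: 3}
  - {atc: N06AA04, score: 3}
  - {atc: N04AA01, score: 3}
  - {atc: C01BA03, score: 3}
  - {atc: N05BB01, score: 3}
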