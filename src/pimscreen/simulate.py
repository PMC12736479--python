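"""Synthetic dispensing-claims generator with exact ground-truth PIM labels.

The generator emulates the statistical structure the screening pipeline
assumes in real claims: an older-adult age/sex mix (triangular ages over
65–100 with median near 77, ~40% male), a 2018–2021 study window, chronic
(roughly monthly) versus sporadic (Poisson) dispensing processes, and a
set of *injection patterns* that place dispensation dates constructed to
satisfy — or deliberately just miss — the catalog's rule conditions:

======================  ====================================================
pattern                 construction
======================  ====================================================
PPI_LONG_TERM           two PPI dates 60–170 days apart within one year
                        (inside the >56-and-<=180-day qualifying band)
PAROXETINE_CHRONIC      5–8 roughly monthly paroxetine dates in one year
SULFONYLUREA            1–4 glibenclamide dates in one year
TICLOPIDINE             3–9 ticlopidine dates in one year
FUROSEMIDE              1–4 furosemide dates in one year
CO_DISPENSING_PAIR      one NSAID date with a corticosteroid date within
                        60 days of it
MULTI_ANTICHOLINERGIC   k distinct strong anticholinergics (excluding
                        paroxetine), each 5–8 monthly dates in one year
PPI_SHORT_GAP           negative control: two PPI dates 14–56 days apart
NSAID_SUBCHRONIC        negative control: exactly 4 NSAID dates in a year
======================  ====================================================

Ground truth lists, per eligible patient and year, exactly the
(rule_id, category) labels the placed dates entail under the shipped
catalog, plus the expected chronic-anticholinergic agent sets and ACB
totals. It is derived from the construction itself (not by running the
detector), so end-to-end tests can compare ``detect_all`` output against
an independent statement of the truth.

All randomness flows through one ``numpy`` generator seeded from the
config; draw order is fixed (per patient: sex, age, birth-day offset,
death, one uniform per pattern in declaration order, then pattern
internals, then background drugs), so a seed reproduces the dataset
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

from .cohort import Patient, StudyWindow
from .io import DeathRecord, DispensingRecord

#: Injection pattern names in draw order.
PATTERNS = (
    "PPI_LONG_TERM",
    "PAROXETINE_CHRONIC",
    "SULFONYLUREA",
    "TICLOPIDINE",
    "FUROSEMIDE",
    "CO_DISPENSING_PAIR",
    "MULTI_ANTICHOLINERGIC",
    "PPI_SHORT_GAP",
    "NSAID_SUBCHRONIC",
)

#: Strong anticholinergics available to MULTI_ANTICHOLINERGIC (paroxetine is
#: deliberately excluded so the pattern composes with PAROXETINE_CHRONIC).
_ACHOL_MENU = (
    ("N06AA09", "AMITRIPTYLINE 25MG CPR", 25.0, (("achol_amitriptyline", "ANTICHOLINERGIC"), ("tca", "AVOID"))),
    ("N05AH03", "OLANZAPINE 5MG CPR", 5.0, (("achol_olanzapine", "ANTICHOLINERGIC"), ("antipsychotics", "CAUTION"))),
    ("G04BD04", "OXYBUTYNIN 5MG CPR", 5.0, (("achol_oxybutynin", "ANTICHOLINERGIC"),)),
    ("N06AA04", "CLOMIPRAMINE 25MG CPR", 25.0, (("achol_clomipramine", "ANTICHOLINERGIC"), ("tca", "AVOID"))),
)


@dataclass(frozen=True)
class BackgroundDrug:
    """A non-catalog drug giving the cohort a realistic claims background."""

    atc_code: str
    name: str
    unit_dose_mg: float
    process: str  # "sporadic" (Poisson per year) or "chronic" (monthly)
    rate: float = 1.0  # sporadic: Poisson mean/year; chronic: participation prob


DEFAULT_BACKGROUND: tuple[BackgroundDrug, ...] = (
    BackgroundDrug("C10AA05", "ATORVASTATIN 20MG CPR", 20.0, "chronic", 0.35),
    BackgroundDrug("C09AA05", "RAMIPRIL 5MG CPR", 5.0, "chronic", 0.30),
    BackgroundDrug("N02BE01", "PARACETAMOL 500MG CPR", 500.0, "sporadic", 1.2),
    BackgroundDrug("J01CA04", "AMOXICILLIN 1G CPR", 1000.0, "sporadic", 0.6),
    BackgroundDrug("B03BA01", "CYANOCOBALAMIN 1MG FIALE", 1.0, "sporadic", 0.3),
)

#: Default per-patient injection probabilities: PPI long-term use dominant,
#: a tenth chronically on paroxetine, furosemide common, ticlopidine and
#: multiple-anticholinergic use rare; negative controls off by default.
DEFAULT_INJECTION_RATES: dict[str, float] = {
    "PPI_LONG_TERM": 0.30,
    "PAROXETINE_CHRONIC": 0.10,
    "SULFONYLUREA": 0.05,
    "TICLOPIDINE": 0.02,
    "FUROSEMIDE": 0.20,
    "CO_DISPENSING_PAIR": 0.05,
    "MULTI_ANTICHOLINERGIC": 0.02,
    "PPI_SHORT_GAP": 0.0,
    "NSAID_SUBCHRONIC": 0.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-cohort configuration (defaults are the study conditions)."""

    n_patients: int = 1000
    seed: int = 0
    window: StudyWindow = StudyWindow()
    sex_male_prob: float = 0.40
    age_low: float = 65.0
    age_mode: float = 73.0  # triangular mode giving a median near 77
    age_high: float = 100.0
    mortality_prob: float = 0.05
    chronic_count_min: int = 5
    chronic_count_max: int = 8
    injection_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INJECTION_RATES)
    )
    multi_anticholinergic_k: int = 2
    background: tuple[BackgroundDrug, ...] = DEFAULT_BACKGROUND

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name, p in self.injection_rates.items():
            if name not in PATTERNS:
                raise ValueError(f"unknown injection pattern {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"injection rate for {name} outside [0, 1]")
        if not 0.0 <= self.sex_male_prob <= 1.0:
            raise ValueError("sex_male_prob outside [0, 1]")
        if not 0.0 <= self.mortality_prob <= 1.0:
            raise ValueError("mortality_prob outside [0, 1]")
        if self.chronic_count_min < 5:
            raise ValueError(
                "chronic_count_min below 5 contradicts the chronic-use definition"
            )
        if self.chronic_count_max < self.chronic_count_min:
            raise ValueError("chronic_count_max < chronic_count_min")
        if not 2 <= self.multi_anticholinergic_k <= len(_ACHOL_MENU):
            raise ValueError("multi_anticholinergic_k must be in [2, 4]")


@dataclass
class GroundTruth:
    """Expected detector output for a generated cohort.

    ``labels[(patient_id, year)]`` is the exact set of (rule_id, category)
    pairs the detector must emit; ``chronic_agents`` and ``acb_totals``
    state the expected chronic strong-anticholinergic agent sets and their
    summed ACB scores (every shipped agent scores 3).
    """

    labels: dict[tuple[str, int], set[tuple[str, str]]] = field(default_factory=dict)
    chronic_agents: dict[tuple[str, int], frozenset[str]] = field(default_factory=dict)
    acb_totals: dict[tuple[str, int], int] = field(default_factory=dict)

    def add_label(self, pid: str, year: int, rule_id: str, category: str) -> None:
        self.labels.setdefault((pid, year), set()).add((rule_id, category))

    def add_chronic_agent(self, pid: str, year: int, agent: str) -> None:
        key = (pid, year)
        agents = set(self.chronic_agents.get(key, frozenset())) | {agent}
        self.chronic_agents[key] = frozenset(agents)
        self.acb_totals[key] = 3 * len(agents)

    def to_json(self) -> str:
        doc = {
            "labels": [
                {
                    "patient_id": pid,
                    "year": year,
                    "expected": sorted(list(pair) for pair in pairs),
                }
                for (pid, year), pairs in sorted(self.labels.items())
            ],
            "chronic_anticholinergics": [
                {
                    "patient_id": pid,
                    "year": year,
                    "agents": sorted(agents),
                    "acb_total": self.acb_totals[(pid, year)],
                }
                for (pid, year), agents in sorted(self.chronic_agents.items())
            ],
        }
        return json.dumps(doc, indent=1)


def labels_from_events(events) -> dict[tuple[str, int], set[tuple[str, str]]]:
    """Detector events in GroundTruth label form, for exact comparison."""
    out: dict[tuple[str, int], set[tuple[str, str]]] = {}
    for e in events:
        out.setdefault((e.patient_id, e.year), set()).add((e.rule_id, e.category))
    return out


def _birth_date_for_age(age: int, window_end: date, rng: np.random.Generator) -> date:
    """A birth date giving exactly *age* completed years at *window_end*."""
    from dateutil.relativedelta import relativedelta

    latest = window_end - relativedelta(years=age)
    earliest = window_end - relativedelta(years=age + 1) + timedelta(days=1)
    span = (latest - earliest).days
    return earliest + timedelta(days=int(rng.integers(0, span + 1)))


def sample_demographics(config: SimConfig, rng: np.random.Generator) -> list[Patient]:
    """Draw the patient roster: id, sex, birth date, optional in-window death."""
    window = config.window
    window_days = (window.end - window.start).days
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        sex = "M" if rng.random() < config.sex_male_prob else "F"
        age = int(rng.triangular(config.age_low, config.age_mode, config.age_high))
        birth = _birth_date_for_age(age, window.end, rng)
        death = None
        if rng.random() < config.mortality_prob:
            death = window.start + timedelta(days=int(rng.integers(0, window_days + 1)))
        patients.append(Patient(pid, birth, sex, death))
    return patients


def _day_in_year(year: int, day_of_year: int) -> date:
    return date(year, 1, 1) + timedelta(days=day_of_year)


def _monthly_dates(
    rng: np.random.Generator, year: int, count: int
) -> list[date]:
    """*count* roughly monthly dates within one calendar year (gaps 24–36 d)."""
    latest_start = 364 - (count - 1) * 30 - 3
    start = int(rng.integers(0, max(1, latest_start)))
    dates = []
    for j in range(count):
        jitter = int(rng.integers(-3, 4)) if j > 0 else 0
        dates.append(_day_in_year(year, start + j * 30 + jitter))
    return sorted(set(dates))


def _uniform_dates_in_year(
    rng: np.random.Generator, year: int, count: int
) -> list[date]:
    days = rng.choice(365, size=count, replace=False)
    return sorted(_day_in_year(year, int(d)) for d in days)


def generate(
    config: SimConfig,
) -> tuple[list[DispensingRecord], list[DeathRecord], GroundTruth]:
    """Generate claims, deaths and the exact expected PIM labels.

    Deterministic for a fixed seed. Patients who die inside the window
    still produce claims (their exclusion is what downstream eligibility
    logic must handle) but contribute no ground-truth labels, since the
    detector must never emit events for them.
    """
    rng = np.random.default_rng(config.seed)
    window = config.window
    years = list(window.years)
    truth = GroundTruth()
    records: list[DispensingRecord] = []
    deaths: list[DeathRecord] = []

    patients = sample_demographics(config, rng)
    for patient in patients:
        pid = patient.patient_id
        eligible = patient.death_date is None
        if patient.death_date is not None:
            deaths.append(DeathRecord(pid, patient.death_date))

        def emit(dispense_date, atc, name, dose):
            records.append(
                DispensingRecord(
                    patient_id=pid,
                    birth_date=patient.birth_date,
                    sex=patient.sex,
                    dispense_date=dispense_date,
                    atc_code=atc,
                    medication_name=name,
                    n_packages=1,
                    unit_dose_mg=dose,
                )
            )

        n_records_before = len(records)
        drawn = {
            name: rng.random() < config.injection_rates.get(name, 0.0)
            for name in PATTERNS
        }
        # incompatible negative controls back off to the positive pattern
        if drawn["PPI_LONG_TERM"] and drawn["PPI_SHORT_GAP"]:
            drawn["PPI_SHORT_GAP"] = False
        if drawn["CO_DISPENSING_PAIR"] and drawn["NSAID_SUBCHRONIC"]:
            drawn["NSAID_SUBCHRONIC"] = False

        if drawn["PPI_LONG_TERM"]:
            year = int(rng.choice(years))
            gap = int(rng.integers(60, 171))
            start = int(rng.integers(0, 365 - gap))
            for d in (start, start + gap):
                emit(_day_in_year(year, d), "A02BC02", "PANTOPRAZOLE 40MG CPR", 40.0)
            if eligible:
                truth.add_label(pid, year, "ppi_long_term", "AVOID")

        if drawn["PAROXETINE_CHRONIC"]:
            year = int(rng.choice(years))
            count = int(
                rng.integers(config.chronic_count_min, config.chronic_count_max + 1)
            )
            for d in _monthly_dates(rng, year, count):
                emit(d, "N06AB05", "PAROXETINE 20MG CPR", 20.0)
            if eligible:
                truth.add_label(pid, year, "paroxetine", "AVOID")
                truth.add_label(pid, year, "achol_paroxetine", "ANTICHOLINERGIC")
                truth.add_chronic_agent(pid, year, "N06AB05")

        if drawn["SULFONYLUREA"]:
            year = int(rng.choice(years))
            for d in _uniform_dates_in_year(rng, year, int(rng.integers(1, 5))):
                emit(d, "A10BB01", "GLIBENCLAMIDE 5MG CPR", 5.0)
            if eligible:
                truth.add_label(pid, year, "sulfonylureas", "AVOID")

        if drawn["TICLOPIDINE"]:
            year = int(rng.choice(years))
            count = int(rng.integers(3, 10))
            for d in _monthly_dates(rng, year, count):
                emit(d, "B01AC05", "TICLOPIDINE 250MG CPR", 250.0)
            if eligible:
                truth.add_label(pid, year, "ticlopidine", "AVOID")

        if drawn["FUROSEMIDE"]:
            year = int(rng.choice(years))
            for d in _uniform_dates_in_year(rng, year, int(rng.integers(1, 5))):
                emit(d, "C03CA01", "FUROSEMIDE 25MG CPR", 25.0)
            if eligible:
                truth.add_label(pid, year, "furosemide", "CAUTION")

        if drawn["CO_DISPENSING_PAIR"]:
            year = int(rng.choice(years))
            index_day = int(rng.integers(61, 300))
            offset = int(rng.integers(-60, 61))
            index_date = _day_in_year(year, index_day)
            emit(index_date, "M01AB05", "DICLOFENAC 50MG CPR", 50.0)
            emit(index_date + timedelta(days=offset), "H02AB07", "PREDNISONE 25MG CPR", 25.0)
            if eligible:
                truth.add_label(pid, year, "nsaid_corticosteroid", "AVOID")

        if drawn["MULTI_ANTICHOLINERGIC"]:
            year = int(rng.choice(years))
            idx = rng.choice(
                len(_ACHOL_MENU), size=config.multi_anticholinergic_k, replace=False
            )
            for i in sorted(int(j) for j in idx):
                atc, name, dose, rule_hits = _ACHOL_MENU[i]
                count = int(
                    rng.integers(config.chronic_count_min, config.chronic_count_max + 1)
                )
                for d in _monthly_dates(rng, year, count):
                    emit(d, atc, name, dose)
                if eligible:
                    for rule_id, category in rule_hits:
                        truth.add_label(pid, year, rule_id, category)
                    truth.add_chronic_agent(pid, year, atc)

        if drawn["PPI_SHORT_GAP"]:
            year = int(rng.choice(years))
            gap = int(rng.integers(14, 57))
            start = int(rng.integers(0, 365 - gap))
            for d in (start, start + gap):
                emit(_day_in_year(year, d), "A02BC02", "PANTOPRAZOLE 40MG CPR", 40.0)

        if drawn["NSAID_SUBCHRONIC"]:
            year = int(rng.choice(years))
            for d in _monthly_dates(rng, year, 4):
                emit(d, "M01AE01", "IBUPROFEN 600MG CPR", 600.0)

        for drug in config.background:
            if drug.process == "chronic":
                if rng.random() < drug.rate:
                    for year in years:
                        count = int(
                            rng.integers(
                                config.chronic_count_min, config.chronic_count_max + 1
                            )
                        )
                        for d in _monthly_dates(rng, year, count):
                            emit(d, drug.atc_code, drug.name, drug.unit_dose_mg)
            else:
                for year in years:
                    n = int(rng.poisson(drug.rate))
                    if n > 0:
                        for d in _uniform_dates_in_year(rng, year, min(n, 365)):
                            emit(d, drug.atc_code, drug.name, drug.unit_dose_mg)

        if len(records) == n_records_before:
            # guarantee at least one in-window dispensation per patient
            day = int(rng.integers(0, (window.end - window.start).days + 1))
            emit(window.start + timedelta(days=day), "N02BE01", "PARACETAMOL 500MG CPR", 500.0)

    records.sort(key=lambda r: (r.patient_id, r.dispense_date, r.atc_code))
    return records, deaths, truth
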