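from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from pimscreen import DeathRecord, DispensingRecord, StudyWindow, load_catalog


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture
def window():
    return StudyWindow(date(2018, 1, 1), date(2021, 12, 31))


def make_record(
    patient_id="P001",
    birth_date=date(1945, 6, 15),
    sex="F",
    dispense_date=date(2019, 2, 1),
    atc_code="A02BC02",
    medication_name="PANTOPRAZOLE 40MG CPR",
    n_packages=1,
    unit_dose_mg=None,
):
    return DispensingRecord(
        patient_id=patient_id,
        birth_date=birth_date,
        sex=sex,
        dispense_date=dispense_date,
        atc_code=atc_code,
        medication_name=medication_name,
        n_packages=n_packages,
        unit_dose_mg=unit_dose_mg,
    )


# drug menu for randomized micro-cohorts: covers ALWAYS, duration, chronic,
# co-dispensing and unit-dose rule mechanics plus one non-catalog drug
MICRO_MENU = (
    ("A02BC02", "PANTOPRAZOLE 40MG CPR", 40.0),
    ("N06AB05", "PAROXETINE 20MG CPR", 20.0),
    ("M01AB05", "DICLOFENAC 50MG CPR", 50.0),
    ("H02AB07", "PREDNISONE 25MG CPR", 25.0),
    ("C03CA01", "FUROSEMIDE 25MG CPR", 25.0),
    ("B01AC06", "ASPIRIN 500MG CPR", 500.0),
    ("B01AC06", "ASPIRIN 100MG CPR", 100.0),
    ("C09AA05", "RAMIPRIL 5MG CPR", 5.0),
)


def random_micro_cohort(seed: int, window: StudyWindow):
    """A tiny random claims set: <=10 patients x <=5 drugs, random dates.

    Birth years straddle the eligibility boundary and a few patients die
    in-window, so cohort rules are exercised alongside rule conditions.
    """
    rng = np.random.default_rng(seed)
    span = (window.end - window.start).days
    records = []
    deaths = []
    n_patients = int(rng.integers(1, 11))
    for i in range(n_patients):
        pid = f"M{seed:03d}_{i:02d}"
        birth = date(int(rng.integers(1935, 1960)), int(rng.integers(1, 13)), 15)
        sex = "M" if rng.random() < 0.5 else "F"
        drug_idx = rng.choice(len(MICRO_MENU), size=int(rng.integers(1, 6)), replace=False)
        for j in sorted(int(k) for k in drug_idx):
            atc, name, dose = MICRO_MENU[j]
            n_disp = int(rng.poisson(3))
            for _ in range(n_disp):
                # dates may fall slightly outside the window (lookback rows)
                offset = int(rng.integers(-120, span + 120))
                d = window.start + timedelta(days=offset)
                if d < birth:
                    continue
                records.append(
                    make_record(
                        patient_id=pid,
                        birth_date=birth,
                        sex=sex,
                        dispense_date=d,
                        atc_code=atc,
                        medication_name=name,
                        unit_dose_mg=dose if rng.random() < 0.8 else None,
                    )
                )
        if rng.random() < 0.15 and records:
            deaths.append(
                DeathRecord(pid, window.start + timedelta(days=int(rng.integers(0, span))))
            )
    return records, deaths
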