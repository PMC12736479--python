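"""Study-cohort construction: eligibility, exclusions and age/sex strata.

Eligible patients are those who reach age 65 on or before the end of the
study window, have at least one dispensation inside the window, and do not
die on or before the window end (deaths after the window, or an absent
death registry, exclude nobody). Age and age strata are computed once, at
the window end, by completed-years (birthday-anniversary) arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from dateutil.relativedelta import relativedelta

from .io import DeathRecord, DispensingRecord

AGE_GROUPS = ("YOUNG_ELDERLY", "ELDERLY", "VERY_ELDERLY")

ELIGIBILITY_AGE = 65


@dataclass(frozen=True)
class StudyWindow:
    """Closed calendar interval of the analysis (default 2018–2021)."""

    start: date = date(2018, 1, 1)
    end: date = date(2021, 12, 31)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window start must precede end")

    @property
    def years(self) -> range:
        return range(self.start.year, self.end.year + 1)

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: date
    sex: str
    death_date: date | None = None

    def __post_init__(self) -> None:
        if self.death_date is not None and self.death_date < self.birth_date:
            raise ValueError("death_date precedes birth_date")


@dataclass
class Cohort:
    """Eligible patients plus per-year denominators.

    ``yearly_denominators[year]`` is the set of eligible patient ids with at
    least one dispensation in that calendar year — the denominator of the
    annual prevalence (older adults who received any dispensing that year).
    """

    window: StudyWindow
    patients: dict[str, Patient] = field(default_factory=dict)
    yearly_denominators: dict[int, set[str]] = field(default_factory=dict)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self.patients


def age_at(birth_date: date, reference_date: date) -> int:
    """Completed years of age at *reference_date* (birthday arithmetic)."""
    if reference_date < birth_date:
        raise ValueError("reference_date precedes birth_date")
    return relativedelta(reference_date, birth_date).years


def age_group(age: int) -> str:
    """Stratum for a completed age: 65–74, 75–84, or ≥85 years."""
    if age < ELIGIBILITY_AGE:
        raise ValueError(f"age {age} below study minimum of {ELIGIBILITY_AGE}")
    if age <= 74:
        return "YOUNG_ELDERLY"
    if age <= 84:
        return "ELDERLY"
    return "VERY_ELDERLY"


def build_cohort(
    records: list[DispensingRecord],
    deaths: list[DeathRecord] | None = None,
    window: StudyWindow = StudyWindow(),
) -> Cohort:
    """Apply eligibility and exclusion rules to validated claims.

    Included iff: reaches age 65 by ``window.end``, has >=1 dispensation in
    the window, and has no registered death on or before ``window.end``.
    Raises ``ValueError`` on inconsistent birth dates or sexes for a single
    patient id (an identity error in the source extract).
    """
    death_by_id = {d.patient_id: d.death_date for d in (deaths or [])}

    birth: dict[str, date] = {}
    sex: dict[str, str] = {}
    years_with_claims: dict[str, set[int]] = {}
    for r in records:
        prev = birth.get(r.patient_id)
        if prev is not None and prev != r.birth_date:
            raise ValueError(
                f"inconsistent birth_date for patient {r.patient_id}: "
                f"{prev} vs {r.birth_date}"
            )
        birth[r.patient_id] = r.birth_date
        prev_sex = sex.get(r.patient_id)
        if prev_sex is not None and prev_sex != r.sex:
            raise ValueError(f"inconsistent sex for patient {r.patient_id}")
        sex[r.patient_id] = r.sex
        if window.contains(r.dispense_date):
            years_with_claims.setdefault(r.patient_id, set()).add(
                r.dispense_date.year
            )

    cohort = Cohort(window=window, yearly_denominators={y: set() for y in window.years})
    for pid, years in years_with_claims.items():
        if age_at(birth[pid], window.end) < ELIGIBILITY_AGE:
            continue
        death = death_by_id.get(pid)
        if death is not None and death <= window.end:
            continue
        cohort.patients[pid] = Patient(pid, birth[pid], sex[pid], death)
        for y in years:
            cohort.yearly_denominators[y].add(pid)
    return cohort
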