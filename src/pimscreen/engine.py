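"""The PIM detection engine: rule evaluation over dispensing histories.

For every (patient, rule, calendar year) triple the engine decides whether
the patient's dispensing pattern makes the rule fire, and emits at most one
:class:`PIMEvent` per triple. The operational predicates mirror how
dispensing claims are screened when prescription durations and doses are
not recorded:

- *duration over 8 weeks*: two consecutive dispensing dates of the drug
  more than 56 days apart but within 180 days — a refill gap pattern
  indicating use extending beyond 8 weeks rather than a one-off course;
- *co-dispensing*: dispensations of two drug classes within 90 days
  (a 3-month concomitance window);
- *chronic use*: >=5 dispensing events of one ingredient in a calendar
  year;
- *unit dose as daily-dose proxy*: the strength of one dose unit stands in
  for the unknown prescribed daily dose;
- *route/form*: parsed from keywords in the free-text medication name.

Same-day duplicate dispensations of one ingredient collapse to a single
dispensing *event* for gap and chronicity counting (pack-level duplication
would otherwise inflate chronic-use counts); the raw rows are preserved in
the event's trigger list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date

from .catalog import BeersCatalog, Condition, PIMRule
from .cohort import Cohort
from .io import DispensingRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RouteForm:
    """Administration route and pharmaceutical form parsed from a name."""

    route: str = "UNKNOWN"
    form: str = "UNKNOWN"


@dataclass(frozen=True)
class PIMEvent:
    """One detected patient–year–rule hit with its triggering dispensations."""

    patient_id: str
    rule_id: str
    category: str
    label: str
    year: int
    trigger_dispensations: tuple[DispensingRecord, ...]

    def __post_init__(self) -> None:
        if not self.trigger_dispensations:
            raise ValueError("trigger_dispensations must be non-empty")

    @property
    def n_triggers(self) -> int:
        return len(self.trigger_dispensations)

    @property
    def first_trigger_date(self) -> date:
        return min(r.dispense_date for r in self.trigger_dispensations)


def duration_over_8_weeks(
    dates: list[date], min_gap_days: int = 56, max_gap_days: int = 180
) -> tuple[bool, list[tuple[date, date]]]:
    """Screen sorted dispensing dates for a use-beyond-8-weeks gap pattern.

    Returns ``(hit, pairs)`` where *pairs* lists every consecutive pair
    ``(d_i, d_{i+1})`` whose gap is strictly greater than *min_gap_days*
    and at most *max_gap_days*. Zero or one date never qualifies. The check
    is deliberately pairwise on consecutive dates, not an episode merge.
    """
    pairs = []
    for a, b in zip(dates, dates[1:]):
        gap = (b - a).days
        if min_gap_days < gap <= max_gap_days:
            pairs.append((a, b))
    return bool(pairs), pairs


def co_dispensed(
    history_a: list[date], history_b: list[date], window_days: int = 90
) -> bool:
    """True iff any date of A falls within *window_days* of any date of B."""
    return any(
        abs((a - b).days) <= window_days for a in history_a for b in history_b
    )


def chronic_in_year(dates: list[date], year: int, min_events: int = 5) -> bool:
    """True iff >=min_events distinct dispensing dates fall in *year*."""
    return len({d for d in dates if d.year == year}) >= min_events


def unit_dose_exceeds(record: DispensingRecord, mg_per_day_threshold: float) -> bool:
    """Unit dose strictly above the threshold; raises on a missing dose."""
    dose = effective_unit_dose(record)
    if dose is None:
        raise MissingUnitDose(record)
    return dose > mg_per_day_threshold


class MissingUnitDose(Exception):
    """Unit dose unavailable: explicit column empty and name unparseable."""

    def __init__(self, record: DispensingRecord):
        self.record = record
        super().__init__(f"no unit dose for {record.atc_code} {record.medication_name!r}")


_STRENGTH_RE = re.compile(r"(\d+(?:[.,]\d+)?)\s*(MG|G)\b", re.IGNORECASE)


def parse_strength(medication_name: str) -> float | None:
    """First mg/g strength token in a medication name, in mg; None if absent."""
    m = _STRENGTH_RE.search(medication_name)
    if not m:
        return None
    value = float(m.group(1).replace(",", "."))
    if m.group(2).upper() == "G":
        value *= 1000.0
    return value


def effective_unit_dose(record: DispensingRecord) -> float | None:
    """Explicit unit_dose_mg when present, else strength parsed from name."""
    if record.unit_dose_mg is not None:
        return record.unit_dose_mg
    return parse_strength(record.medication_name)


# Keyword dictionary for route/form parsing; multilingual (Italian claims
# exports abbreviate forms heavily). Order matters: first hit wins.
_FORM_KEYWORDS: list[tuple[str, str, str]] = [
    ("CPR", "TABLET", "ORAL"),
    ("TABS", "TABLET", "ORAL"),
    ("TABLET", "TABLET", "ORAL"),
    ("COMPRESSE", "TABLET", "ORAL"),
    ("CPS", "CAPSULE", "ORAL"),
    ("CAPS", "CAPSULE", "ORAL"),
    ("CAPSULE", "CAPSULE", "ORAL"),
    ("SUPP", "SUPPOSITORY", "RECTAL"),
    ("CEROTTO", "PATCH", "TRANSDERMAL"),
    ("PATCH", "PATCH", "TRANSDERMAL"),
    ("CREMA", "CREAM", "TOPICAL"),
    ("CREAM", "CREAM", "TOPICAL"),
    ("UNGUENTO", "CREAM", "TOPICAL"),
    ("COLLIRIO", "DROPS", "OPHTHALMIC"),
    ("EYE DROPS", "DROPS", "OPHTHALMIC"),
    ("SOLUZ IV", "SOLUTION", "PARENTERAL"),
    ("VIAL", "SOLUTION", "PARENTERAL"),
    ("FIALE", "SOLUTION", "PARENTERAL"),
    ("FL", "SOLUTION", "PARENTERAL"),
    ("IV", "SOLUTION", "PARENTERAL"),
    ("IM", "SOLUTION", "PARENTERAL"),
    ("GTT", "DROPS", "ORAL"),
    ("SCIROPPO", "SOLUTION", "ORAL"),
    ("SYRUP", "SOLUTION", "ORAL"),
]

_WORD_RE = re.compile(r"[A-Z]+(?:\s[A-Z]+)*")


def parse_route_form(medication_name: str) -> RouteForm:
    """Route/form from case-insensitive keyword lookup; UNKNOWN when none."""
    name = medication_name.upper()
    tokens = set(re.split(r"[^A-Z]+", name))
    for keyword, form, route in _FORM_KEYWORDS:
        if " " in keyword:
            if keyword in name:
                return RouteForm(route=route, form=form)
        elif keyword in tokens:
            return RouteForm(route=route, form=form)
    return RouteForm()


def _event_dates(records: list[DispensingRecord]) -> list[date]:
    """Distinct dispensing dates, sorted (same-day duplicates collapse)."""
    return sorted({r.dispense_date for r in records})


def _condition_years(
    condition: Condition,
    matching: list[DispensingRecord],
    history: list[DispensingRecord],
) -> set[int] | None:
    """Years in which *condition* holds for the rule's matching records.

    *None* means "every year with a matching dispensation qualifies"
    (the ALWAYS case); a set restricts to years where the pattern-specific
    attribution lands. Raises MissingUnitDose only in the sense of
    skipping: dose-less records are ignored here, the caller logs them.
    """
    if condition.type == "ALWAYS":
        return None
    if condition.type == "DURATION_OVER_8_WEEKS":
        _, pairs = duration_over_8_weeks(
            _event_dates(matching), condition.min_gap_days, condition.max_gap_days
        )
        # a duration event belongs to the year of the later date of the pair
        return {b.year for _, b in pairs}
    if condition.type == "CO_DISPENSED_WITH":
        partner_dates = _event_dates(
            [
                r
                for r in history
                if any(r.atc_code.startswith(p) for p in condition.atc_patterns)
            ]
        )
        index_dates = _event_dates(matching)
        # attribution: the year of the index (rule-drug) date of a qualifying pair
        return {
            a.year
            for a in index_dates
            if any(abs((a - b).days) <= condition.window_days for b in partner_dates)
        }
    if condition.type == "UNIT_DOSE_EXCEEDS":
        years: set[int] = set()
        for r in matching:
            dose = effective_unit_dose(r)
            if dose is None:
                logger.warning(
                    "unit dose unavailable for %s %r; dose rule skipped for this row",
                    r.atc_code,
                    r.medication_name,
                )
                continue
            if dose > condition.mg_per_day:
                years.add(r.dispense_date.year)
        return years
    if condition.type == "CHRONIC_USE":
        # chronicity is per ingredient (ATC level 5), not per rule class
        by_code: dict[str, list[date]] = {}
        for r in matching:
            by_code.setdefault(r.atc_code, []).append(r.dispense_date)
        years = set()
        for dates in by_code.values():
            distinct = {d for d in dates}
            for y in {d.year for d in distinct}:
                if chronic_in_year(sorted(distinct), y, condition.min_events):
                    years.add(y)
        return years
    if condition.type == "ROUTE_IS":
        return {
            r.dispense_date.year
            for r in matching
            if parse_route_form(r.medication_name).route == condition.value
        }
    if condition.type == "FORM_IS":
        return {
            r.dispense_date.year
            for r in matching
            if parse_route_form(r.medication_name).form == condition.value
        }
    if condition.type == "ALL_OF":
        result: set[int] | None = None
        for sub in condition.subconditions:
            sub_years = _condition_years(sub, matching, history)
            if sub_years is None:
                continue
            result = sub_years if result is None else result & sub_years
        return result
    raise AssertionError(f"unreachable condition type {condition.type}")


def evaluate_rule(
    patient_history: list[DispensingRecord],
    rule: PIMRule,
    year: int,
    catalog: BeersCatalog | None = None,
) -> PIMEvent | None:
    """Evaluate one rule for one patient and calendar year.

    An event is emitted iff the patient has a dispensation matching the
    rule's ATC patterns in *year* and the rule's condition holds with its
    year attribution landing in *year*. Triggers are the matching raw rows
    of that year.
    """
    matching = [r for r in patient_history if rule.matches(r.atc_code)]
    in_year = [r for r in matching if r.dispense_date.year == year]
    if not in_year:
        return None
    qualifying_years = _condition_years(rule.condition, matching, patient_history)
    if qualifying_years is not None and year not in qualifying_years:
        return None
    return PIMEvent(
        patient_id=in_year[0].patient_id,
        rule_id=rule.rule_id,
        category=rule.category,
        label=rule.label,
        year=year,
        trigger_dispensations=tuple(in_year),
    )


def detect_all(
    cohort: Cohort,
    records: list[DispensingRecord],
    catalog: BeersCatalog,
) -> list[PIMEvent]:
    """Evaluate every catalog rule for every cohort patient and window year.

    Deterministic output order: (patient_id, year, rule_id); at most one
    event per (patient, rule, year). Records of non-cohort patients and
    records outside the window contribute nothing (out-of-window records of
    a cohort patient still inform duration/co-dispensing lookback, but
    events are only attributed to window years).
    """
    by_patient: dict[str, list[DispensingRecord]] = {}
    for r in records:
        if r.patient_id in cohort:
            by_patient.setdefault(r.patient_id, []).append(r)

    rules = sorted(catalog.rules, key=lambda r: r.rule_id)
    window_years = set(cohort.window.years)
    events: list[PIMEvent] = []
    for pid in sorted(by_patient):
        history = sorted(by_patient[pid], key=lambda r: r.dispense_date)
        for rule in rules:
            matching = [r for r in history if rule.matches(r.atc_code)]
            if not matching:
                continue
            in_year: dict[int, list[DispensingRecord]] = {}
            for r in matching:
                y = r.dispense_date.year
                if y in window_years:
                    in_year.setdefault(y, []).append(r)
            if not in_year:
                continue
            cond_years = _condition_years(rule.condition, matching, history)
            for y in sorted(in_year):
                if cond_years is not None and y not in cond_years:
                    continue
                events.append(
                    PIMEvent(
                        patient_id=pid,
                        rule_id=rule.rule_id,
                        category=rule.category,
                        label=rule.label,
                        year=y,
                        trigger_dispensations=tuple(in_year[y]),
                    )
                )
    events.sort(key=lambda e: (e.patient_id, e.year, e.rule_id))
    return events


def events_to_frame(events: list[PIMEvent]):
    """Events as a tidy DataFrame (exportable to CSV)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": e.patient_id,
            "year": e.year,
            "rule_id": e.rule_id,
            "category": e.category,
            "label": e.label,
            "n_triggers": e.n_triggers,
            "first_trigger_date": e.first_trigger_date,
        }
        for e in events
    )
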