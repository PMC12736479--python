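"""Independent brute-force PIM evaluator used as the test oracle.

Deliberately naive: quadratic pair enumeration, per-year counting and
plain calendar arithmetic, re-derived from the rule definitions without
reusing the engine's predicates. Route/form conditions are out of scope
here (they are dictionary lookups, covered by direct unit tests); every
quantitative condition is re-implemented.
"""

from __future__ import annotations

import re
from datetime import date


def _completed_age(birth: date, ref: date) -> int:
    age = ref.year - birth.year
    if (ref.month, ref.day) < (birth.month, birth.day):
        age -= 1
    return age


def _strength_mg(name: str) -> float | None:
    m = re.search(r"(\d+(?:[.,]\d+)?)\s*(MG|G)\b", name, re.IGNORECASE)
    if not m:
        return None
    v = float(m.group(1).replace(",", "."))
    return v * 1000 if m.group(2).upper() == "G" else v


def _matched(records, patterns):
    return [r for r in records if any(r.atc_code.startswith(p) for p in patterns)]


def _condition_holds(condition, matched, history, year) -> bool:
    """Does *condition* fire with its year attribution landing in *year*?"""
    kind = condition.type
    if kind == "ALWAYS":
        return True
    if kind == "DURATION_OVER_8_WEEKS":
        dates = sorted({r.dispense_date for r in matched})
        for i in range(len(dates) - 1):
            gap = (dates[i + 1] - dates[i]).days
            if condition.min_gap_days < gap <= condition.max_gap_days:
                if dates[i + 1].year == year:
                    return True
        return False
    if kind == "CO_DISPENSED_WITH":
        partners = sorted(
            {r.dispense_date for r in _matched(history, condition.atc_patterns)}
        )
        index_dates = sorted({r.dispense_date for r in matched})
        for a in index_dates:
            if a.year != year:
                continue
            for b in partners:
                if abs((a - b).days) <= condition.window_days:
                    return True
        return False
    if kind == "UNIT_DOSE_EXCEEDS":
        for r in matched:
            if r.dispense_date.year != year:
                continue
            dose = r.unit_dose_mg
            if dose is None:
                dose = _strength_mg(r.medication_name)
            if dose is not None and dose > condition.mg_per_day:
                return True
        return False
    if kind == "CHRONIC_USE":
        by_code: dict[str, set[date]] = {}
        for r in matched:
            if r.dispense_date.year == year:
                by_code.setdefault(r.atc_code, set()).add(r.dispense_date)
        return any(len(dates) >= condition.min_events for dates in by_code.values())
    if kind == "ALL_OF":
        return all(
            _condition_holds(sub, matched, history, year)
            for sub in condition.subconditions
        )
    raise NotImplementedError(f"oracle does not cover {kind}")


def brute_force_detect(records, deaths, window, catalog) -> set[tuple[str, str, int]]:
    """All (patient_id, rule_id, year) hits by exhaustive enumeration."""
    death_by_id = {d.patient_id: d.death_date for d in deaths}
    by_patient: dict[str, list] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    hits: set[tuple[str, str, int]] = set()
    for pid, history in by_patient.items():
        birth = history[0].birth_date
        if _completed_age(birth, window.end) < 65:
            continue
        death = death_by_id.get(pid)
        if death is not None and death <= window.end:
            continue
        if not any(window.start <= r.dispense_date <= window.end for r in history):
            continue
        for rule in catalog.rules:
            matched = _matched(history, rule.atc_patterns)
            if not matched:
                continue
            for year in range(window.start.year, window.end.year + 1):
                if not any(
                    r.dispense_date.year == year
                    and window.start <= r.dispense_date <= window.end
                    for r in matched
                ):
                    continue
                if _condition_holds(rule.condition, matched, history, year):
                    hits.add((pid, rule.rule_id, year))
    return hits
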