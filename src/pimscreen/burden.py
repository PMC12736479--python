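"""Chronic users of strong anticholinergics and their cumulative ACB load.

A patient is a *chronic user* of an anticholinergic agent in a year when
that ingredient (ATC level 5) matches an ANTICHOLINERGIC catalog rule and
was dispensed on at least five distinct dates that year. The patient's
anticholinergic burden is the sum of per-agent ACB scores over the agents
used chronically that year; with every strong anticholinergic scoring 3,
three concurrent agents give a total of 9.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .catalog import BeersCatalog, acb_score_of
from .engine import chronic_in_year
from .io import DispensingRecord

logger = logging.getLogger(__name__)

#: Table-style class grouping for chronic anticholinergic agents, by ATC
#: prefix (first match wins); agents outside these classes are reported
#: under their own rule label.
DEFAULT_CLASS_GROUPS: tuple[tuple[str, str], ...] = (
    ("N06A", "Antidepressants"),
    ("N05A", "Antipsychotics"),
    ("G04BD", "Drugs for urinary frequency and incontinence"),
)


@dataclass(frozen=True)
class ChronicUserRecord:
    """One patient-year of chronic strong-anticholinergic use."""

    patient_id: str
    year: int
    chronic_agents: frozenset[str]
    acb_total: int

    def __post_init__(self) -> None:
        if not self.chronic_agents:
            raise ValueError("chronic_agents must be non-empty")


def chronic_anticholinergics(
    patient_history: list[DispensingRecord],
    year: int,
    catalog: BeersCatalog,
    min_events: int = 5,
) -> set[str]:
    """ATC level-5 agents used chronically in *year* that are strong
    anticholinergics per the catalog."""
    achol_rules = catalog.rules_of_category("ANTICHOLINERGIC")
    by_code: dict[str, set] = {}
    for r in patient_history:
        if any(rule.matches(r.atc_code) for rule in achol_rules):
            by_code.setdefault(r.atc_code, set()).add(r.dispense_date)
    return {
        code
        for code, dates in by_code.items()
        if chronic_in_year(sorted(dates), year, min_events)
    }


def acb_total(agents: set[str], catalog: BeersCatalog) -> int:
    """Sum of per-agent ACB scores (longest-prefix lookup; additive)."""
    total = 0
    for agent in sorted(agents):
        score = acb_score_of(agent, catalog)
        if score == 0:
            logger.warning("agent %s missing from ACB table; contributes 0", agent)
        total += score
    return total


def summarize_chronic_users(
    histories: dict[str, list[DispensingRecord]],
    year: int,
    catalog: BeersCatalog,
    class_groups: tuple[tuple[str, str], ...] = DEFAULT_CLASS_GROUPS,
    min_events: int = 5,
) -> tuple[list[ChronicUserRecord], dict[str, int]]:
    """Per-patient chronic-user records plus class frequencies for *year*.

    Class counts are patient-level: a patient chronic on two antidepressants
    counts once in the Antidepressants row. Agents outside the configured
    class prefixes are counted under the matching rule's label (e.g.
    "Trihexyphenidyl"). Percentages against the total number of chronic
    users are left to the caller (see reporting.percent).
    """
    users: list[ChronicUserRecord] = []
    class_members: dict[str, set[str]] = {}
    label_by_pattern = {
        p: r.label
        for r in catalog.rules_of_category("ANTICHOLINERGIC")
        for p in r.atc_patterns
    }
    for pid in sorted(histories):
        agents = chronic_anticholinergics(histories[pid], year, catalog, min_events)
        if not agents:
            continue
        users.append(
            ChronicUserRecord(
                patient_id=pid,
                year=year,
                chronic_agents=frozenset(agents),
                acb_total=acb_total(agents, catalog),
            )
        )
        for agent in agents:
            group = None
            for prefix, name in class_groups:
                if agent.startswith(prefix):
                    group = name
                    break
            if group is None:
                hits = [
                    label
                    for p, label in label_by_pattern.items()
                    if agent.startswith(p)
                ]
                group = hits[0] if hits else agent
            class_members.setdefault(group, set()).add(pid)
    frequencies = {name: len(pids) for name, pids in sorted(class_members.items())}
    return users, frequencies


def chronic_users_to_frame(users: list[ChronicUserRecord]):
    """Chronic-user records as a DataFrame (CSV-exportable)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": u.patient_id,
            "year": u.year,
            "n_agents": len(u.chronic_agents),
            "acb_total": u.acb_total,
            "agents": ";".join(sorted(u.chronic_agents)),
        }
        for u in users
    )
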