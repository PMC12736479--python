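"""Machine-readable PIM rule catalog and anticholinergic-burden score table.

The catalog renders an explicit prescribing-criteria set (the 2019 American
Geriatrics Society Beers Criteria, restricted to rules decidable from
dispensing data alone) as a list of :class:`PIMRule` entries keyed by ATC
prefixes, each with a :class:`Condition` stating when a dispensation
pattern makes the drug potentially inappropriate. It also carries the
Anticholinergic Cognitive Burden (ACB) score table used to total per-patient
anticholinergic load.

Rules match by ATC prefix so a single entry covers a whole chemical
subgroup (e.g. ``A10BB`` for all sulfonylureas); the ACB lookup resolves by
longest prefix so a specific ingredient can override its class score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import yaml

from .io import is_valid_atc_code, is_valid_atc_prefix

CATEGORIES = ("AVOID", "CAUTION", "ANTICHOLINERGIC")

ROUTES = (
    "ORAL",
    "PARENTERAL",
    "TOPICAL",
    "TRANSDERMAL",
    "RECTAL",
    "OPHTHALMIC",
    "OTHER",
    "UNKNOWN",
)
FORMS = (
    "TABLET",
    "CAPSULE",
    "SOLUTION",
    "CREAM",
    "PATCH",
    "SUPPOSITORY",
    "DROPS",
    "OTHER",
    "UNKNOWN",
)


class CatalogError(ValueError):
    """Catalog file failed validation; message lists offending entries."""


@dataclass(frozen=True)
class Condition:
    """Applicability condition of a PIM rule.

    Variants (``type``):

    - ``ALWAYS`` — any dispensation qualifies.
    - ``DURATION_OVER_8_WEEKS`` — some pair of consecutive dispensing dates
      is more than ``min_gap_days`` apart and within ``max_gap_days``
      (screen for use extending beyond 8 weeks).
    - ``CO_DISPENSED_WITH`` — a dispensation of ``atc_patterns`` occurs
      within ``window_days`` of a dispensation matching the rule.
    - ``UNIT_DOSE_EXCEEDS`` — the unit dose exceeds ``mg_per_day`` mg
      (unit dose as a daily-dose proxy).
    - ``CHRONIC_USE`` — at least ``min_events`` dispensing events of one
      ingredient within the calendar year.
    - ``ROUTE_IS`` / ``FORM_IS`` — administration route / pharmaceutical
      form parsed from the medication name equals ``value``.
    - ``ALL_OF`` — every sub-condition holds.
    """

    type: str
    min_gap_days: int = 56
    max_gap_days: int = 180
    atc_patterns: tuple[str, ...] = ()
    window_days: int = 90
    mg_per_day: float = 0.0
    min_events: int = 5
    value: str = ""
    subconditions: tuple["Condition", ...] = ()

    _TYPES = (
        "ALWAYS",
        "DURATION_OVER_8_WEEKS",
        "CO_DISPENSED_WITH",
        "UNIT_DOSE_EXCEEDS",
        "CHRONIC_USE",
        "ROUTE_IS",
        "FORM_IS",
        "ALL_OF",
    )

    def __post_init__(self) -> None:
        if self.type not in self._TYPES:
            raise CatalogError(f"unknown condition variant: {self.type!r}")
        if self.type == "DURATION_OVER_8_WEEKS":
            if not (0 < self.min_gap_days < self.max_gap_days):
                raise CatalogError("need 0 < min_gap_days < max_gap_days")
        if self.type == "CO_DISPENSED_WITH":
            if self.window_days <= 0:
                raise CatalogError("window_days must be positive")
            if not self.atc_patterns:
                raise CatalogError("CO_DISPENSED_WITH needs atc_patterns")
            bad = [p for p in self.atc_patterns if not is_valid_atc_prefix(p)]
            if bad:
                raise CatalogError(f"invalid ATC prefix(es): {bad}")
        if self.type == "CHRONIC_USE" and self.min_events < 1:
            raise CatalogError("min_events must be >= 1")
        if self.type == "ROUTE_IS" and self.value not in ROUTES:
            raise CatalogError(f"unknown route {self.value!r}")
        if self.type == "FORM_IS" and self.value not in FORMS:
            raise CatalogError(f"unknown form {self.value!r}")
        if self.type == "ALL_OF" and not self.subconditions:
            raise CatalogError("ALL_OF needs at least one sub-condition")


ALWAYS = Condition("ALWAYS")


@dataclass(frozen=True)
class PIMRule:
    """One catalog entry: ATC patterns + category + applicability condition."""

    rule_id: str
    category: str
    label: str
    atc_patterns: tuple[str, ...]
    condition: Condition = ALWAYS
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"rule {self.rule_id}: category must be one of {CATEGORIES}"
            )
        if not self.atc_patterns:
            raise CatalogError(f"rule {self.rule_id}: no ATC patterns")
        bad = [p for p in self.atc_patterns if not is_valid_atc_prefix(p)]
        if bad:
            raise CatalogError(f"rule {self.rule_id}: invalid ATC prefix(es) {bad}")

    def matches(self, atc_code: str) -> bool:
        return any(atc_code.startswith(p) for p in self.atc_patterns)


@dataclass(frozen=True)
class ACBEntry:
    """ACB score (1–3) for an ATC prefix; specific codes override classes."""

    atc_pattern: str
    score: int

    def __post_init__(self) -> None:
        if not is_valid_atc_prefix(self.atc_pattern):
            raise CatalogError(f"invalid ATC prefix: {self.atc_pattern!r}")
        if self.score not in (1, 2, 3):
            raise CatalogError(f"ACB score must be 1, 2 or 3, got {self.score}")


@dataclass(frozen=True)
class BeersCatalog:
    """A validated rule catalog plus ACB table."""

    rules: tuple[PIMRule, ...]
    acb_table: tuple[ACBEntry, ...]
    version_tag: str = "unversioned"

    def __post_init__(self) -> None:
        validate_catalog(self)

    def rules_of_category(self, category: str) -> list[PIMRule]:
        return [r for r in self.rules if r.category == category]


def validate_catalog(catalog: BeersCatalog) -> None:
    """Raise :class:`CatalogError` listing every invalid entry."""
    problems: list[str] = []
    seen: set[str] = set()
    for rule in catalog.rules:
        if rule.rule_id in seen:
            problems.append(f"duplicate rule_id: {rule.rule_id}")
        seen.add(rule.rule_id)
    acb_seen: set[str] = set()
    for entry in catalog.acb_table:
        if entry.atc_pattern in acb_seen:
            problems.append(f"duplicate ACB pattern: {entry.atc_pattern}")
        acb_seen.add(entry.atc_pattern)
    if problems:
        raise CatalogError("; ".join(problems))


def match_rules(atc_code: str, catalog: BeersCatalog) -> list[PIMRule]:
    """Every rule with a pattern that prefixes *atc_code*, rule_id ascending."""
    if not is_valid_atc_code(atc_code):
        raise ValueError(f"invalid ATC level-5 code: {atc_code!r}")
    hits = [r for r in catalog.rules if r.matches(atc_code)]
    return sorted(hits, key=lambda r: r.rule_id)


def acb_score_of(atc_code: str, catalog: BeersCatalog) -> int:
    """ACB score for an ingredient: longest-prefix match, 0 when unlisted."""
    if not is_valid_atc_code(atc_code):
        raise ValueError(f"invalid ATC level-5 code: {atc_code!r}")
    best_len = -1
    best = 0
    for entry in catalog.acb_table:
        p = entry.atc_pattern
        if atc_code.startswith(p) and len(p) > best_len:
            best_len = len(p)
            best = entry.score
    return best


def _condition_from_dict(d: dict) -> Condition:
    if not isinstance(d, dict) or "type" not in d:
        raise CatalogError(f"condition must be a mapping with 'type', got {d!r}")
    kind = d["type"]
    params = {k: v for k, v in d.items() if k != "type"}
    if kind == "ALL_OF":
        subs = tuple(_condition_from_dict(s) for s in params.pop("subconditions", []))
        return Condition("ALL_OF", subconditions=subs, **params)
    if "atc_patterns" in params:
        params["atc_patterns"] = tuple(params["atc_patterns"])
    try:
        return Condition(kind, **params)
    except TypeError as exc:
        raise CatalogError(f"bad condition parameters for {kind}: {exc}") from exc


def _condition_to_dict(c: Condition) -> dict:
    d: dict = {"type": c.type}
    if c.type == "DURATION_OVER_8_WEEKS":
        d.update(min_gap_days=c.min_gap_days, max_gap_days=c.max_gap_days)
    elif c.type == "CO_DISPENSED_WITH":
        d.update(atc_patterns=list(c.atc_patterns), window_days=c.window_days)
    elif c.type == "UNIT_DOSE_EXCEEDS":
        d.update(mg_per_day=c.mg_per_day)
    elif c.type == "CHRONIC_USE":
        d.update(min_events=c.min_events)
    elif c.type in ("ROUTE_IS", "FORM_IS"):
        d.update(value=c.value)
    elif c.type == "ALL_OF":
        d.update(subconditions=[_condition_to_dict(s) for s in c.subconditions])
    return d


def load_catalog(source: str | Path | IO[str] | None = None) -> BeersCatalog:
    """Load and validate a YAML catalog; *None* loads the shipped default."""
    if source is None:
        text = (
            importlib.resources.files("pimscreen")
            .joinpath("data/default_catalog.yaml")
            .read_text(encoding="utf-8")
        )
        doc = yaml.safe_load(text)
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise CatalogError("catalog must be a mapping with a 'rules' list")
    rules = []
    for entry in doc["rules"]:
        condition = (
            _condition_from_dict(entry["condition"]) if "condition" in entry else ALWAYS
        )
        rules.append(
            PIMRule(
                rule_id=str(entry["id"]),
                category=str(entry["category"]),
                label=str(entry["label"]),
                atc_patterns=tuple(entry["atc"]),
                condition=condition,
                rationale=str(entry.get("rationale", "")),
            )
        )
    acb = [
        ACBEntry(atc_pattern=str(e["atc"]), score=int(e["score"]))
        for e in doc.get("acb", [])
    ]
    return BeersCatalog(
        rules=tuple(rules),
        acb_table=tuple(acb),
        version_tag=str(doc.get("version", "unversioned")),
    )


def serialize_catalog(catalog: BeersCatalog, sink: str | Path | IO[str]) -> None:
    """Write a catalog back to YAML; reloads to an equal catalog."""
    doc = {
        "version": catalog.version_tag,
        "rules": [
            {
                "id": r.rule_id,
                "category": r.category,
                "label": r.label,
                "atc": list(r.atc_patterns),
                "condition": _condition_to_dict(r.condition),
                "rationale": r.rationale,
            }
            for r in catalog.rules
        ],
        "acb": [{"atc": e.atc_pattern, "score": e.score} for e in catalog.acb_table],
    }
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        yaml.safe_dump(doc, sink, sort_keys=False)
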