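"""Annual prevalence, descriptive statistics and ranked PIM frequency tables.

Annual prevalence is crude: distinct patients with at least one detected
PIM event in a year over distinct older adults with any dispensation that
year. Every printed percentage uses half-up rounding at one decimal.
Ranked tables group events by rule label (class rules are already grouped
at ATC level 4 by the catalog) and report, per category-year, the share of
category patients hit by each group.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .cohort import Cohort, age_at
from .engine import PIMEvent
from .io import is_valid_atc_code


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with half-up rounding at *decimals* places.

    Half-up (not banker's) rounding matches how descriptive tables print
    percentages; ``percent(65807, 115962) == 56.7``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("need 0 <= numerator <= denominator")
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceCell:
    """One stratum-year prevalence: numerator/denominator and the percent."""

    stratum: str
    year: int | str
    numerator: int
    denominator: int
    percent: float


@dataclass(frozen=True)
class RankRow:
    """One row of a ranked PIM frequency table (dense ranks, label ties)."""

    year: int
    category: str
    rank: int
    label: str
    n_patients: int
    percent: float


def annual_prevalence(
    events: list[PIMEvent],
    cohort: Cohort,
    category: str | None = None,
    stratum: str = "all",
) -> list[PrevalenceCell]:
    """Per-year prevalence cells plus a whole-window "total" cell.

    *category* filters events (AVOID / CAUTION / ANTICHOLINERGIC); the
    denominator is always the set of patients with any dispensation.
    """
    filtered = [e for e in events if category is None or e.category == category]
    by_year: dict[int, set[str]] = {}
    for e in filtered:
        by_year.setdefault(e.year, set()).add(e.patient_id)
    cells = []
    for year in cohort.window.years:
        if year not in cohort.yearly_denominators:
            raise ValueError(f"no denominator for year {year}")
        denom = len(cohort.yearly_denominators[year])
        numer = len(by_year.get(year, set()))
        cells.append(
            PrevalenceCell(
                stratum=stratum,
                year=year,
                numerator=numer,
                denominator=denom,
                percent=percent(numer, denom) if denom else 0.0,
            )
        )
    total_numer = len({e.patient_id for e in filtered})
    total_denom = len(set().union(*cohort.yearly_denominators.values()))
    cells.append(
        PrevalenceCell(
            stratum=stratum,
            year="total",
            numerator=total_numer,
            denominator=total_denom,
            percent=percent(total_numer, total_denom) if total_denom else 0.0,
        )
    )
    return cells


def rank_pims(
    events: list[PIMEvent],
    year: int,
    category: str,
    top_k: int = 6,
    min_percent: float | None = None,
) -> list[RankRow]:
    """Top-k PIM groups of one category-year, by distinct patients.

    The denominator is the number of distinct patients with any event of
    *category* in *year*; groups are rule labels. Ties break by label.
    *min_percent* drops groups at or below the threshold (e.g. 2.0 keeps
    only PIMs dispensed to more than 2% of the category's patients).
    """
    in_scope = [e for e in events if e.year == year and e.category == category]
    denominator = len({e.patient_id for e in in_scope})
    if denominator == 0:
        return []
    by_label: dict[str, set[str]] = {}
    for e in in_scope:
        by_label.setdefault(e.label, set()).add(e.patient_id)
    ordered = sorted(by_label.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = []
    for rank, (label, pids) in enumerate(ordered[:top_k], start=1):
        pct = percent(len(pids), denominator)
        if min_percent is not None and pct <= min_percent:
            continue
        rows.append(
            RankRow(
                year=year,
                category=category,
                rank=rank,
                label=label,
                n_patients=len(pids),
                percent=pct,
            )
        )
    return rows


def group_atc_level4(atc_code: str) -> str:
    """ATC level-4 (chemical subgroup) prefix of a level-5 code."""
    if not is_valid_atc_code(atc_code):
        import logging

        logging.getLogger(__name__).warning(
            "not a level-5 ATC code: %r; returned unchanged", atc_code
        )
        return atc_code
    return atc_code[:5]


def _median_iqr(values: list[float]) -> tuple[float, float, float]:
    """Median and quartiles with linear interpolation between order stats."""
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def summarize_sample(
    cohort: Cohort,
    events: list[PIMEvent],
    year: int | None = None,
) -> dict:
    """Descriptive summary of patients with PIMs (whole window or one year).

    Reports: number of patients with at least one PIM, males n (%), median
    [IQR] age at window end, median [IQR] PIM dispensations per patient
    (trigger dispensations, i.e. rows that fired a rule), and per-category
    patient counts with percentages of the with-PIM population.
    """
    scoped = [e for e in events if year is None or e.year == year]
    pim_patients = sorted({e.patient_id for e in scoped})
    n = len(pim_patients)
    summary: dict = {"year": "total" if year is None else year, "n_patients": n}
    if n == 0:
        return summary
    males = sum(1 for pid in pim_patients if cohort.patients[pid].sex == "M")
    ages = [
        age_at(cohort.patients[pid].birth_date, cohort.window.end)
        for pid in pim_patients
    ]
    # PIM dispensations per patient: distinct trigger rows across events
    triggers_per_patient = {pid: set() for pid in pim_patients}
    for e in scoped:
        triggers_per_patient[e.patient_id].update(
            (r.dispense_date, r.atc_code) for r in e.trigger_dispensations
        )
    counts = [len(v) for v in triggers_per_patient.values()]
    med_age, a_q1, a_q3 = _median_iqr(ages)
    med_pim, p_q1, p_q3 = _median_iqr([float(c) for c in counts])
    summary.update(
        males_n=males,
        males_percent=percent(males, n),
        age_median=med_age,
        age_iqr=(a_q1, a_q3),
        pims_per_patient_median=med_pim,
        pims_per_patient_iqr=(p_q1, p_q3),
    )
    for category in ("AVOID", "CAUTION", "ANTICHOLINERGIC"):
        cat_pids = {e.patient_id for e in scoped if e.category == category}
        summary[f"{category.lower()}_n"] = len(cat_pids)
        summary[f"{category.lower()}_percent"] = percent(len(cat_pids), n)
    return summary


def prevalence_to_frame(cells: list[PrevalenceCell]):
    import pandas as pd

    return pd.DataFrame(
        {
            "stratum": c.stratum,
            "year": c.year,
            "numerator": c.numerator,
            "denominator": c.denominator,
            "percent": c.percent,
        }
        for c in cells
    )


def ranks_to_frame(rows: list[RankRow]):
    import pandas as pd

    return pd.DataFrame(
        {
            "year": r.year,
            "category": r.category,
            "rank": r.rank,
            "label": r.label,
            "n_patients": r.n_patients,
            "percent": r.percent,
        }
        for r in rows
    )
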