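"""Reading, validating and writing dispensing-claims and death-registry tables.

Claims arrive as delimited text with a header row, one row per reimbursed
dispensation. The canonical dialect is comma-separated with ISO 8601 dates,
but local exports vary, so a :class:`DialectConfig` carries the delimiter,
the date pattern and the error policy (strict: any malformed row aborts the
run; lenient: malformed rows are skipped and reported).
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import IO, Iterable, Sequence

logger = logging.getLogger(__name__)

#: ATC level-5 code: anatomical letter, 2 digits, 2 letters, 2 digits.
ATC_LEVEL5_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: Valid prefix lengths at ATC level boundaries (levels 1, 2, 3, 4, 5).
ATC_PREFIX_LENGTHS = (1, 3, 4, 5, 7)

_ATC_PREFIX_RES = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    7: ATC_LEVEL5_RE,
}

SEXES = ("M", "F", "U")


def is_valid_atc_code(code: str) -> bool:
    """True iff *code* is a syntactically valid 7-character ATC level-5 code."""
    return bool(ATC_LEVEL5_RE.match(code))


def is_valid_atc_prefix(pattern: str) -> bool:
    """True iff *pattern* is an ATC prefix cut at a level boundary."""
    rx = _ATC_PREFIX_RES.get(len(pattern))
    return bool(rx and rx.match(pattern))


class SchemaError(ValueError):
    """A mandatory column is missing or the header is unreadable."""


class RowError(ValueError):
    """A single data row failed validation (strict mode only)."""


@dataclass(frozen=True)
class RowProblem:
    """One rejected input row, with its 1-based row number and the reason."""

    row_number: int
    message: str


@dataclass(frozen=True)
class DialectConfig:
    """Delimited-text dialect for claims and death-registry files."""

    delimiter: str = ","
    date_format: str = "%Y-%m-%d"
    strict: bool = True

    def parse_date(self, text: str) -> date:
        return datetime.strptime(text.strip(), self.date_format).date()

    def format_date(self, d: date) -> str:
        return d.strftime(self.date_format)


@dataclass(frozen=True)
class DispensingRecord:
    """One reimbursed dispensation event.

    ``atc_code`` is the WHO ATC level-5 code identifying the active
    ingredient; ``medication_name`` keeps the free-text brand/strength/form
    string that route and strength parsing operate on. ``unit_dose_mg`` is
    the strength of one dose unit, when known.
    """

    patient_id: str
    birth_date: date
    sex: str
    dispense_date: date
    atc_code: str
    medication_name: str
    n_packages: int
    unit_dose_mg: float | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not is_valid_atc_code(self.atc_code):
            raise ValueError(f"invalid ATC level-5 code: {self.atc_code!r}")
        if self.dispense_date < self.birth_date:
            raise ValueError("dispense_date precedes birth_date")
        if self.n_packages < 1:
            raise ValueError("n_packages must be >= 1")
        if self.unit_dose_mg is not None and self.unit_dose_mg < 0:
            raise ValueError("unit_dose_mg must be non-negative")


@dataclass(frozen=True)
class DeathRecord:
    """One death-registry entry (at most one per patient after ingest)."""

    patient_id: str
    death_date: date

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


DISPENSING_COLUMNS = (
    "patient_id",
    "birth_date",
    "sex",
    "dispense_date",
    "atc_code",
    "medication_name",
    "n_packages",
)
OPTIONAL_DISPENSING_COLUMNS = ("unit_dose_mg",)
DEATH_COLUMNS = ("patient_id", "death_date")


def _open_source(source: str | Path | IO[str]):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _open_sink(sink: str | Path | IO[str]):
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8", newline=""), True
    return sink, False


def normalize_sex(raw: str) -> str:
    """Map arbitrary sex codes onto {M, F, U}; anything unrecognised is U."""
    up = raw.strip().upper()
    if up in ("M", "MALE"):
        return "M"
    if up in ("F", "FEMALE"):
        return "F"
    return "U"


def _parse_dispensing_row(
    row: dict[str, str], dialect: DialectConfig
) -> DispensingRecord:
    atc = row["atc_code"].strip().upper()
    dose_text = (row.get("unit_dose_mg") or "").strip()
    return DispensingRecord(
        patient_id=row["patient_id"].strip(),
        birth_date=dialect.parse_date(row["birth_date"]),
        sex=normalize_sex(row["sex"]),
        dispense_date=dialect.parse_date(row["dispense_date"]),
        atc_code=atc,
        medication_name=row["medication_name"].strip(),
        n_packages=int(row["n_packages"]),
        unit_dose_mg=float(dose_text) if dose_text else None,
    )


def read_dispensing(
    source: str | Path | IO[str],
    dialect: DialectConfig = DialectConfig(),
    errors: list[RowProblem] | None = None,
) -> list[DispensingRecord]:
    """Read a dispensing-claims table.

    Row order is preserved; every returned record satisfies the
    :class:`DispensingRecord` invariants (ATC uppercased, dates parsed,
    positive package count). Malformed rows raise :class:`RowError` in
    strict mode; in lenient mode they are skipped and appended to *errors*
    (and logged) with their 1-based data-row number.
    """
    if errors is None:
        errors = []
    fh, close = _open_source(source)
    try:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise SchemaError("empty input: no header row")
        missing = [c for c in DISPENSING_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        out: list[DispensingRecord] = []
        for i, row in enumerate(reader, start=1):
            try:
                out.append(_parse_dispensing_row(row, dialect))
            except (ValueError, KeyError) as exc:
                problem = RowProblem(i, str(exc))
                if dialect.strict:
                    raise RowError(f"row {i}: {exc}") from exc
                errors.append(problem)
                logger.warning("skipping malformed claims row %d: %s", i, exc)
        return out
    finally:
        if close:
            fh.close()


def read_deaths(
    source: str | Path | IO[str],
    dialect: DialectConfig = DialectConfig(),
    errors: list[RowProblem] | None = None,
) -> list[DeathRecord]:
    """Read a death-registry table, keeping the earliest date per patient.

    Duplicate patient_ids are collapsed to the earliest death_date with a
    warning; output order follows first appearance.
    """
    if errors is None:
        errors = []
    fh, close = _open_source(source)
    try:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        if reader.fieldnames is None:
            raise SchemaError("empty input: no header row")
        missing = [c for c in DEATH_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        earliest: dict[str, date] = {}
        order: list[str] = []
        for i, row in enumerate(reader, start=1):
            try:
                pid = row["patient_id"].strip()
                if not pid:
                    raise ValueError("patient_id must be non-empty")
                dd = dialect.parse_date(row["death_date"])
            except (ValueError, KeyError) as exc:
                if dialect.strict:
                    raise RowError(f"row {i}: {exc}") from exc
                errors.append(RowProblem(i, str(exc)))
                logger.warning("skipping malformed death row %d: %s", i, exc)
                continue
            if pid in earliest:
                logger.warning(
                    "duplicate death record for %s; keeping earliest date", pid
                )
                earliest[pid] = min(earliest[pid], dd)
            else:
                earliest[pid] = dd
                order.append(pid)
        return [DeathRecord(pid, earliest[pid]) for pid in order]
    finally:
        if close:
            fh.close()


def write_records(
    records: Sequence[DispensingRecord],
    sink: str | Path | IO[str],
    dialect: DialectConfig = DialectConfig(),
) -> int:
    """Write dispensing records; returns the number of data rows written.

    Round-trip guarantee: ``read_dispensing(write_records(x)) == x`` in the
    same dialect. ``unit_dose_mg`` is emitted only when some record has one.
    """
    with_dose = any(r.unit_dose_mg is not None for r in records)
    columns = DISPENSING_COLUMNS + (OPTIONAL_DISPENSING_COLUMNS if with_dose else ())
    fh, close = _open_sink(sink)
    try:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(columns)
        n = 0
        for r in records:
            row = [
                r.patient_id,
                dialect.format_date(r.birth_date),
                r.sex,
                dialect.format_date(r.dispense_date),
                r.atc_code,
                r.medication_name,
                str(r.n_packages),
            ]
            if with_dose:
                row.append("" if r.unit_dose_mg is None else repr(r.unit_dose_mg))
            writer.writerow(row)
            n += 1
        return n
    finally:
        if close:
            fh.close()


def write_deaths(
    records: Sequence[DeathRecord],
    sink: str | Path | IO[str],
    dialect: DialectConfig = DialectConfig(),
) -> int:
    """Write death-registry records; returns the number of data rows."""
    fh, close = _open_sink(sink)
    try:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(DEATH_COLUMNS)
        for r in records:
            writer.writerow([r.patient_id, dialect.format_date(r.death_date)])
        return len(records)
    finally:
        if close:
            fh.close()


def records_to_frame(records: Iterable[DispensingRecord]):
    """Dispensing records as a pandas DataFrame (one row per dispensation)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "patient_id": r.patient_id,
            "birth_date": r.birth_date,
            "sex": r.sex,
            "dispense_date": r.dispense_date,
            "atc_code": r.atc_code,
            "medication_name": r.medication_name,
            "n_packages": r.n_packages,
            "unit_dose_mg": r.unit_dose_mg,
        }
        for r in records
    )
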