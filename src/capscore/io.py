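"""Cohort CSV reading/writing and the per-patient score table.

Dialect: comma-separated, UTF-8, header row required; missing values are an
empty field or ``NA``.  Row-level validation failures are collected and
reported together with their line numbers rather than aborting on the first.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence, Union

from .records import PatientRecord, Sex
from .scoring import ScoreResult

__all__ = ["CohortLoadError", "read_cohort", "write_cohort", "write_scores"]

_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "confusion",
    "urea",
    "resp_rate",
    "sbp",
    "dbp",
    "heart_rate",
    "temperature",
    "died_6wk",
    "icu_6wk",
]

_MISSING = {"", "NA"}
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class CohortLoadError(ValueError):
    """Aggregated row-level load failures, each tagged with its line number."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("cohort load failed:\n" + "\n".join(errors))


def _parse_bool(raw: str, field: str) -> bool:
    lowered = raw.strip().lower()
    if lowered in _TRUE:
        return True
    if lowered in _FALSE:
        return False
    raise ValueError(f"{field}: cannot parse {raw!r} as boolean")


def _parse_row(row: dict) -> PatientRecord:
    def opt(field):
        raw = (row[field] or "").strip()
        return None if raw in _MISSING else raw

    confusion_raw = opt("confusion")
    urea_raw = opt("urea")
    return PatientRecord(
        patient_id=row["patient_id"].strip(),
        age=int(row["age"]),
        sex=Sex(row["sex"].strip().lower()),
        confusion=None
        if confusion_raw is None
        else _parse_bool(confusion_raw, "confusion"),
        urea=None if urea_raw is None else float(urea_raw),
        resp_rate=int(row["resp_rate"]),
        sbp=float(row["sbp"]),
        dbp=float(row["dbp"]),
        heart_rate=float(row["heart_rate"]),
        temperature=float(row["temperature"]),
        died_6wk=_parse_bool(row["died_6wk"], "died_6wk"),
        icu_6wk=_parse_bool(row["icu_6wk"], "icu_6wk"),
    )


def read_cohort(path: Union[str, Path]) -> list[PatientRecord]:
    """Read and validate a cohort CSV; collect row errors with line numbers."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise CohortLoadError(["file is empty (no header row)"])
        unknown = set(reader.fieldnames) - set(_COLUMNS)
        missing = set(_COLUMNS) - set(reader.fieldnames)
        if unknown or missing:
            problems = []
            if unknown:
                problems.append(f"unknown columns: {sorted(unknown)}")
            if missing:
                problems.append(f"missing columns: {sorted(missing)}")
            raise CohortLoadError(problems)
        records: list[PatientRecord] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise CohortLoadError(errors)
    return records


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return repr(value)  # shortest representation that round-trips exactly
    return str(value)


def write_cohort(cohort: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write a cohort CSV in the dialect :func:`read_cohort` accepts."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_COLUMNS)
        for r in cohort:
            writer.writerow(
                [
                    r.patient_id,
                    r.age,
                    r.sex.value,
                    _fmt(r.confusion),
                    _fmt(r.urea),
                    r.resp_rate,
                    _fmt(r.sbp),
                    _fmt(r.dbp),
                    _fmt(r.heart_rate),
                    _fmt(r.temperature),
                    _fmt(r.died_6wk),
                    _fmt(r.icu_6wk),
                ]
            )


def write_scores(results: Sequence[ScoreResult], path: Union[str, Path]) -> None:
    """Write the per-(patient, criterion) score table as CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "patient_id",
                "criterion",
                "component_flags",
                "score_lower",
                "score_upper",
                "severity",
                "disposition",
            ]
        )
        for r in results:
            flags = ";".join("NA" if f is None else str(f) for f in r.component_flags)
            writer.writerow(
                [
                    r.patient_id,
                    r.criterion.value,
                    flags,
                    r.score_lower,
                    r.score_upper,
                    r.severity.value,
                    r.disposition.value,
                ]
            )
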