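"""Shared data model for prescription-register extracts and tabular I/O.

One dispensation is one register row: person, drug (ATC code + Nordic
article number), strength and package information, dispensation date,
prescriber context and the free-text dosing instruction.  Register extracts
are flat UTF-8 CSV tables with ISO-8601 dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: columns every register extract must provide, in canonical order
RECORD_COLUMNS = [
    "person_id", "age", "sex", "atc", "article_number", "dispensation_date",
    "n_packages", "package_size", "strength_mg", "specialty", "county",
    "free_text", "returned",
]

PERIOD_COLUMNS = [
    "person_id", "atc", "stratum_start", "stratum_end",
    "dose_mg_per_day", "pills_per_day", "n_dispensations",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass(frozen=True)
class GoldLabel:
    """Reviewer gold standard for one sig text (or titration segment).

    ``dosage_class`` is present exactly when the text is informative.
    """

    informative: bool
    dosage_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.informative == (self.dosage_class is None):
            raise ValueError(
                "dosage_class must be present iff the text is informative"
            )


@dataclass
class PrescriptionRecord:
    """One dispensation row of the register."""

    person_id: str
    age: int
    sex: str
    atc: str
    article_number: str
    dispensation_date: date
    n_packages: int
    package_size: int
    strength_mg: float
    specialty: str
    county: str
    free_text: str
    returned: bool

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.n_packages < 1:
            raise ValueError(f"n_packages must be >= 1, got {self.n_packages}")
        if self.package_size < 1:
            raise ValueError(
                f"package_size must be >= 1, got {self.package_size}"
            )
        if self.strength_mg <= 0:
            raise ValueError(f"strength_mg must be > 0, got {self.strength_mg}")

    @property
    def pills_total(self) -> float:
        return self.n_packages * self.package_size


@dataclass
class RowError:
    """A row that failed validation, kept for audit (never silently dropped)."""

    row_index: int
    message: str


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def record_from_row(row, row_index: int = -1) -> PrescriptionRecord:
    return PrescriptionRecord(
        person_id=str(row["person_id"]),
        age=int(row["age"]),
        sex=str(row["sex"]),
        atc=str(row["atc"]),
        article_number=str(row["article_number"]),
        dispensation_date=date.fromisoformat(str(row["dispensation_date"])),
        n_packages=int(row["n_packages"]),
        package_size=int(row["package_size"]),
        strength_mg=float(row["strength_mg"]),
        specialty=str(row["specialty"]),
        county=str(row["county"]),
        free_text="" if pd.isna(row["free_text"]) else str(row["free_text"]),
        returned=_parse_bool(row["returned"]),
    )


def read_prescriptions(
    path, *, sep: str = ",", collect_errors: bool = False
) -> list[PrescriptionRecord] | tuple[list[PrescriptionRecord], list[RowError]]:
    """Read a register extract CSV into validated records, order preserved.

    With ``collect_errors=True`` invalid rows are returned as
    :class:`RowError` entries alongside the valid records, so that
    ``len(records) + len(errors)`` equals the number of data rows.
    Otherwise the first invalid row raises.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    records: list[PrescriptionRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(record_from_row(row, i))
        except (ValueError, KeyError) as exc:
            if not collect_errors:
                raise ValueError(f"row {i}: {exc}") from exc
            errors.append(RowError(i, str(exc)))
    if collect_errors:
        return records, errors
    return records


def records_to_frame(records: Iterable[PrescriptionRecord]) -> pd.DataFrame:
    rows = [
        {
            **{c: getattr(r, c) for c in RECORD_COLUMNS if c != "dispensation_date"},
            "dispensation_date": r.dispensation_date.isoformat(),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_prescriptions(records: Sequence[PrescriptionRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_periods(periods: Sequence, path) -> None:
    """Write treatment periods as one CSV row per dose stratum."""
    rows = []
    for p in periods:
        for s in p.strata:
            rows.append(
                {
                    "person_id": p.person_id,
                    "atc": p.atc,
                    "stratum_start": s.start.isoformat(),
                    "stratum_end": s.end.isoformat(),
                    "dose_mg_per_day": s.mg_per_day,
                    "pills_per_day": s.pills_per_day,
                    "n_dispensations": p.n_dispensations,
                }
            )
    pd.DataFrame(rows, columns=PERIOD_COLUMNS).to_csv(path, index=False)


def read_periods(path) -> pd.DataFrame:
    """Read a period table back; inverse of :func:`write_periods` at the
    stratum level."""
    df = pd.read_csv(path, dtype={"person_id": str, "atc": str})
    missing = [c for c in PERIOD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df
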