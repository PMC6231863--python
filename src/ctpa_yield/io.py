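"""Read and write the five flat EHR tables as comma-delimited UTF-8 text.

Each table kind has a fixed header; every row is validated against its
record type's invariants before acceptance. Errors name the missing column,
the 1-based data-row number and field, or the duplicated key — rows are
never silently dropped. write_table/read_table form a field-for-field
round trip.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import IntegrityError, RowValidationError, SchemaError
from .model import (
    DiagnosisRank,
    DischargeDiagnosis,
    Disposition,
    EDEncounter,
    GoldStandardLabel,
    ICDVersion,
    ImagingOrder,
    InpatientAdmission,
    OrderStatus,
    OrderType,
)

__all__ = ["TableKind", "read_table", "write_table", "TABLE_FILENAMES"]


class TableKind(Enum):
    ORDERS = "orders"
    ED_ENCOUNTERS = "ed_encounters"
    ADMISSIONS = "admissions"
    DIAGNOSES = "diagnoses"
    GOLD_LABELS = "gold_labels"


#: conventional file name for each table kind
TABLE_FILENAMES = {
    TableKind.ORDERS: "orders.csv",
    TableKind.ED_ENCOUNTERS: "ed_encounters.csv",
    TableKind.ADMISSIONS: "admissions.csv",
    TableKind.DIAGNOSES: "diagnoses.csv",
    TableKind.GOLD_LABELS: "gold_labels.csv",
}

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


def _parse_str(raw: str) -> str:
    if not raw.strip():
        raise ValueError("must be non-empty")
    return raw.strip()


def _parse_optional_str(raw: str) -> Optional[str]:
    return raw.strip() or None


def _parse_datetime(raw: str) -> datetime:
    try:
        return datetime.fromisoformat(raw.strip())
    except ValueError as exc:
        raise ValueError(f"unparseable ISO-8601 timestamp {raw!r}") from exc


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"{raw!r} is not a boolean (true/false)")


def _enum_parser(enum_cls, synonyms: Optional[Mapping[str, str]] = None) -> Callable:
    """Case-insensitive enum parser; optional synonym map (raw -> member name)."""
    canon = {m.value.lower(): m for m in enum_cls}
    extra = {k.lower(): v for k, v in (synonyms or {}).items()}

    def parse(raw: str):
        low = raw.strip().lower()
        low = extra.get(low, low)
        if low in canon:
            return canon[low]
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValueError(f"{raw!r} not in enumeration {{{allowed}}}")

    return parse


def _serialize(value) -> str:
    if value is None:
        return ""
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, datetime):
        return value.isoformat()
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


@dataclass(frozen=True)
class _Field:
    name: str
    parse: Callable
    enum_cls: type | None = None  # set for enum fields so synonyms can rebind


@dataclass(frozen=True)
class _Schema:
    record_type: type
    fields: tuple
    key: Optional[str]  # column whose values must be unique, if any


_SCHEMAS = {
    TableKind.ORDERS: _Schema(
        ImagingOrder,
        (
            _Field("order_id", _parse_str),
            _Field("patient_id", _parse_str),
            _Field("ed_encounter_id", _parse_str),
            _Field("order_type", _enum_parser(OrderType), OrderType),
            _Field("status", _enum_parser(OrderStatus), OrderStatus),
            _Field("order_datetime", _parse_datetime),
            _Field("site_id", _parse_str),
        ),
        key="order_id",
    ),
    TableKind.ED_ENCOUNTERS: _Schema(
        EDEncounter,
        (
            _Field("ed_encounter_id", _parse_str),
            _Field("patient_id", _parse_str),
            _Field("arrival_datetime", _parse_datetime),
            _Field("disposition", _enum_parser(Disposition), Disposition),
        ),
        key="ed_encounter_id",
    ),
    TableKind.ADMISSIONS: _Schema(
        InpatientAdmission,
        (
            _Field("admission_id", _parse_str),
            _Field("patient_id", _parse_str),
            _Field("source_ed_encounter_id", _parse_optional_str),
            _Field("admit_datetime", _parse_datetime),
            _Field("discharge_datetime", _parse_datetime),
        ),
        key="admission_id",
    ),
    TableKind.DIAGNOSES: _Schema(
        DischargeDiagnosis,
        (
            _Field("admission_id", _parse_str),
            _Field("icd_code", _parse_str),
            _Field("icd_version", _enum_parser(ICDVersion), ICDVersion),
            _Field("rank", _enum_parser(DiagnosisRank), DiagnosisRank),
        ),
        key=None,
    ),
    TableKind.GOLD_LABELS: _Schema(
        GoldStandardLabel,
        (
            _Field("order_id", _parse_str),
            _Field("chart_review_pe_positive", _parse_bool),
        ),
        key="order_id",
    ),
}

_RECORD_TO_KIND = {s.record_type: k for k, s in _SCHEMAS.items()}


def read_table(
    path: Union[str, Path],
    table_kind: TableKind,
    synonyms: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> list:
    """Read one table from CSV, validating every row.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    table_kind : TableKind
        Which of the five tables the file holds.
    synonyms : mapping, optional
        Per-column synonym maps for enumerated fields, e.g.
        ``{"status": {"comp": "completed"}}`` — applied case-insensitively
        before enumeration lookup, to absorb EHR-export vocabulary drift.

    Returns
    -------
    list of typed records, in file row order.

    Raises
    ------
    SchemaError
        A required column is missing (named in the message).
    RowValidationError
        A cell fails parsing/validation (row number and field in the message).
    IntegrityError
        A duplicate primary key.
    """
    schema = _SCHEMAS[table_kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for f in schema.fields:
        if f.name not in df.columns:
            raise SchemaError(
                f"{table_kind.value}: missing required column '{f.name}'"
            )

    parsers = {}
    for f in schema.fields:
        if f.enum_cls is not None and synonyms and f.name in synonyms:
            parsers[f.name] = _enum_parser(f.enum_cls, synonyms[f.name])
        else:
            parsers[f.name] = f.parse

    records = []
    seen_keys = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        kwargs = {}
        for f in schema.fields:
            try:
                kwargs[f.name] = parsers[f.name](row[f.name])
            except ValueError as exc:
                raise RowValidationError(i, f.name, str(exc)) from exc
        try:
            rec = schema.record_type(**kwargs)
        except ValueError as exc:
            raise RowValidationError(i, "<record>", str(exc)) from exc
        if schema.key is not None:
            key = kwargs[schema.key]
            if key in seen_keys:
                raise IntegrityError(
                    f"{table_kind.value}: duplicate {schema.key} {key!r} at row {i}"
                )
            seen_keys.add(key)
        records.append(rec)
    return records


def write_table(records: Sequence, path: Union[str, Path]) -> None:
    """Write records of a single type to CSV so that read_table round-trips.

    An empty collection needs an explicit kind and is not writable here;
    use :func:`write_empty_table`.
    """
    if not records:
        raise ValueError(
            "cannot infer table kind from empty collection; use write_empty_table"
        )
    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValueError(f"records of mixed types: {sorted(k.__name__ for k in kinds)}")
    kind = _RECORD_TO_KIND[kinds.pop()]
    schema = _SCHEMAS[kind]
    cols = [f.name for f in schema.fields]
    rows = [{c: _serialize(getattr(r, c)) for c in cols} for r in records]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_empty_table(table_kind: TableKind, path: Union[str, Path]) -> None:
    """Write a header-only CSV for the given table kind."""
    cols = [f.name for f in _SCHEMAS[table_kind].fields]
    pd.DataFrame(columns=cols).to_csv(path, index=False)
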