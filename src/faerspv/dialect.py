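"""FAERS quarterly ASCII dialect: '$'-delimited text tables with one header row.

The six quarterly tables (DEMO, DRUG, REAC, THER, INDI, OUTC) share the same
dialect: a single header line naming the columns, then one record per line
with fields separated by a literal ``$``.  The dialect has no quoting or
escape mechanism, so a field value may never itself contain a ``$`` — the
writer rejects such values rather than emitting a file that cannot be
round-tripped.

Dates in FAERS are integers of one of three precisions: ``YYYYMMDD`` (full),
``YYYYMM`` or ``YYYY`` (partial).  All date columns are kept as raw strings
at this layer; parsing policy lives with the consumers.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd

DELIMITER = "$"

#: Required columns per table kind; extra columns in a file are ignored.
TABLE_COLUMNS: Mapping[str, list[str]] = {
    "demo": [
        "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age",
        "age_cod", "wt", "wt_cod", "occp_cod", "reporter_country",
    ],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "caseid", "pt"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "indi": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
}

#: Columns that are always full integers (identifiers and the full-precision
#: FDA receipt date).  Everything else stays a string, '' meaning missing.
INT_COLUMNS = frozenset({"primaryid", "caseid", "fda_dt", "drug_seq", "dsg_drug_seq", "indi_drug_seq"})


class DialectError(ValueError):
    """A value cannot be represented in the '$'-delimited dialect."""


class SchemaError(ValueError):
    """A file does not match the declared table kind's schema."""


def _check_kind(kind: str) -> str:
    kind = kind.lower()
    if kind not in TABLE_COLUMNS:
        raise SchemaError(f"unknown table kind {kind!r}; expected one of {sorted(TABLE_COLUMNS)}")
    return kind


def empty_table(kind: str) -> pd.DataFrame:
    """An empty, correctly typed frame for *kind*."""
    kind = _check_kind(kind)
    cols = TABLE_COLUMNS[kind]
    frame = pd.DataFrame({c: pd.Series(dtype="int64" if c in INT_COLUMNS else "object") for c in cols})
    return frame


def write_table(frame: pd.DataFrame, path: str | os.PathLike, kind: str) -> str:
    """Write *frame* as a '$'-delimited table; returns the path written.

    Raises :class:`DialectError` if any field contains a literal '$' and
    :class:`SchemaError` if a required column is absent.
    """
    kind = _check_kind(kind)
    cols = TABLE_COLUMNS[kind]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"{kind.upper()} frame lacks required column(s) {missing}")
    out = frame[cols]
    for col in cols:
        series = out[col]
        if series.dtype == object and series.map(lambda v: isinstance(v, str) and DELIMITER in v).any():
            raise DialectError(
                f"column {col!r} contains a literal {DELIMITER!r}; "
                "the FAERS ASCII dialect has no escape mechanism"
            )
    out.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")
    return os.fspath(path)


def read_table(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    """Read a '$'-delimited table, returning only the schema columns.

    Identifier columns are coerced to int64; all other columns stay raw
    strings with '' for missing values.  A header-only or zero-byte file
    yields an empty frame.  Row order is preserved.
    """
    kind = _check_kind(kind)
    cols = TABLE_COLUMNS[kind]
    try:
        frame = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False, engine="python")
    except pd.errors.EmptyDataError:
        return empty_table(kind)
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise SchemaError(f"{os.fspath(path)}: missing required column(s) {missing} for {kind.upper()}")
    frame = frame[cols]
    for col in cols:
        if col in INT_COLUMNS:
            try:
                frame[col] = frame[col].astype("int64")
            except ValueError as exc:
                raise SchemaError(f"{os.fspath(path)}: column {col!r} is not integral: {exc}") from exc
    return frame
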