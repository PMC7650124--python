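"""CSV/JSON/YAML readers and writers plus run logging.

CSV dialect: comma-separated, UTF-8, mandatory header, empty string =
missing.  Booleans serialise as ``1``/``0``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .records import (
    BOOL_ADVANTAGED,
    CATEGORICAL_LEVELS,
    CSV_COLUMNS,
    PROFESSION_FALLBACK_LEVELS,
    RISK_FACTORS,
    SEC_ITEMS,
    SubjectRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyValidationError",
    "read_study_csv",
    "read_study_frame",
    "write_study_csv",
    "records_to_frame",
    "frame_to_records",
    "load_config_file",
    "write_json",
    "setup_run_logging",
]

#: occupation-like columns where out-of-frame values collapse to the
#: blue-collar/unskilled pole
_PROFESSION_COLUMNS = {
    "father_occupation": "blue_or_unskilled",
    "mother_occupation": "blue_or_unskilled",
    "professional_education": "unskilled_incl_housewife",
    "last_profession": "unskilled_incl_housewife",
}

_BOOL_ITEMS = tuple(BOOL_ADVANTAGED)


class StudyValidationError(ValidationError):
    """Aggregated row-level validation failures."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        lines = [f"row {row}: {msg}" for row, msg in errors[:20]]
        if len(errors) > 20:
            lines.append(f"... and {len(errors) - 20} more")
        super().__init__(f"{len(errors)} invalid rows:\n" + "\n".join(lines))


def _parse_bool(raw: str, column: str) -> bool:
    if raw in ("1", "true", "True"):
        return True
    if raw in ("0", "false", "False"):
        return False
    raise ValidationError(f"{column}: expected 0/1, got {raw!r}")


def _parse_cell(column: str, raw: str):
    """One CSV cell -> typed value; empty string means missing."""
    if raw == "":
        return None
    if column == "id":
        return raw
    if column in ("status", "sex"):
        return raw
    if column == "age_years":
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(f"age_years: not a number: {raw!r}") from None
    if column == "n_siblings":
        try:
            return int(raw)
        except ValueError:
            raise ValidationError(f"n_siblings: not an integer: {raw!r}") from None
    if column in _BOOL_ITEMS:
        return _parse_bool(raw, column)
    if column in RISK_FACTORS:
        return int(_parse_bool(raw, column))
    if column in _PROFESSION_COLUMNS and raw in PROFESSION_FALLBACK_LEVELS:
        logger.warning(
            "%s: level %r outside the coding frame; mapped to %r",
            column, raw, _PROFESSION_COLUMNS[column],
        )
        return _PROFESSION_COLUMNS[column]
    return raw


def read_study_csv(path) -> list[SubjectRecord]:
    """Read and validate a study CSV into typed records.

    Row-level problems are collected and reported together with their
    row numbers (header = row 1); a missing mandatory column is a hard
    error.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValidationError(f"missing mandatory columns: {missing_cols}")
    unknown = [c for c in raw.columns if c not in CSV_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")

    records: list[SubjectRecord] = []
    errors: list[tuple[int, str]] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):
        values = dict(zip(raw.columns, row))
        try:
            parsed = {c: _parse_cell(c, values[c]) for c in CSV_COLUMNS}
            rf = {name: parsed.pop(name) for name in RISK_FACTORS}
            records.append(SubjectRecord(risk_factors=rf, **parsed))
        except ValidationError as exc:
            errors.append((i, str(exc)))
    if errors:
        raise StudyValidationError(errors)
    return records


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    data = {}
    for col in CSV_COLUMNS:
        if col in RISK_FACTORS:
            data[col] = [r.risk_factors.get(col) for r in records]
        else:
            data[col] = [getattr(r, col) for r in records]
    df = pd.DataFrame(data).astype(object)
    df["age_years"] = df["age_years"].astype(float)
    return df


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    def _clean(col, v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        if col in _BOOL_ITEMS:
            return bool(v)
        if col == "n_siblings":
            return int(v)
        if col in RISK_FACTORS:
            return int(v)
        if col == "age_years":
            return float(v)
        return v

    records = []
    for row in df[list(CSV_COLUMNS)].itertuples(index=False):
        values = {c: _clean(c, v) for c, v in zip(CSV_COLUMNS, row)}
        rf = {name: values.pop(name) for name in RISK_FACTORS}
        records.append(SubjectRecord(risk_factors=rf, **values))
    return records


def read_study_frame(path) -> pd.DataFrame:
    """Validated study frame (via the record layer)."""
    return records_to_frame(read_study_csv(path))


def _format_cell(col: str, value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return ""
    if col in _BOOL_ITEMS:
        return "1" if value else "0"
    if col in RISK_FACTORS or col == "n_siblings":
        return str(int(value))
    if col == "age_years":
        return format(float(value), "g")
    return str(value)


def write_study_csv(data, path) -> None:
    """Write records or a study frame in the canonical CSV dialect."""
    if isinstance(data, list):
        data = records_to_frame(data)
    out = pd.DataFrame(
        {c: [_format_cell(c, v) for v in data[c]] for c in CSV_COLUMNS}
    )
    out.to_csv(path, index=False, lineterminator="\n")


def load_config_file(path, cls):
    """Load a flat YAML config into dataclass ``cls``; unknown keys rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(data) - cls.field_names()
    if unknown:
        raise ValidationError(f"{path}: unknown config keys: {sorted(unknown)}")
    return cls(**data)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def setup_run_logging(log_path) -> logging.Handler:
    """Attach a plain-text file handler for one run; caller removes it."""
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lcm")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler
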