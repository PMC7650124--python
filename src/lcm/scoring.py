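"""Life-stage socioeconomic risk scores.

Three additive point scores measure disadvantage in childhood (0-12),
adolescence (0-8) and adulthood (0-8); higher totals mean more
disadvantaged conditions.  Point values follow the questionnaire coding
frame: each categorical item awards points ascending from its most
advantaged level, booleans award points for the disadvantaged value, and
sibling count is binarised at more-than-three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .records import (
    BOOL_ADVANTAGED,
    CATEGORICAL_LEVELS,
    RISK_FACTORS,
    SEC_ITEMS,
    SubjectRecord,
    ValidationError,
    validate_item,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ChildhoodItems",
    "AdolescenceItems",
    "AdulthoodItems",
    "score_childhood",
    "score_adolescence",
    "score_adulthood",
    "score_record",
    "score_frame",
    "item_points",
    "impute_items",
    "impute_frame",
    "CHILDHOOD_MAX",
    "ADOLESCENCE_MAX",
    "ADULTHOOD_MAX",
]

CHILDHOOD_MAX = 12
ADOLESCENCE_MAX = 8
ADULTHOOD_MAX = 8

SIBLINGS_CUTOFF = 3  # more than this many siblings scores 1 point

#: categorical item -> {level: points}
CATEGORICAL_POINTS: dict[str, dict[str, int]] = {
    "father_occupation": {"academic": 0, "white_collar": 1, "blue_or_unskilled": 2},
    "mother_occupation": {"white_collar_or_academic_or_housewife": 0, "blue_or_unskilled": 1},
    "family_structure": {"both_parents": 0, "one_parent": 1, "no_parents": 2},
    "rooms_per_person": {"gt1": 0, "half_to_1": 1, "lt_half": 2},
    "school_degree": {"high_school": 0, "middle_school": 2, "primary_school": 4},
    "professional_education": {
        "academic_exam": 0,
        "white_collar_degree": 1,
        "skilled_worker": 2,
        "unskilled_incl_housewife": 4,
    },
    "last_profession": {
        "academic": 0,
        "white_collar": 1,
        "skilled_blue_collar": 2,
        "unskilled_incl_housewife": 4,
    },
}

#: boolean item -> points awarded when the value is disadvantaged
BOOL_POINTS: dict[str, int] = {
    "toilet_in_house": 1,
    "parental_car": 1,
    "income_upper_half": 1,
    "paternal_unemployment": 1,
    "unemployment_gt6mo": 2,
    "partnered": 2,
}


def item_points(name: str, value) -> int:
    """Points contributed by one item value (the per-item lookup)."""
    if value is None:
        raise ValidationError(f"{name}: missing value at scoring time")
    validate_item(name, value)
    if name == "n_siblings":
        return 1 if value > SIBLINGS_CUTOFF else 0
    if name in CATEGORICAL_POINTS:
        return CATEGORICAL_POINTS[name][value]
    if name in BOOL_POINTS:
        return BOOL_POINTS[name] if bool(value) != BOOL_ADVANTAGED[name] else 0
    raise ValidationError(f"{name}: not a scored item")


@dataclass(frozen=True)
class ChildhoodItems:
    father_occupation: str
    mother_occupation: str
    family_structure: str
    n_siblings: int
    rooms_per_person: str
    toilet_in_house: bool
    parental_car: bool
    income_upper_half: bool
    paternal_unemployment: bool

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            validate_item(name, getattr(self, name))


@dataclass(frozen=True)
class AdolescenceItems:
    school_degree: str
    professional_education: str

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            validate_item(name, getattr(self, name))


@dataclass(frozen=True)
class AdulthoodItems:
    last_profession: str
    unemployment_gt6mo: bool
    partnered: bool

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            validate_item(name, getattr(self, name))


def _score(items, names: Iterable[str]) -> int:
    return sum(item_points(name, getattr(items, name)) for name in names)


def score_childhood(items: ChildhoodItems) -> int:
    """Childhood disadvantage score in [0, 12]."""
    return _score(items, ChildhoodItems.__dataclass_fields__)


def score_adolescence(items: AdolescenceItems) -> int:
    """Adolescence disadvantage score in [0, 8]."""
    return _score(items, AdolescenceItems.__dataclass_fields__)


def score_adulthood(items: AdulthoodItems) -> int:
    """Adulthood disadvantage score in [0, 8]."""
    return _score(items, AdulthoodItems.__dataclass_fields__)


def score_record(record: SubjectRecord) -> tuple[int, int, int]:
    """All three life-stage scores for one fully observed record."""
    child = _score(record, ChildhoodItems.__dataclass_fields__)
    adol = _score(record, AdolescenceItems.__dataclass_fields__)
    adult = _score(record, AdulthoodItems.__dataclass_fields__)
    return child, adol, adult


def score_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a fully imputed study frame.

    Returns a copy of ``df`` with ``score_childhood``, ``score_adolescence``
    and ``score_adulthood`` columns appended.
    """
    for name in SEC_ITEMS:
        if df[name].isna().any():
            raise ValidationError(f"{name}: missing values present; impute first")
    pts = {}
    for name, table in CATEGORICAL_POINTS.items():
        col = df[name].map(table)
        if col.isna().any():
            bad = df.loc[col.isna(), name].iloc[0]
            raise ValidationError(f"{name}: unknown level {bad!r}")
        pts[name] = col.astype(int)
    for name, p in BOOL_POINTS.items():
        pts[name] = (df[name].astype(bool) != BOOL_ADVANTAGED[name]).astype(int) * p
    pts["n_siblings"] = (df["n_siblings"].astype(int) > SIBLINGS_CUTOFF).astype(int)

    out = df.copy()
    out["score_childhood"] = sum(pts[n] for n in ChildhoodItems.__dataclass_fields__)
    out["score_adolescence"] = sum(pts[n] for n in AdolescenceItems.__dataclass_fields__)
    out["score_adulthood"] = sum(pts[n] for n in AdulthoodItems.__dataclass_fields__)
    return out


# ---------------------------------------------------------------------------
# imputation

IMPUTABLE = SEC_ITEMS + RISK_FACTORS


def _lower_risk_rank(name: str, value) -> tuple:
    """Sort key that ranks candidate values from least to most disadvantaged."""
    if name in CATEGORICAL_LEVELS:
        return (CATEGORICAL_LEVELS[name].index(value),)
    if name in BOOL_ADVANTAGED:
        return (0 if bool(value) == BOOL_ADVANTAGED[name] else 1,)
    # n_siblings and 0/1 risk factors: smaller is lower risk
    return (value,)


def _cell_mode(series: pd.Series, name: str):
    """Most frequent non-missing value; ties break to the lower-risk level."""
    counts = series.dropna().value_counts()
    if counts.empty:
        return None
    top = counts[counts == counts.max()].index.tolist()
    return min(top, key=lambda v: _lower_risk_rank(name, v))


def impute_frame(
    df: pd.DataFrame, strategy: str = "mode_cell", seed: int = 0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Fill missing SEC items and risk factors on a study frame.

    ``mode_cell`` imputes the within sex x case/control cell mode
    (deterministic; ties break to the lower-risk level; an all-missing cell
    falls back to the column-wide mode).  ``complete_case`` drops rows with
    any missing imputable field.  Returns the completed frame and a count of
    imputed cells per field.
    """
    for col in ("status", "age_years", "sex"):
        if df[col].isna().any():
            raise ValidationError(f"{col}: missing values are not allowed")
    counts: dict[str, int] = {}
    if strategy == "complete_case":
        mask = df[list(IMPUTABLE)].notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("complete_case: dropped %d rows with missing fields", dropped)
        return df.loc[mask].reset_index(drop=True), counts
    if strategy != "mode_cell":
        raise ValueError(f"unknown imputation strategy {strategy!r}")

    out = df.copy()
    cell = out["sex"].astype(str) + "|" + out["status"].astype(str)
    for name in IMPUTABLE:
        missing = out[name].isna()
        if not missing.any():
            continue
        counts[name] = int(missing.sum())
        fallback = _cell_mode(out[name], name)
        if fallback is None:
            raise ValidationError(f"{name}: no observed values to impute from")
        fill = pd.Series(index=out.index, dtype=object)
        for _, idx in out.groupby(cell).groups.items():
            mode = _cell_mode(out.loc[idx, name], name)
            fill.loc[idx] = mode if mode is not None else fallback
        out.loc[missing, name] = fill[missing]
        logger.info("imputed %d cells in %s (mode_cell)", counts[name], name)
    return out, counts


def impute_items(
    records: list[SubjectRecord], strategy: str = "mode_cell", seed: int = 0
) -> tuple[list[SubjectRecord], dict[str, int]]:
    """Record-level wrapper around :func:`impute_frame`."""
    from .io import frame_to_records, records_to_frame

    df = records_to_frame(records)
    out, counts = impute_frame(df, strategy=strategy, seed=seed)
    return frame_to_records(out), counts
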