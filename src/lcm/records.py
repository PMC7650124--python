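"""Subject-level data model: field names, permitted levels, and the
:class:`SubjectRecord` container shared by every stage of the analysis.

Conventions
-----------
* Categorical item levels are listed from most advantaged to most
  disadvantaged; point values elsewhere are ascending in that order.
* Boolean items carry their *advantaged* value in :data:`BOOL_ADVANTAGED`.
* ``None`` marks a missing value (CSV empty string).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

__all__ = [
    "SubjectRecord",
    "ValidationError",
    "CATEGORICAL_LEVELS",
    "BOOL_ADVANTAGED",
    "CHILDHOOD_ITEMS",
    "ADOLESCENCE_ITEMS",
    "ADULTHOOD_ITEMS",
    "SEC_ITEMS",
    "RISK_FACTORS",
    "MANDATORY_COLUMNS",
    "CSV_COLUMNS",
    "AGE_MIN",
    "AGE_MAX",
]

AGE_MIN = 18
AGE_MAX = 80

#: levels ordered best -> worst (ascending risk points)
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "father_occupation": ("academic", "white_collar", "blue_or_unskilled"),
    "mother_occupation": ("white_collar_or_academic_or_housewife", "blue_or_unskilled"),
    "family_structure": ("both_parents", "one_parent", "no_parents"),
    "rooms_per_person": ("gt1", "half_to_1", "lt_half"),
    "school_degree": ("high_school", "middle_school", "primary_school"),
    "professional_education": (
        "academic_exam",
        "white_collar_degree",
        "skilled_worker",
        "unskilled_incl_housewife",
    ),
    "last_profession": (
        "academic",
        "white_collar",
        "skilled_blue_collar",
        "unskilled_incl_housewife",
    ),
}

#: boolean item -> the advantaged (0-point) value
BOOL_ADVANTAGED: dict[str, bool] = {
    "toilet_in_house": True,
    "parental_car": True,
    "income_upper_half": True,
    "paternal_unemployment": False,
    "unemployment_gt6mo": False,
    "partnered": True,
}

CHILDHOOD_ITEMS = (
    "father_occupation",
    "mother_occupation",
    "family_structure",
    "n_siblings",
    "rooms_per_person",
    "toilet_in_house",
    "parental_car",
    "income_upper_half",
    "paternal_unemployment",
)
ADOLESCENCE_ITEMS = ("school_degree", "professional_education")
ADULTHOOD_ITEMS = ("last_profession", "unemployment_gt6mo", "partnered")
SEC_ITEMS = CHILDHOOD_ITEMS + ADOLESCENCE_ITEMS + ADULTHOOD_ITEMS

RISK_FACTORS = (
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
    "atrial_fibrillation",
    "coronary_heart_disease",
    "peripheral_arterial_disease",
    "cardiac_failure",
    "low_teeth",
    "smoking",
    "high_alcohol",
    "low_dentist_visits",
    "low_physical_activity",
    "low_fruit",
    "low_vegetable",
)

MANDATORY_COLUMNS = ("id", "status", "age_years", "sex")
CSV_COLUMNS = MANDATORY_COLUMNS + SEC_ITEMS + RISK_FACTORS

#: professions reported outside the coding frame collapse onto the
#: blue-collar/unskilled pole (with a logged warning at read time)
PROFESSION_FALLBACK_LEVELS = ("other", "unknown")


class ValidationError(ValueError):
    """Raised when a field value violates the schema; names the field."""


def validate_item(name: str, value) -> None:
    """Validate a single (non-missing) SEC item or risk-factor value."""
    if name in CATEGORICAL_LEVELS:
        if value not in CATEGORICAL_LEVELS[name]:
            raise ValidationError(
                f"{name}: unknown level {value!r}; expected one of "
                f"{CATEGORICAL_LEVELS[name]}"
            )
    elif name in BOOL_ADVANTAGED:
        if not isinstance(value, bool):
            raise ValidationError(f"{name}: expected boolean, got {value!r}")
    elif name == "n_siblings":
        if not (isinstance(value, int) and not isinstance(value, bool)) or value < 0:
            raise ValidationError(f"n_siblings: expected non-negative integer, got {value!r}")
    elif name in RISK_FACTORS:
        if value not in (0, 1):
            raise ValidationError(f"{name}: expected 0/1 indicator, got {value!r}")
    else:
        raise ValidationError(f"unknown field {name!r}")


@dataclass
class SubjectRecord:
    """One study participant.

    ``status``/``age_years``/``sex`` are mandatory; SEC items and risk
    factors may be ``None`` (missing) until imputation.
    """

    id: str
    status: str  # 'case' | 'control'
    age_years: float
    sex: str  # 'm' | 'f'

    father_occupation: Optional[str] = None
    mother_occupation: Optional[str] = None
    family_structure: Optional[str] = None
    n_siblings: Optional[int] = None
    rooms_per_person: Optional[str] = None
    toilet_in_house: Optional[bool] = None
    parental_car: Optional[bool] = None
    income_upper_half: Optional[bool] = None
    paternal_unemployment: Optional[bool] = None

    school_degree: Optional[str] = None
    professional_education: Optional[str] = None

    last_profession: Optional[str] = None
    unemployment_gt6mo: Optional[bool] = None
    partnered: Optional[bool] = None

    risk_factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"status: expected 'case' or 'control', got {self.status!r}")
        if self.sex not in ("m", "f"):
            raise ValidationError(f"sex: expected 'm' or 'f', got {self.sex!r}")
        if self.age_years is None:
            raise ValidationError("age_years: missing")
        if not (AGE_MIN <= float(self.age_years) <= AGE_MAX):
            raise ValidationError(
                f"age_years: {self.age_years!r} outside [{AGE_MIN}, {AGE_MAX}]"
            )
        for name in SEC_ITEMS:
            value = getattr(self, name)
            if value is not None:
                validate_item(name, value)
        for name, value in self.risk_factors.items():
            if name not in RISK_FACTORS:
                raise ValidationError(f"unknown risk factor {name!r}")
            if value is not None:
                validate_item(name, value)

    @property
    def is_case(self) -> bool:
        return self.status == "case"

    def missing_fields(self) -> list[str]:
        out = [name for name in SEC_ITEMS if getattr(self, name) is None]
        out += [name for name in RISK_FACTORS if self.risk_factors.get(name) is None]
        return out


def record_field_names() -> tuple[str, ...]:
    return tuple(f.name for f in fields(SubjectRecord) if f.name != "risk_factors")
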