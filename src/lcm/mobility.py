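"""Social mobility classification.

Two classifiers share the same trichotomy {advancement, no_change,
descent}:

* occupational mobility compares ordered three-level profession
  categories (academic > white-collar > blue-collar/other, housewives in
  the last group) between father and subject, or between the subject's
  professional training and last profession;
* score mobility compares low/middle/high risk strata, cut at the
  tertiles of the *control* score distribution, between two life stages.
  Strata are risk-ordered, so reaching a higher-risk stratum is descent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ValidationError

__all__ = [
    "ADVANCEMENT",
    "NO_CHANGE",
    "DESCENT",
    "MOBILITY_CATEGORIES",
    "STRATA",
    "PROFESSION_LEVEL",
    "TertileCutpoints",
    "profession_category",
    "classify_profession_mobility",
    "control_tertile_cutpoints",
    "score_stratum",
    "classify_score_mobility",
    "annotate_mobility",
    "MOBILITY_COLUMNS",
]

ADVANCEMENT = "advancement"
NO_CHANGE = "no_change"
DESCENT = "descent"
MOBILITY_CATEGORIES = (ADVANCEMENT, NO_CHANGE, DESCENT)

STRATA = ("low", "middle", "high")
_STRATUM_RANK = {s: i for i, s in enumerate(STRATA)}

PROFESSION_LEVEL = {"blue_collar_other": 0, "white_collar": 1, "academic": 2}

#: raw item level -> three-level profession category
_FATHER_TO_CATEGORY = {
    "academic": "academic",
    "white_collar": "white_collar",
    "blue_or_unskilled": "blue_collar_other",
}
_TRAINING_TO_CATEGORY = {
    "academic_exam": "academic",
    "white_collar_degree": "white_collar",
    "skilled_worker": "blue_collar_other",
    "unskilled_incl_housewife": "blue_collar_other",
}
_LAST_TO_CATEGORY = {
    "academic": "academic",
    "white_collar": "white_collar",
    "skilled_blue_collar": "blue_collar_other",
    "unskilled_incl_housewife": "blue_collar_other",
}

#: six mobility comparisons appended to the analysis frame
MOBILITY_COLUMNS = (
    "mobility_father_training",
    "mobility_father_last",
    "mobility_training_last",
    "mobility_child_adol",
    "mobility_child_adult",
    "mobility_adol_adult",
)


def profession_category(source: str, value: str) -> str:
    """Map a raw occupation item level to the three-level category.

    ``source`` is one of ``father``, ``training``, ``last``.
    """
    table = {
        "father": _FATHER_TO_CATEGORY,
        "training": _TRAINING_TO_CATEGORY,
        "last": _LAST_TO_CATEGORY,
    }[source]
    try:
        return table[value]
    except KeyError:
        raise ValidationError(f"{source} occupation: unknown level {value!r}") from None


def classify_profession_mobility(father: str, subject: str) -> str:
    """Intergenerational mobility between two profession categories."""
    try:
        f, s = PROFESSION_LEVEL[father], PROFESSION_LEVEL[subject]
    except KeyError as exc:
        raise ValidationError(f"unknown profession category {exc.args[0]!r}") from None
    if s > f:
        return ADVANCEMENT
    if s < f:
        return DESCENT
    return NO_CHANGE


@dataclass(frozen=True)
class TertileCutpoints:
    """Integer cutpoints ``q1 <= q2``; stratum(x) is low for x <= q1,
    middle for q1 < x <= q2, high for x > q2."""

    q1: int
    q2: int

    def __post_init__(self):
        if self.q1 > self.q2:
            raise ValidationError(f"cutpoints out of order: {self.q1} > {self.q2}")


def control_tertile_cutpoints(control_scores) -> TertileCutpoints:
    """Tertile cutpoints of a discrete score from control values only.

    q1 is the smallest observed value whose empirical CDF reaches 1/3, q2
    the smallest reaching 2/3 — deterministic under heavy integer ties.
    """
    values = np.asarray(list(control_scores))
    if values.size == 0:
        raise ValidationError("control_scores: empty")
    values = np.sort(values)
    n = values.size
    cdf = np.arange(1, n + 1) / n
    q1 = values[np.searchsorted(cdf, 1 / 3 - 1e-12)]
    q2 = values[np.searchsorted(cdf, 2 / 3 - 1e-12)]
    return TertileCutpoints(int(q1), int(q2))


def score_stratum(score: int, cuts: TertileCutpoints) -> str:
    if score <= cuts.q1:
        return "low"
    if score <= cuts.q2:
        return "middle"
    return "high"


def classify_score_mobility(stratum_early: str, stratum_late: str) -> str:
    """Mobility between risk strata of two life stages.

    Strata are ordered by risk (low < middle < high); moving to any
    higher-risk stratum is descent, to any lower-risk stratum advancement.
    """
    try:
        e, l = _STRATUM_RANK[stratum_early], _STRATUM_RANK[stratum_late]
    except KeyError as exc:
        raise ValidationError(f"unknown stratum {exc.args[0]!r}") from None
    if l > e:
        return DESCENT
    if l < e:
        return ADVANCEMENT
    return NO_CHANGE


def annotate_mobility(
    df: pd.DataFrame, cutpoints: dict[str, TertileCutpoints] | None = None
) -> tuple[pd.DataFrame, dict[str, TertileCutpoints]]:
    """Append strata and the six mobility columns to a scored frame.

    ``df`` must carry ``score_childhood``/``score_adolescence``/
    ``score_adulthood`` and the raw occupation items.  ``cutpoints`` maps
    life stage to precomputed cutpoints; when omitted they are derived
    from the frame's own controls.
    """
    out = df.copy()
    if cutpoints is None:
        controls = out[out["status"] == "control"]
        if controls.empty:
            raise ValidationError("no controls available to derive tertile cutpoints")
        cutpoints = {
            stage: control_tertile_cutpoints(controls[f"score_{stage}"])
            for stage in ("childhood", "adolescence", "adulthood")
        }

    for stage in ("childhood", "adolescence", "adulthood"):
        cuts = cutpoints[stage]
        score = out[f"score_{stage}"].astype(int)
        out[f"{stage}_stratum"] = np.select(
            [score <= cuts.q1, score <= cuts.q2], ["low", "middle"], default="high"
        )

    father = out["father_occupation"].map(_FATHER_TO_CATEGORY)
    training = out["professional_education"].map(_TRAINING_TO_CATEGORY)
    last = out["last_profession"].map(_LAST_TO_CATEGORY)
    for col in (father, training, last):
        if col.isna().any():
            raise ValidationError("unmapped occupation level in frame")

    def _occ(a: pd.Series, b: pd.Series) -> pd.Series:
        lo = a.map(PROFESSION_LEVEL).to_numpy()
        hi = b.map(PROFESSION_LEVEL).to_numpy()
        return pd.Series(
            np.select([hi > lo, hi < lo], [ADVANCEMENT, DESCENT], default=NO_CHANGE),
            index=a.index,
        )

    def _strat(a: pd.Series, b: pd.Series) -> pd.Series:
        lo = a.map(_STRATUM_RANK).to_numpy()
        hi = b.map(_STRATUM_RANK).to_numpy()
        return pd.Series(
            np.select([hi > lo, hi < lo], [DESCENT, ADVANCEMENT], default=NO_CHANGE),
            index=a.index,
        )

    out["mobility_father_training"] = _occ(father, training)
    out["mobility_father_last"] = _occ(father, last)
    out["mobility_training_last"] = _occ(training, last)
    out["mobility_child_adol"] = _strat(out["childhood_stratum"], out["adolescence_stratum"])
    out["mobility_child_adult"] = _strat(out["childhood_stratum"], out["adulthood_stratum"])
    out["mobility_adol_adult"] = _strat(out["adolescence_stratum"], out["adulthood_stratum"])
    return out, cutpoints
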