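"""End-to-end analysis: scores -> tertile strata -> mobility -> three
nested conditional-logistic models per exposure -> mobility tables and
sex-stratified fits.

Model variants
--------------
* model1: mobility exposure only, conditioning on 2-year age band x sex.
* model2: model1 + the 14 binary medical/lifestyle risk factors.
* model3: model2 + the three life-stage score terms (tertile-stratum
  indicators by default, raw scores via ``model3_scores='continuous'``).

The mobility reference category is ``no_change`` and the stratum
reference is ``low``; tables report counts, percentages (half-up, one
decimal) and OR (95% CI) per variant, rounded only at presentation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clogit, mobility, scoring
from .mobility import ADVANCEMENT, DESCENT, MOBILITY_CATEGORIES, NO_CHANGE
from .records import RISK_FACTORS, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ModelSpec",
    "AnalysisResult",
    "OCCUPATION_EXPOSURES",
    "SCORE_EXPOSURES",
    "EXPOSURES",
    "VARIANTS",
    "make_percentages",
    "crude_or_from_counts",
    "prepare_frame",
    "run_analysis",
    "sex_stratified_fits",
]

OCCUPATION_EXPOSURES = ("father_training", "father_last", "training_last")
SCORE_EXPOSURES = ("child_adol", "child_adult", "adol_adult")
EXPOSURES = OCCUPATION_EXPOSURES + SCORE_EXPOSURES
VARIANTS = ("model1", "model2", "model3")

STAGES = ("childhood", "adolescence", "adulthood")


@dataclass
class AnalysisConfig:
    seed: int = 0
    imputation: str = "mode_cell"  # or 'complete_case'
    model3_scores: str = "strata"  # or 'continuous'
    ci_level: float = 0.95
    exposures: tuple = EXPOSURES
    variants: tuple = VARIANTS

    def __post_init__(self):
        if self.model3_scores not in ("strata", "continuous"):
            raise ValueError(f"model3_scores: unknown coding {self.model3_scores!r}")
        self.exposures = tuple(self.exposures)
        self.variants = tuple(self.variants)
        for e in self.exposures:
            if e not in EXPOSURES:
                raise ValueError(f"unknown exposure {e!r}")
        for v in self.variants:
            if v not in VARIANTS:
                raise ValueError(f"unknown model variant {v!r}")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "imputation": self.imputation,
            "model3_scores": self.model3_scores,
            "ci_level": self.ci_level,
            "exposures": list(self.exposures),
            "variants": list(self.variants),
        }


@dataclass(frozen=True)
class ModelSpec:
    """Covariate list for one exposure x variant (nested across variants)."""

    exposure: str
    variant: str
    score_coding: str = "strata"

    @property
    def covariates(self) -> list[str]:
        cols = [f"{self.exposure}_{ADVANCEMENT}", f"{self.exposure}_{DESCENT}"]
        if self.variant in ("model2", "model3"):
            cols += list(RISK_FACTORS)
        if self.variant == "model3":
            if self.score_coding == "continuous":
                cols += [f"score_{stage}" for stage in STAGES]
            else:
                cols += [
                    f"{stage}_stratum_{level}"
                    for stage in STAGES
                    for level in ("middle", "high")
                ]
        return cols


def make_percentages(counts: dict, total: int) -> dict:
    """Percentages of ``counts`` relative to ``total``, half-up, 1 decimal."""
    if total == 0:
        raise ValidationError("total is zero")
    if sum(counts.values()) != total:
        raise ValidationError(
            f"counts sum to {sum(counts.values())}, expected {total}"
        )
    return {
        key: float(
            (Decimal(100 * int(n)) / Decimal(int(total))).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for key, n in counts.items()
    }


def crude_or_from_counts(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float], bool]:
    """Crude 2x2 odds ratio ``ad/bc`` with a Woolf confidence interval.

    Layout: a = exposed cases, b = exposed controls, c = reference cases,
    d = reference controls.  A zero cell triggers the 0.5 continuity
    correction and sets the returned flag.  This is a per-row diagnostic,
    not the conditional estimate the tables report.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("counts must be non-negative")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        logger.warning("zero cell in 2x2 table; applying 0.5 continuity correction")
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi)), corrected


def prepare_frame(
    df: pd.DataFrame, config: AnalysisConfig
) -> tuple[pd.DataFrame, dict, dict]:
    """Impute, score, derive strata/mobility and add model design columns.

    Returns ``(frame, cutpoints, imputation_counts)``.
    """
    imputed, counts = scoring.impute_frame(df, strategy=config.imputation, seed=config.seed)
    scored = scoring.score_frame(imputed)
    annotated, cutpoints = mobility.annotate_mobility(scored)

    out = annotated
    for exposure in EXPOSURES:
        col = out[f"mobility_{exposure}"]
        for category in (ADVANCEMENT, DESCENT):
            out[f"{exposure}_{category}"] = (col == category).astype(float)
    for stage in STAGES:
        col = out[f"{stage}_stratum"]
        for level in ("middle", "high"):
            out[f"{stage}_stratum_{level}"] = (col == level).astype(float)
    for rf in RISK_FACTORS:
        out[rf] = out[rf].astype(float)
    return out, cutpoints, counts


def _fit_model(frame: pd.DataFrame, spec: ModelSpec, config: AnalysisConfig) -> clogit.FitResult:
    strata = clogit.build_strata(frame, spec.covariates)
    return clogit.fit(strata, spec.covariates, ci_level=config.ci_level)


@dataclass
class AnalysisResult:
    table_occupation: pd.DataFrame
    table_scores: pd.DataFrame
    fits: dict
    cutpoints: dict
    imputation_counts: dict
    config: AnalysisConfig
    n_cases: int
    n_controls: int

    def fit(self, exposure: str, variant: str) -> clogit.FitResult:
        return self.fits[(exposure, variant)]


def _or_cell(fit_result: clogit.FitResult, name: str):
    """(OR, lo, hi) for one coefficient, or None when unavailable."""
    if not fit_result.converged or fit_result.separated:
        return None
    return fit_result.or_ci.get(name)


def _build_table(
    frame: pd.DataFrame,
    exposures: Sequence[str],
    fits: dict,
    variants: Sequence[str],
) -> pd.DataFrame:
    cases = frame[frame["status"] == "case"]
    controls = frame[frame["status"] == "control"]
    rows = []
    for exposure in exposures:
        col = f"mobility_{exposure}"
        case_n = {cat: int((cases[col] == cat).sum()) for cat in MOBILITY_CATEGORIES}
        ctrl_n = {cat: int((controls[col] == cat).sum()) for cat in MOBILITY_CATEGORIES}
        case_pct = make_percentages(case_n, len(cases))
        ctrl_pct = make_percentages(ctrl_n, len(controls))
        for category in MOBILITY_CATEGORIES:
            row = {
                "exposure": exposure,
                "category": category,
                "case_n": case_n[category],
                "case_pct": case_pct[category],
                "control_n": ctrl_n[category],
                "control_pct": ctrl_pct[category],
            }
            for variant in variants:
                key = (exposure, variant)
                cell = None
                if category == NO_CHANGE:
                    cell = (1.0, float("nan"), float("nan"))
                elif key in fits and case_n[category] + ctrl_n[category] > 0:
                    cell = _or_cell(fits[key], f"{exposure}_{category}")
                if cell is None:
                    row[f"{variant}_or"] = np.nan
                    row[f"{variant}_lo"] = np.nan
                    row[f"{variant}_hi"] = np.nan
                else:
                    row[f"{variant}_or"], row[f"{variant}_lo"], row[f"{variant}_hi"] = cell
            rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(df: pd.DataFrame, config: Optional[AnalysisConfig] = None) -> AnalysisResult:
    """Full analysis on a validated study frame.

    Every requested exposure x variant gets one conditional-logistic fit;
    non-converged fits leave their table cells empty and the run
    continues.
    """
    if config is None:
        config = AnalysisConfig()
    frame, cutpoints, imputation_counts = prepare_frame(df, config)

    fits = {}
    for exposure in config.exposures:
        for variant in config.variants:
            spec = ModelSpec(exposure, variant, config.model3_scores)
            try:
                result = _fit_model(frame, spec, config)
            except ValidationError as exc:
                logger.warning("fit %s/%s failed: %s", exposure, variant, exc)
                continue
            if not result.converged:
                logger.warning(
                    "fit %s/%s did not converge (separated=%s)",
                    exposure, variant, result.separated,
                )
            fits[(exposure, variant)] = result

    occ = [e for e in config.exposures if e in OCCUPATION_EXPOSURES]
    sco = [e for e in config.exposures if e in SCORE_EXPOSURES]
    return AnalysisResult(
        table_occupation=_build_table(frame, occ, fits, config.variants),
        table_scores=_build_table(frame, sco, fits, config.variants),
        fits=fits,
        cutpoints=cutpoints,
        imputation_counts=imputation_counts,
        config=config,
        n_cases=int((frame["status"] == "case").sum()),
        n_controls=int((frame["status"] == "control").sum()),
    )


def sex_stratified_fits(
    df: pd.DataFrame, config: Optional[AnalysisConfig] = None
) -> dict[str, dict[str, clogit.FitResult]]:
    """Fully adjusted (model3) fits refit per sex subset.

    Within a single-sex subset the matching strata reduce to the 2-year
    age bands.  A sex with no informative strata is skipped with a
    warning.
    """
    if config is None:
        config = AnalysisConfig()
    out: dict[str, dict[str, clogit.FitResult]] = {}
    for sex in ("m", "f"):
        subset = df[df["sex"] == sex]
        if subset.empty:
            logger.warning("sex %r absent from input; skipped", sex)
            continue
        frame, _, _ = prepare_frame(subset.reset_index(drop=True), config)
        fits = {}
        for exposure in config.exposures:
            spec = ModelSpec(exposure, "model3", config.model3_scores)
            try:
                fits[exposure] = _fit_model(frame, spec, config)
            except ValidationError as exc:
                logger.warning("sex %s, exposure %s: %s", sex, exposure, exc)
        if fits:
            out[sex] = fits
        else:
            logger.warning("sex %r: no informative strata; skipped", sex)
    return out
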