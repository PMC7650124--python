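"""Synthetic frequency-matched case-control studies.

A Gaussian-copula-style construction: one latent disadvantage value per
life stage (childhood -> adolescence -> adulthood follow an AR-style
chain with configurable correlations), each questionnaire item thresholds
its stage's latent value (through an item-specific loading), risk factors
are Bernoulli with logistic dependence on adult disadvantage, and
case/control status follows a logistic model whose coefficients — the
true log odds ratios per mobility category and risk factor — are the
simulation's ground truth.  Controls are then frequency-matched to the
sampled cases on 2-year age band x sex.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

from . import mobility, scoring
from .clogit import age_band
from .records import (
    BOOL_ADVANTAGED,
    CATEGORICAL_LEVELS,
    CSV_COLUMNS,
    RISK_FACTORS,
    SEC_ITEMS,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PopulationDraw",
    "generate_population",
    "assign_outcome",
    "sample_matched_study",
    "simulate_study",
]

#: stage driving each SEC item's latent value
ITEM_STAGE = {name: "child" for name in SEC_ITEMS[:9]}
ITEM_STAGE.update({"school_degree": "adol", "professional_education": "adol"})
ITEM_STAGE.update({name: "adult" for name in ("last_profession", "unemployment_gt6mo", "partnered")})

#: cumulative probabilities of the levels best -> worst (categoricals: all
#: but the last level; booleans: probability of the advantaged value;
#: n_siblings: cumulative probabilities of counts 0..len-1, remainder above)
#: chosen so each life-stage score's control CDF stays clear of 1/3 and
#: 2/3 — tertile cutpoints on discrete scores are then stable across
#: resampled control sets instead of flipping between adjacent values
DEFAULT_ITEM_THRESHOLDS: dict[str, list[float]] = {
    "father_occupation": [0.12, 0.38],
    "mother_occupation": [0.73],
    "family_structure": [0.81, 0.97],
    "n_siblings": [0.15, 0.40, 0.65, 0.85, 0.95],
    "rooms_per_person": [0.29, 0.84],
    "toilet_in_house": [0.90],
    "parental_car": [0.50],
    "income_upper_half": [0.54],
    "paternal_unemployment": [0.88],
    "school_degree": [0.25, 0.60],
    "professional_education": [0.12, 0.42, 0.72],
    "last_profession": [0.25, 0.55, 0.86],
    "unemployment_gt6mo": [0.90],
    "partnered": [0.84],
}

DEFAULT_RF_PREVALENCE: dict[str, float] = {
    "hypertension": 0.50,
    "diabetes": 0.15,
    "hypercholesterolemia": 0.40,
    "atrial_fibrillation": 0.08,
    "coronary_heart_disease": 0.12,
    "peripheral_arterial_disease": 0.05,
    "cardiac_failure": 0.05,
    "low_teeth": 0.30,
    "smoking": 0.25,
    "high_alcohol": 0.10,
    "low_dentist_visits": 0.30,
    "low_physical_activity": 0.40,
    "low_fruit": 0.40,
    "low_vegetable": 0.35,
}

EXPOSURE_NAMES = tuple(c.removeprefix("mobility_") for c in mobility.MOBILITY_COLUMNS)


@dataclass
class SimulationConfig:
    """All knobs of the generator; every random draw flows from ``seed``."""

    seed: int = 0
    n_cases: int = 466
    n_controls: int = 807
    population_size: int = 20_000
    age_mean: float = 66.7
    age_sd: float = 10.7
    #: fraction of ages drawn uniform over [18, 80] so every 2-year band
    #: holds candidate controls (pure truncated normal leaves young bands
    #: empty and matching unfillable)
    age_uniform_mix: float = 0.08
    male_fraction: float = 0.585
    rho_child_adol: float = 0.6
    rho_adol_adult: float = 0.6
    item_loading: float = 0.7
    #: expected population case count = multiple * n_cases (capped at 40%)
    case_target_multiple: float = 3.0
    risk_factor_ses_slope: float = 0.3
    missing_rate: float = 0.0
    #: exposure name -> {"advancement"/"descent": log OR}
    true_log_or: dict = field(default_factory=dict)
    #: risk factor -> log OR on case status
    risk_factor_log_or: dict = field(default_factory=dict)
    risk_factor_prevalence: dict = field(
        default_factory=lambda: dict(DEFAULT_RF_PREVALENCE)
    )
    item_thresholds: dict = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_ITEM_THRESHOLDS)
    )

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0 or self.population_size <= 0:
            raise ValueError("counts must be positive")
        for name in ("rho_child_adol", "rho_adol_adult"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 < self.item_loading <= 1:
            raise ValueError("item_loading must lie in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.age_uniform_mix < 1:
            raise ValueError("age_uniform_mix must lie in [0, 1)")
        for exposure in self.true_log_or:
            if exposure not in EXPOSURE_NAMES:
                raise ValueError(f"unknown exposure {exposure!r}")
        for rf in set(self.risk_factor_log_or) | set(self.risk_factor_prevalence):
            if rf not in RISK_FACTORS:
                raise ValueError(f"unknown risk factor {rf!r}")
        for name, cum in self.item_thresholds.items():
            if name not in DEFAULT_ITEM_THRESHOLDS:
                raise ValueError(f"unknown item {name!r}")
            if any(not 0 < c < 1 for c in cum) or list(cum) != sorted(cum):
                raise ValueError(f"{name}: thresholds must be increasing in (0, 1)")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}


@dataclass
class PopulationDraw:
    """Source population with latent disadvantage values retained."""

    frame: pd.DataFrame
    config: SimulationConfig
    intercept: Optional[float] = None

    @property
    def n(self) -> int:
        return len(self.frame)


def _draw_item(name: str, z_item: np.ndarray, cum: list[float]):
    """Map a standard-normal item latent (higher = worse) to item values."""
    cuts = norm.ppf(np.asarray(cum))
    idx = np.searchsorted(cuts, z_item)
    if name in CATEGORICAL_LEVELS:
        levels = np.array(CATEGORICAL_LEVELS[name], dtype=object)
        return levels[idx]
    if name == "n_siblings":
        return idx.astype(int)
    # boolean: advantaged while the latent stays below the threshold
    advantaged = z_item <= cuts[0]
    return advantaged if BOOL_ADVANTAGED[name] else ~advantaged


def generate_population(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> PopulationDraw:
    """Draw the source population (no outcome yet); deterministic per seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.population_size

    z_child = rng.standard_normal(n)
    r1, r2 = config.rho_child_adol, config.rho_adol_adult
    z_adol = r1 * z_child + np.sqrt(1 - r1**2) * rng.standard_normal(n)
    z_adult = r2 * z_adol + np.sqrt(1 - r2**2) * rng.standard_normal(n)
    stage_latent = {"child": z_child, "adol": z_adol, "adult": z_adult}

    a = (18 - config.age_mean) / config.age_sd
    b = (80 - config.age_mean) / config.age_sd
    ages = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)
    uniform_draw = rng.random(n) < config.age_uniform_mix
    ages = np.where(uniform_draw, 18 + 62 * rng.random(n), ages)

    data: dict[str, object] = {
        "id": np.array([f"p{i:06d}" for i in range(n)], dtype=object),
        "status": np.full(n, "", dtype=object),
        "age_years": np.round(ages, 1),
        "sex": np.where(rng.random(n) < config.male_fraction, "m", "f"),
    }

    load = config.item_loading
    noise_scale = np.sqrt(1 - load**2)
    for name in SEC_ITEMS:
        z_item = load * stage_latent[ITEM_STAGE[name]] + noise_scale * rng.standard_normal(n)
        data[name] = _draw_item(name, z_item, config.item_thresholds[name])

    slope = config.risk_factor_ses_slope
    for rf in RISK_FACTORS:
        prev = config.risk_factor_prevalence.get(rf, 0.2)
        logit_p = np.log(prev / (1 - prev)) + slope * z_adult
        p = 1.0 / (1.0 + np.exp(-logit_p))
        data[rf] = (rng.random(n) < p).astype(int)

    frame = pd.DataFrame(data)
    frame["ses_child"], frame["ses_adol"], frame["ses_adult"] = z_child, z_adol, z_adult
    return PopulationDraw(frame=frame, config=config)


def _annotate(frame: pd.DataFrame) -> pd.DataFrame:
    """Scores, whole-population tertile strata, mobility columns."""
    scored = scoring.score_frame(frame)
    cutpoints = {
        stage: mobility.control_tertile_cutpoints(scored[f"score_{stage}"])
        for stage in ("childhood", "adolescence", "adulthood")
    }
    annotated, _ = mobility.annotate_mobility(scored, cutpoints)
    return annotated


def assign_outcome(
    population: PopulationDraw, rng: Optional[np.random.Generator] = None
) -> PopulationDraw:
    """Draw case/control status from the ground-truth logistic model.

    The intercept is solved numerically so the expected case count hits
    ``case_target_multiple * n_cases`` (capped at 40% of the population).
    """
    config = population.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    frame = _annotate(population.frame)

    lp = np.zeros(len(frame))
    for exposure, effects in config.true_log_or.items():
        col = frame[f"mobility_{exposure}"]
        for category, log_or in effects.items():
            if category not in mobility.MOBILITY_CATEGORIES:
                raise ValueError(f"unknown mobility category {category!r}")
            lp += float(log_or) * (col == category).to_numpy(dtype=float)
    for rf, log_or in config.risk_factor_log_or.items():
        lp += float(log_or) * frame[rf].to_numpy(dtype=float)

    target = min(config.case_target_multiple * config.n_cases, 0.4 * len(frame))

    def expected_cases(intercept: float) -> float:
        return float(np.sum(1.0 / (1.0 + np.exp(-(intercept + lp))))) - target

    intercept = brentq(expected_cases, -40.0, 15.0, xtol=1e-10)
    p_case = 1.0 / (1.0 + np.exp(-(intercept + lp)))
    frame = frame.copy()
    frame["status"] = np.where(rng.random(len(frame)) < p_case, "case", "control")
    logger.info(
        "outcome assigned: intercept=%.4f, %d cases (target %.0f expected)",
        intercept, int((frame["status"] == "case").sum()), target,
    )
    return PopulationDraw(frame=frame, config=config, intercept=intercept)


def _allocate_controls(case_cells: pd.Series, n_controls: int) -> dict:
    """Largest-remainder allocation of controls proportional to case cells."""
    n_cases = case_cells.sum()
    raw = case_cells * n_controls / n_cases
    base = np.floor(raw).astype(int)
    remainder = n_controls - int(base.sum())
    # deterministic order: largest fractional part, cell label as tie-break
    frac = (raw - base).sort_values(ascending=False, kind="stable")
    alloc = base.to_dict()
    for cell in frac.index[:remainder]:
        alloc[cell] += 1
    return alloc


def sample_matched_study(
    population: PopulationDraw, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Sample a frequency-matched study from an outcome-assigned population.

    Controls reproduce the sampled cases' 2-year age band x sex cell
    distribution scaled to ``n_controls``.  Optional MCAR missingness is
    applied to SEC items and risk factors at ``missing_rate``.
    """
    config = population.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    frame = population.frame
    if (frame["status"] == "").any():
        raise ValueError("population has no outcome; run assign_outcome first")

    cell = frame["sex"].astype(str) + "|" + frame["age_years"].map(age_band).astype(str)
    cases = frame[frame["status"] == "case"]
    if len(cases) < config.n_cases:
        raise ValueError(
            f"population holds only {len(cases)} cases; need {config.n_cases}"
        )
    picked_cases = cases.loc[rng.choice(cases.index, size=config.n_cases, replace=False)]

    alloc = _allocate_controls(
        cell.loc[picked_cases.index].value_counts().sort_index(), config.n_controls
    )
    controls = frame[frame["status"] == "control"]
    picked_controls = []
    for cell_label, need in sorted(alloc.items()):
        if need == 0:
            continue
        pool = controls.index[cell.loc[controls.index] == cell_label]
        if len(pool) < need:
            raise ValueError(
                f"cell {cell_label}: need {need} controls, only {len(pool)} available"
            )
        picked_controls.append(controls.loc[rng.choice(pool, size=need, replace=False)])

    study = pd.concat([picked_cases] + picked_controls)
    study = study.sort_index()[list(CSV_COLUMNS)].reset_index(drop=True)

    if config.missing_rate > 0:
        knockout_cols = list(SEC_ITEMS) + list(RISK_FACTORS)
        mask = rng.random((len(study), len(knockout_cols))) < config.missing_rate
        values = study[knockout_cols].to_numpy(dtype=object)
        values[mask] = None
        study[knockout_cols] = values
    return study


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Full chain population -> outcome -> matched study; returns truth too."""
    rng = np.random.default_rng(config.seed)
    population = generate_population(config, rng)
    population = assign_outcome(population, rng)
    study = sample_matched_study(population, rng)
    truth = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "true_log_or": config.true_log_or,
        "risk_factor_log_or": config.risk_factor_log_or,
        "intercept": population.intercept,
        "population_cases": int((population.frame["status"] == "case").sum()),
        "latent_summary": {
            stage: {
                "mean": float(population.frame[f"ses_{stage}"].mean()),
                "sd": float(population.frame[f"ses_{stage}"].std()),
            }
            for stage in ("child", "adol", "adult")
        },
    }
    return study, truth
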