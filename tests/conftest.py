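import numpy as np
import pandas as pd
import pytest

from lcm.records import CSV_COLUMNS, RISK_FACTORS


def make_row(**overrides) -> dict:
    """One fully observed study row with advantaged defaults."""
    row = {
        "id": "s1",
        "status": "control",
        "age_years": 60.0,
        "sex": "m",
        "father_occupation": "academic",
        "mother_occupation": "white_collar_or_academic_or_housewife",
        "family_structure": "both_parents",
        "n_siblings": 1,
        "rooms_per_person": "gt1",
        "toilet_in_house": True,
        "parental_car": True,
        "income_upper_half": True,
        "paternal_unemployment": False,
        "school_degree": "high_school",
        "professional_education": "academic_exam",
        "last_profession": "academic",
        "unemployment_gt6mo": False,
        "partnered": True,
    }
    row.update({rf: 0 for rf in RISK_FACTORS})
    row.update(overrides)
    return row


def make_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows)[list(CSV_COLUMNS)].astype(object)
    df["age_years"] = df["age_years"].astype(float)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated matched study reused across tests."""
    from lcm.synthetic import SimulationConfig, simulate_study

    config = SimulationConfig(
        seed=777, n_cases=80, n_controls=140, population_size=6000,
        age_uniform_mix=0.25,
    )
    study, truth = simulate_study(config)
    return study, truth, config
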