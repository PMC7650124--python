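"""Independent oracles used by the test suite.

Everything here is deliberately naive — enumeration and generic
optimisation — and shares no code path with the package internals it
checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize

# frozen per-item point table, written down independently of the package
ORACLE_POINTS = {
    "father_occupation": {"academic": 0, "white_collar": 1, "blue_or_unskilled": 2},
    "mother_occupation": {"white_collar_or_academic_or_housewife": 0, "blue_or_unskilled": 1},
    "family_structure": {"both_parents": 0, "one_parent": 1, "no_parents": 2},
    "rooms_per_person": {"gt1": 0, "half_to_1": 1, "lt_half": 2},
    "toilet_in_house": {True: 0, False: 1},
    "parental_car": {True: 0, False: 1},
    "income_upper_half": {True: 0, False: 1},
    "paternal_unemployment": {False: 0, True: 1},
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
    "unemployment_gt6mo": {False: 0, True: 2},
    "partnered": {True: 0, False: 2},
}


def oracle_score(profile: dict) -> int:
    total = 0
    for name, value in profile.items():
        if name == "n_siblings":
            total += 1 if value > 3 else 0
        else:
            total += ORACLE_POINTS[name][value]
    return total


def brute_stratum_logdenom(eta: np.ndarray, m: int) -> float:
    """log sum over all size-m subsets of exp(sum eta), by enumeration."""
    terms = [
        sum(eta[i] for i in subset)
        for subset in itertools.combinations(range(len(eta)), m)
    ]
    mx = max(terms)
    return mx + math.log(sum(math.exp(t - mx) for t in terms))


def brute_loglik(strata, beta) -> float:
    """Exact conditional log-likelihood by subset enumeration."""
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for s in strata:
        if not (0 < s.y.sum() < len(s.y)):
            continue
        eta = s.X @ beta
        total += float(eta[s.y == 1].sum()) - brute_stratum_logdenom(eta, int(s.y.sum()))
    return total


def brute_fit(strata, p: int) -> np.ndarray:
    """Maximiser of the enumerated likelihood via generic optimisation.

    BFGS is followed by a few finite-difference Newton polish steps so
    the oracle is accurate well past 1e-6 even along flat directions.
    """
    res = minimize(
        lambda b: -brute_loglik(strata, b),
        np.zeros(p),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    beta = res.x
    eps = 1e-5
    for _ in range(8):
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        for j in range(p):
            ej = np.zeros(p)
            ej[j] = eps
            grad[j] = (brute_loglik(strata, beta + ej) - brute_loglik(strata, beta - ej)) / (2 * eps)
            for k in range(j + 1):
                ek = np.zeros(p)
                ek[k] = eps
                hess[j, k] = hess[k, j] = (
                    brute_loglik(strata, beta + ej + ek)
                    - brute_loglik(strata, beta + ej - ek)
                    - brute_loglik(strata, beta - ej + ek)
                    + brute_loglik(strata, beta - ej - ek)
                ) / (4 * eps**2)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)) or np.max(np.abs(step)) > 1.0:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def brute_tertile_cutpoints(values):
    """Smallest values whose empirical CDF reaches 1/3 and 2/3."""
    values = sorted(values)
    n = len(values)

    def cdf(v):
        return sum(1 for x in values if x <= v) / n

    uniq = sorted(set(values))
    q1 = next(v for v in uniq if cdf(v) >= 1 / 3 - 1e-12)
    q2 = next(v for v in uniq if cdf(v) >= 2 / 3 - 1e-12)
    return q1, q2


def random_strata(rng, n_strata=4, max_size=8, p=2, beta_scale=0.8):
    """Random small informative strata for oracle comparisons."""
    from lcm.clogit import Stratum

    strata = []
    for k in range(n_strata):
        n = rng.integers(2, max_size + 1)
        m = rng.integers(1, n)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=m, replace=False)] = 1
        X = rng.normal(scale=beta_scale, size=(n, p))
        strata.append(Stratum(f"s{k}", y, X))
    return strata
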