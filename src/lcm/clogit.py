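"""Exact conditional logistic regression for frequency-matched strata.

The conditional likelihood for a stratum with members ``(y_i, x_i)`` and
``m`` cases conditions on the number of cases; its denominator — the sum
of ``exp(sum of x'beta)`` over all size-``m`` subsets — is computed by
the standard recursion over elementary symmetric-type sums, never by
subset enumeration.  Gradient and Hessian use the same recursion carried
to first and second order, so Newton-Raphson converges in a handful of
steps.  The hot loop is JIT-compiled with numba when available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import AGE_MAX, AGE_MIN, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Stratum",
    "FitResult",
    "build_strata",
    "age_band",
    "conditional_loglik",
    "fit",
    "wald_or_ci",
]

BAND_WIDTH = 2

# separation / convergence policy
MAX_ABS_BETA = 15.0
DEFAULT_MAX_ITER = 50
SCORE_TOL = 1e-8
STEP_TOL = 1e-10


def _stratum_core_loops(eta, X, m, order):
    """Log-denominator of one stratum plus ratio derivatives.

    Returns ``(logdenom, d1, d2)`` where ``d1 = B'/B`` (length p) and
    ``d2 = B''/B`` (p x p); ``B`` is the sum over all size-``m`` subsets
    of ``exp(sum eta)``.  ``order`` in {0,1,2} limits the work done.
    Scalar loops on purpose: numba compiles them allocation-free.
    """
    n = eta.shape[0]
    p = X.shape[1]
    shift = eta.max()
    w = np.exp(eta - shift)
    f = np.zeros(m + 1)
    f[0] = 1.0
    f1 = np.zeros((m + 1, p))
    f2 = np.zeros((m + 1, p, p))
    for i in range(n):
        e = w[i]
        x = X[i]
        kmax = min(i + 1, m)
        for k in range(kmax, 0, -1):
            fk1 = f[k - 1]
            if order >= 2:
                for a in range(p):
                    xa = x[a]
                    g1a = f1[k - 1, a]
                    for b in range(a + 1):
                        f2[k, a, b] += e * (
                            f2[k - 1, a, b]
                            + xa * f1[k - 1, b]
                            + g1a * x[b]
                            + fk1 * xa * x[b]
                        )
            if order >= 1:
                for a in range(p):
                    f1[k, a] += e * (f1[k - 1, a] + fk1 * x[a])
            f[k] += e * fk1
    B = f[m]
    d2 = f2[m] / B
    for a in range(p):  # mirror the lower triangle
        for b in range(a):
            d2[b, a] = d2[a, b]
    return np.log(B) + m * shift, f1[m] / B, d2


def _stratum_core_numpy(eta, X, m, order):
    """Vectorised fallback with identical semantics (used without numba)."""
    n, p = X.shape
    shift = eta.max()
    w = np.exp(eta - shift)
    f = np.zeros(m + 1)
    f[0] = 1.0
    f1 = np.zeros((m + 1, p))
    f2 = np.zeros((m + 1, p, p))
    for i in range(n):
        e = w[i]
        x = X[i]
        kmax = min(i + 1, m)
        for k in range(kmax, 0, -1):
            if order >= 2:
                xf = np.outer(x, f1[k - 1])
                f2[k] += e * (f2[k - 1] + xf + xf.T + f[k - 1] * np.outer(x, x))
            if order >= 1:
                f1[k] += e * (f1[k - 1] + f[k - 1] * x)
            f[k] += e * f[k - 1]
    B = f[m]
    return np.log(B) + m * shift, f1[m] / B, f2[m] / B


try:  # pragma: no cover - numba is the normal path
    import numba

    _stratum_core = numba.njit(cache=True)(_stratum_core_loops)
except ImportError:  # pragma: no cover
    _stratum_core = _stratum_core_numpy


@dataclass
class Stratum:
    """One matched set (2-year age band x sex)."""

    stratum_id: str
    y: np.ndarray  # 0/1 outcome
    X: np.ndarray  # members x covariates

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValidationError(f"stratum {self.stratum_id}: shape mismatch")

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    @property
    def informative(self) -> bool:
        m = self.n_cases
        return 0 < m < self.y.shape[0]


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit summary."""

    covariate_names: list[str]
    beta: np.ndarray
    covariance: Optional[np.ndarray]
    loglik: float
    n_informative_strata: int
    converged: bool
    separated: bool
    n_iterations: int
    dropped: list[str] = field(default_factory=list)
    ci_level: float = 0.95

    @property
    def se(self) -> Optional[np.ndarray]:
        if self.covariance is None:
            return None
        return np.sqrt(np.diag(self.covariance))

    @property
    def or_ci(self) -> dict[str, tuple[float, float, float]]:
        return wald_or_ci(self, level=self.ci_level)

    def to_dict(self) -> dict:
        out = {
            "covariates": self.covariate_names,
            "beta": [float(b) for b in self.beta],
            "se": None if self.se is None else [float(s) for s in self.se],
            "loglik": float(self.loglik),
            "n_informative_strata": self.n_informative_strata,
            "converged": self.converged,
            "separated": self.separated,
            "n_iterations": self.n_iterations,
            "dropped": self.dropped,
        }
        if self.converged and not self.separated and self.covariance is not None:
            out["or_ci"] = {
                name: [float(v) for v in vals] for name, vals in self.or_ci.items()
            }
        return out


def age_band(age: float) -> int:
    """Index of the half-open 2-year band [18,20), ..., [78,80]."""
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValidationError(f"age_years: {age!r} outside [{AGE_MIN}, {AGE_MAX}]")
    return min(int((age - AGE_MIN) // BAND_WIDTH), (AGE_MAX - AGE_MIN) // BAND_WIDTH - 1)


def build_strata(df: pd.DataFrame, covariates: Sequence[str]) -> list[Stratum]:
    """Group a study frame into 2-year age band x sex strata.

    Uninformative strata (all cases or all controls) are kept in the
    returned list but flagged; :func:`fit` excludes them from the
    likelihood and logs the exclusion.
    """
    bands = df["age_years"].map(age_band)
    y = (df["status"] == "case").to_numpy(dtype=np.int64)
    X = df[list(covariates)].to_numpy(dtype=np.float64)
    strata = []
    keys = pd.DataFrame({"sex": df["sex"].to_numpy(), "band": bands.to_numpy()})
    for (sex, band), idx in keys.groupby(["sex", "band"], sort=True).groups.items():
        lo = AGE_MIN + BAND_WIDTH * band
        sid = f"{sex}:[{lo},{lo + BAND_WIDTH})"
        pos = np.asarray(idx)
        strata.append(Stratum(sid, y[pos], X[pos]))
    return strata


def _loglik_parts(strata: list[Stratum], beta: np.ndarray, order: int):
    p = beta.shape[0]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for s in strata:
        eta = s.X @ beta
        m = s.n_cases
        logdenom, d1, d2 = _stratum_core(eta, s.X, m, order)
        case = s.y == 1
        ll += float(eta[case].sum() - logdenom)
        if order >= 1:
            grad += s.X[case].sum(axis=0) - d1
        if order >= 2:
            hess -= d2 - np.outer(d1, d1)
    return ll, grad, hess


def conditional_loglik(strata: Sequence[Stratum], beta) -> float:
    """Exact conditional log-likelihood over the informative strata."""
    beta = np.asarray(beta, dtype=np.float64)
    informative = [s for s in strata if s.informative]
    if not informative:
        raise ValidationError("no informative strata")
    for s in informative:
        if s.X.shape[1] != beta.shape[0]:
            raise ValidationError(
                f"stratum {s.stratum_id}: {s.X.shape[1]} covariates vs beta of "
                f"length {beta.shape[0]}"
            )
    return _loglik_parts(informative, beta, order=0)[0]


def _constant_within_all_strata(strata: list[Stratum], j: int) -> bool:
    return all(np.ptp(s.X[:, j]) == 0 for s in strata)


def fit(
    strata: Sequence[Stratum],
    covariate_names: Optional[Sequence[str]] = None,
    *,
    max_iter: int = DEFAULT_MAX_ITER,
    score_tol: float = SCORE_TOL,
    step_tol: float = STEP_TOL,
    ci_level: float = 0.95,
) -> FitResult:
    """Newton-Raphson maximisation of the exact conditional likelihood.

    Covariates with no within-stratum variation anywhere are dropped with
    a warning (they cancel from the conditional likelihood).  Monotone
    likelihoods (separation) are flagged and confidence intervals
    suppressed; non-convergence is never reported as success.
    """
    strata = list(strata)
    informative = [s for s in strata if s.informative]
    n_dropped_strata = len(strata) - len(informative)
    if n_dropped_strata:
        logger.info("excluded %d uninformative strata from the likelihood", n_dropped_strata)
    if not informative:
        raise ValidationError("no informative strata")

    p_all = informative[0].X.shape[1]
    if covariate_names is None:
        covariate_names = [f"x{j}" for j in range(p_all)]
    covariate_names = list(covariate_names)
    if len(covariate_names) != p_all:
        raise ValidationError("covariate_names length mismatch")

    keep = [j for j in range(p_all) if not _constant_within_all_strata(informative, j)]
    dropped = [covariate_names[j] for j in range(p_all) if j not in keep]
    if dropped:
        logger.warning("dropping covariates constant within every stratum: %s", dropped)
    names = [covariate_names[j] for j in keep]
    work = [Stratum(s.stratum_id, s.y, s.X[:, keep]) for s in informative]
    p = len(keep)
    if p == 0:
        raise ValidationError("no usable covariates remain")

    beta = np.zeros(p)
    ll, grad, hess = _loglik_parts(work, beta, order=2)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < score_tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # damped step: halve until the loglik does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _loglik_parts(work, cand, order=0)[0]
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        ll, grad, hess = _loglik_parts(work, beta, order=2)
        if np.max(np.abs(scale * step)) < step_tol:
            converged = np.max(np.abs(grad)) < np.sqrt(score_tol)
            break
        if np.max(np.abs(beta)) > MAX_ABS_BETA:
            separated = True
            logger.warning("monotone likelihood suspected: |beta| exceeded %g", MAX_ABS_BETA)
            break
    else:
        it = max_iter
    if not converged and not separated and np.max(np.abs(beta)) > MAX_ABS_BETA / 2:
        separated = True

    covariance = None
    if converged and not separated:
        try:
            covariance = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            logger.warning("singular information matrix; covariance unavailable")
            converged = False
    return FitResult(
        covariate_names=names,
        beta=beta,
        covariance=covariance,
        loglik=ll,
        n_informative_strata=len(informative),
        converged=converged,
        separated=separated,
        n_iterations=it,
        dropped=dropped,
        ci_level=ci_level,
    )


def wald_or_ci(
    fit_result: FitResult, level: float = 0.95, strict: bool = True
) -> dict[str, tuple[float, float, float]]:
    """Per-coefficient odds ratio with Wald interval ``exp(beta +/- z*se)``."""
    if not fit_result.converged or fit_result.separated:
        raise ValidationError("cannot form Wald intervals: fit did not converge")
    se = fit_result.se
    z = norm.ppf(0.5 + level / 2)
    out = {}
    for name, b, s in zip(fit_result.covariate_names, fit_result.beta, se):
        if s == 0:
            if strict:
                raise ValidationError(f"{name}: zero standard error")
            odds = float(np.exp(b))
            out[name] = (odds, odds, odds)
            continue
        out[name] = (
            float(np.exp(b)),
            float(np.exp(b - z * s)),
            float(np.exp(b + z * s)),
        )
    return out
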