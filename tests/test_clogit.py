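import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_frame, make_row
from oracles import brute_fit, brute_loglik, random_strata

from lcm.clogit import (
    FitResult,
    Stratum,
    age_band,
    build_strata,
    conditional_loglik,
    fit,
    wald_or_ci,
)
from lcm.records import ValidationError


def mirror_strata():
    # case x=1 / control x=0 mirrored by case x=0 / control x=1
    return [
        Stratum("a", [1, 0], [[1.0], [0.0]]),
        Stratum("b", [1, 0], [[0.0], [1.0]]),
    ]


class TestLoglik:
    def test_null_beta_gives_log_binomial(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 9))
            m = int(rng.integers(1, n))
            y = np.zeros(n, dtype=int)
            y[:m] = 1
            s = Stratum("s", y, rng.normal(size=(n, 3)))
            ll = conditional_loglik([s], np.zeros(3))
            assert ll == pytest.approx(-math.log(math.comb(n, m)), abs=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            strata = random_strata(rng, n_strata=int(rng.integers(1, 5)), p=3)
            beta = rng.normal(scale=0.7, size=3)
            assert conditional_loglik(strata, beta) == pytest.approx(
                brute_loglik(strata, beta), abs=1e-10
            )

    def test_gradient_matches_finite_differences(self, rng):
        from lcm.clogit import _loglik_parts

        strata = [s for s in random_strata(rng, n_strata=4, p=3) if s.informative]
        beta = rng.normal(scale=0.5, size=3)
        _, grad, hess = _loglik_parts(strata, beta, order=2)
        eps = 1e-6
        for j in range(3):
            step = np.zeros(3)
            step[j] = eps
            fd = (
                brute_loglik(strata, beta + step) - brute_loglik(strata, beta - step)
            ) / (2 * eps)
            assert grad[j] == pytest.approx(fd, abs=1e-5)
            fd2 = (
                _loglik_parts(strata, beta + step, order=1)[1]
                - _loglik_parts(strata, beta - step, order=1)[1]
            ) / (2 * eps)
            np.testing.assert_allclose(hess[:, j], fd2, atol=1e-5)

    def test_dimension_mismatch_rejected(self):
        s = Stratum("s", [1, 0], [[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValidationError):
            conditional_loglik([s], [0.5])

    def test_uninformative_strata_excluded(self):
        informative = Stratum("a", [1, 0], [[1.0], [0.0]])
        all_cases = Stratum("b", [1, 1, 1], [[1.0], [2.0], [3.0]])
        assert not all_cases.informative
        assert conditional_loglik([informative, all_cases], [0.3]) == pytest.approx(
            conditional_loglik([informative], [0.3])
        )


class TestFit:
    def test_mirror_strata_give_zero(self):
        result = fit(mirror_strata())
        assert result.converged and not result.separated
        assert result.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_optimum(self, rng):
        for _ in range(8):
            strata = random_strata(rng, n_strata=6, p=2)
            if not any(s.informative for s in strata):
                continue
            ours = fit(strata)
            if not ours.converged:
                continue
            ref = brute_fit([s for s in strata if s.informative], p=2)
            np.testing.assert_allclose(ours.beta, ref, atol=1e-6)

    def test_separation_flagged(self):
        result = fit([Stratum("s", [1, 0], [[1.0], [0.0]])])
        assert result.separated
        assert not result.converged
        with pytest.raises(ValidationError):
            wald_or_ci(result)

    def test_constant_covariate_dropped_others_unchanged(self, rng):
        strata = random_strata(rng, n_strata=6, p=2)
        # append a covariate constant within each stratum
        augmented = [
            Stratum(s.stratum_id, s.y, np.hstack([s.X, np.full((len(s.y), 1), i * 1.0)]))
            for i, s in enumerate(strata)
        ]
        base = fit(strata, ["x0", "x1"])
        aug = fit(augmented, ["x0", "x1", "const"])
        assert aug.dropped == ["const"]
        assert aug.covariate_names == ["x0", "x1"]
        np.testing.assert_allclose(aug.beta, base.beta, atol=1e-10)

    def test_matched_pair_classical_estimator(self, rng):
        # 1:1 matching with a binary covariate: beta = log(n10/n01)
        strata = []
        n10 = n01 = 0
        for k in range(60):
            x_case, x_ctrl = rng.integers(0, 2, size=2)
            strata.append(Stratum(f"p{k}", [1, 0], [[float(x_case)], [float(x_ctrl)]]))
            n10 += x_case == 1 and x_ctrl == 0
            n01 += x_case == 0 and x_ctrl == 1
        result = fit(strata)
        assert result.beta[0] == pytest.approx(math.log(n10 / n01), abs=1e-8)

    def test_parameter_recovery_small_strata(self, rng):
        # 100 strata of 1 case : 2 controls, true log-OR 0.7, 200 reps
        true = 0.7
        estimates = []
        for _ in range(200):
            strata = []
            for k in range(100):
                x = rng.integers(0, 2, size=3).astype(float)
                w = np.exp(true * x)
                case = rng.choice(3, p=w / w.sum())
                y = np.zeros(3, dtype=int)
                y[case] = 1
                strata.append(Stratum(f"s{k}", y, x.reshape(-1, 1)))
            result = fit(strata)
            if result.converged:
                estimates.append(result.beta[0])
        assert np.mean(estimates) == pytest.approx(true, abs=0.1)

    def test_statsmodels_cross_validation(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        groups, y, X = [], [], []
        for k in range(80):
            size = 3
            xk = rng.normal(size=(size, 2))
            w = np.exp(xk @ np.array([0.5, -0.3]))
            case = rng.choice(size, p=w / w.sum())
            for i in range(size):
                groups.append(k)
                y.append(1 if i == case else 0)
                X.append(xk[i])
        X = np.asarray(X)
        sm_fit = ConditionalLogit(np.asarray(y), X, groups=np.asarray(groups)).fit(disp=0)
        strata = [
            Stratum(
                str(k),
                [y[i] for i in range(len(y)) if groups[i] == k],
                X[[i for i in range(len(y)) if groups[i] == k]],
            )
            for k in range(80)
        ]
        ours = fit(strata)
        np.testing.assert_allclose(ours.beta, sm_fit.params, atol=1e-5)
        np.testing.assert_allclose(ours.se, sm_fit.bse, atol=1e-4)


class TestBuildStrata:
    def test_band_boundary_splits(self):
        df = make_frame(
            [make_row(id="a", age_years=19.0), make_row(id="b", age_years=20.0)]
        )
        strata = build_strata(df, ["hypertension"])
        assert len(strata) == 2

    def test_age_band_edges(self):
        assert age_band(18.0) == 0
        assert age_band(19.99) == 0
        assert age_band(20.0) == 1
        assert age_band(80.0) == 30  # top band is closed
        with pytest.raises(ValidationError):
            age_band(17.5)
        with pytest.raises(ValidationError):
            age_band(80.5)

    def test_partition_covers_all_records(self, rng):
        n_cases, n_controls = 466, 807
        rows = []
        for i in range(n_cases + n_controls):
            rows.append(
                make_row(
                    id=f"s{i}",
                    status="case" if i < n_cases else "control",
                    age_years=float(rng.uniform(18, 80)),
                    sex="m" if rng.random() < 0.5 else "f",
                )
            )
        df = make_frame(rows)
        strata = build_strata(df, ["hypertension"])
        assert len(strata) <= 62  # 31 bands x 2 sexes
        assert sum(len(s.y) for s in strata) == n_cases + n_controls

    def test_uninformative_stratum_flagged_and_excluded(self):
        rows = [make_row(id=f"c{i}", status="case", age_years=30.0) for i in range(3)]
        rows += [
            make_row(id="d1", status="case", age_years=50.0),
            make_row(id="d2", status="control", age_years=50.0, smoking=1),
        ]
        df = make_frame(rows)
        strata = build_strata(df, ["smoking"])
        flags = {s.stratum_id: s.informative for s in strata}
        assert list(flags.values()).count(False) == 1
        result = fit(strata)
        assert result.n_informative_strata == 1


class TestWald:
    def test_null_beta_closed_form(self):
        result = FitResult(
            covariate_names=["x"],
            beta=np.array([0.0]),
            covariance=np.array([[0.01]]),
            loglik=0.0,
            n_informative_strata=1,
            converged=True,
            separated=False,
            n_iterations=1,
        )
        odds, lo, hi = wald_or_ci(result)["x"]
        assert (round(odds, 2), round(lo, 2), round(hi, 2)) == (1.0, 0.82, 1.22)

    def test_log_two_closed_form(self):
        result = FitResult(
            covariate_names=["x"],
            beta=np.array([math.log(2)]),
            covariance=np.array([[0.04]]),
            loglik=0.0,
            n_informative_strata=1,
            converged=True,
            separated=False,
            n_iterations=1,
        )
        odds, lo, hi = wald_or_ci(result)["x"]
        assert (round(odds, 2), round(lo, 2), round(hi, 2)) == (2.0, 1.35, 2.96)

    def test_zero_se_strict_flag(self):
        result = FitResult(
            covariate_names=["x"],
            beta=np.array([0.5]),
            covariance=np.array([[0.0]]),
            loglik=0.0,
            n_informative_strata=1,
            converged=True,
            separated=False,
            n_iterations=1,
        )
        with pytest.raises(ValidationError):
            wald_or_ci(result, strict=True)
        odds, lo, hi = wald_or_ci(result, strict=False)["x"]
        assert odds == lo == hi == pytest.approx(math.exp(0.5))

    def test_bounds_bracket_estimate(self, rng):
        strata = random_strata(rng, n_strata=8, p=2)
        result = fit(strata)
        if result.converged:
            for odds, lo, hi in result.or_ci.values():
                assert lo < odds < hi
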