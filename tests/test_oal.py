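import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivweights import (
    OALConfig,
    ScenarioConfig,
    fit_penalized_logistic,
    gamma_for_lambda,
    oal_estimate,
    outcome_association_coefs,
    penalty_weights,
    simulate_dataset,
    standardize,
    wamd,
)


class TestStandardize:
    def test_near_identity_on_standard_columns(self, rng):
        X = rng.standard_normal((50_000, 3))
        Xs, means, sds = standardize(X)
        assert np.allclose(means, 0, atol=0.02) and np.allclose(sds, 1, atol=0.02)

    def test_scale_recorded(self, rng):
        X = 2.0 * rng.standard_normal((10_000, 1))
        Xs, _, sds = standardize(X)
        assert sds[0] == pytest.approx(2.0, rel=0.05)
        assert Xs.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="0"):
            standardize(np.column_stack([np.ones(10)]))


class TestOutcomeAssociation:
    def test_noise_free_single_predictor(self, rng):
        X = rng.standard_normal((300, 3))
        Xs, _, sds = standardize(X)
        Z = rng.integers(0, 2, 300)
        Y = X[:, 0] * 1.0
        a = outcome_association_coefs(Xs, Z, Y)
        assert a[0] == pytest.approx(sds[0], abs=1e-10)
        assert np.allclose(a[1:], 0, atol=1e-10)

    def test_large_sample_recovers_design_coefficients(self, big_dataset):
        Xs, _, _ = standardize(big_dataset.X)
        a = outcome_association_coefs(Xs, big_dataset.Z, big_dataset.Y)
        assert np.allclose(a[:4], 1.0, atol=0.05)
        assert np.allclose(a[4:], 0.0, atol=0.05)


class TestGammaAlgebra:
    @pytest.mark.parametrize(
        "exponent,expected",
        [(-2.0, 10.0), (0.49, 5.02), (-10.0, 26.0)],
    )
    def test_solves_the_defining_equation(self, exponent, expected):
        n = 500
        lam = float(n) ** exponent
        gamma = gamma_for_lambda(lam, n)
        assert gamma == pytest.approx(expected, abs=1e-10)
        assert lam * n ** (gamma / 2 - 1) == pytest.approx(n**2, rel=1e-8)

    def test_degenerate_n(self):
        with pytest.raises(ValueError):
            gamma_for_lambda(0.5, 1)


class TestPenaltyWeights:
    def test_unit_base(self):
        assert penalty_weights(np.array([1.0]), 2.0)[0] == 1.0

    def test_inverse_power(self):
        assert penalty_weights(np.array([0.5]), 2.0)[0] == pytest.approx(4.0)

    def test_zero_maps_to_cap(self):
        assert penalty_weights(np.array([0.0]), 2.0, omega_cap=1e8)[0] == 1e8

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            penalty_weights(np.array([1.0]), 1.0)


class TestPenalizedLogistic:
    def test_unpenalized_limit_matches_ml(self, small_dataset):
        from ivweights import fit_logistic_ps

        X = small_dataset.X[:, :5]
        Xs, _, _ = standardize(X)
        b0, beta = fit_penalized_logistic(Xs, small_dataset.Z, 0.0, np.ones(5))
        ml = fit_logistic_ps(Xs, small_dataset.Z)
        assert b0 == pytest.approx(ml.intercept, abs=1e-4)
        assert np.allclose(beta, ml.coef, atol=1e-4)

    def test_full_shrinkage_limit(self, small_dataset):
        Xs, _, _ = standardize(small_dataset.X)
        b0, beta = fit_penalized_logistic(Xs, small_dataset.Z, 1e6, np.ones(20))
        assert np.allclose(beta, 0)
        zbar = small_dataset.Z.mean()
        assert b0 == pytest.approx(np.log(zbar / (1 - zbar)), abs=1e-6)

    def test_matches_independent_l1_solver(self, rng):
        # oracle: sklearn's saga L1 logistic on penalty-rescaled columns
        from sklearn.linear_model import LogisticRegression

        n, J = 200, 3
        X = rng.standard_normal((n, J))
        Z = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * X[:, 0] - 0.5 * X[:, 1])))).astype(int)
        lam = 3.0
        omega = np.array([1.0, 2.0, 0.5])
        b0, beta = fit_penalized_logistic(X, Z, lam, omega)
        ref = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="saga", tol=1e-12, max_iter=200_000
        ).fit(X / omega, Z)
        beta_ref = ref.coef_[0] / omega
        assert b0 == pytest.approx(ref.intercept_[0], abs=1e-4)
        assert np.allclose(beta, beta_ref, atol=1e-4)

    def test_capped_penalty_excludes_covariate(self, rng):
        n = 300
        X = rng.standard_normal((n, 2))
        Z = (rng.random(n) < 0.5).astype(int)
        omega = np.array([1.0, 1e8])
        _, beta = fit_penalized_logistic(X, Z, 1e-20, omega, omega_cap=1e8)
        assert beta[1] == 0.0

    def test_local_optimality_of_solution(self, small_dataset):
        # perturbing any coordinate must not increase the penalized likelihood
        Xs, _, _ = standardize(small_dataset.X[:, :6])
        Z = small_dataset.Z
        lam, omega = 5.0, np.ones(6)
        b0, beta = fit_penalized_logistic(Xs, Z, lam, omega)

        def objective(b0_, beta_):
            eta = b0_ + Xs @ beta_
            return float(Z @ eta - np.logaddexp(0, eta).sum() - lam * omega @ np.abs(beta_))

        base = objective(b0, beta)
        for j in range(6):
            for d in (1e-3, -1e-3):
                pert = beta.copy()
                pert[j] += d
                assert objective(b0, pert) <= base + 1e-9

    def test_monotone_shrinkage_in_lambda(self, small_dataset):
        Xs, _, _ = standardize(small_dataset.X[:, :8])
        omega = np.ones(8)
        norms = []
        for lam in (0.0, 1.0, 5.0, 25.0, 125.0):
            _, beta = fit_penalized_logistic(Xs, small_dataset.Z, lam, omega)
            norms.append(np.abs(beta).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))


class TestWAMD:
    def test_zero_outcome_weights(self, rng):
        X = rng.standard_normal((20, 3))
        Z = np.repeat([0, 1], 10)
        assert wamd(X, Z, np.full(20, 0.5), np.zeros(3)) == 0.0

    def test_hand_computed_six_unit_toy(self):
        # constant e_hat = mean(Z) makes the Hajek means plain group means
        X = np.array([[1.0], [2.0], [3.0], [5.0], [6.0], [7.0]])
        Z = np.array([1, 1, 1, 0, 0, 0])
        val = wamd(X, Z, np.full(6, 0.5), np.array([2.0]))
        assert val == pytest.approx(2.0 * abs(2.0 - 6.0))

    def test_perfect_balance_gives_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        Z = np.array([1, 1, 0, 0])
        assert wamd(X, Z, np.full(4, 0.5), np.array([1.5])) == pytest.approx(0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_scales_linearly_in_outcome_coefficients(self, scale):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 4))
        Z = rng.permutation(np.repeat([0, 1], 15))
        e = rng.uniform(0.3, 0.7, 30)
        a = rng.standard_normal(4)
        assert wamd(X, Z, e, scale * a) == pytest.approx(scale * wamd(X, Z, e, a))

    def test_invariant_to_covariate_relabeling(self, rng):
        X = rng.standard_normal((40, 5))
        Z = rng.permutation(np.repeat([0, 1], 20))
        e = rng.uniform(0.2, 0.8, 40)
        a = rng.standard_normal(5)
        perm = rng.permutation(5)
        assert wamd(X[:, perm], Z, e, a[perm]) == pytest.approx(wamd(X, Z, e, a))


class TestOALPipeline:
    def test_selects_confounders_and_outcome_predictors(self):
        # strong-IV design: X1-X4 should be kept, the IVs X5-X6 dropped
        hits = np.zeros(6)
        reps = 20
        for r in range(reps):
            d = simulate_dataset(ScenarioConfig(n=2000, J=20, theta=1.0, seed=6000 + r))
            _, fit = oal_estimate(d.X, d.Z, d.Y)
            for j in range(6):
                hits[j] += j in fit.selected_set
        assert np.all(hits[:4] >= 0.9 * reps)
        assert np.all(hits[4:6] <= 0.5 * reps)

    def test_pure_noise_outcome_falls_back_to_smallest_lambda(self, rng):
        n = 400
        X = rng.standard_normal((n, 6))
        Z = (rng.random(n) < 0.5).astype(int)
        Y = rng.standard_normal(n)  # no covariate touches Y
        est, fit = oal_estimate(X, Z, Y)
        assert fit.selected_index == int(np.argmin(fit.path["wamd"].to_numpy()))
        assert np.isfinite(est.tau_hat)

    def test_path_export_schema(self, small_dataset, tmp_path):
        _, fit = oal_estimate(small_dataset.X, small_dataset.Z, small_dataset.Y)
        p = tmp_path / "path.csv"
        fit.path_csv(p)
        import pandas as pd

        out = pd.read_csv(p)
        assert {"lambda_exponent", "lambda", "gamma", "wamd", "n_nonzero"} <= set(out.columns)
        assert len(out) == len(OALConfig().lambda_exponents)
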