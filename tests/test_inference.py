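"""Asymptotic covariances, Wald tests and the bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esplsm import (
    asymptotic_cov,
    bootstrap_inference,
    fit_esplsm,
    generate_dataset,
    make_design,
    wald_test,
)
from esplsm.inference import asymptotic_cov_params

from conftest import random_dataset


class TestWald:
    def test_null_point(self):
        res = wald_test(np.zeros((2, 2)), np.eye(4), n=50)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_scalar_chi_square(self):
        res = wald_test(np.array([[0.2]]), np.array([[1.0]]), n=100)
        assert np.isclose(res.statistic, 4.0)
        assert np.isclose(res.p_value, 0.0455, atol=2e-4)
        assert res.df == 1

    def test_rank_deficient_covariance_uses_rank_df(self):
        V = np.outer([1.0, 1.0], [1.0, 1.0])  # rank 1
        res = wald_test(np.array([[0.1, 0.1]]), V, n=100)
        assert res.df == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(1, 3), st.integers(1, 3))
    def test_statistic_and_p_value_contracts(self, seed, k, r):
        # for any PSD covariance and effect: stat >= 0, p in [0, 1],
        # df equals the numerical rank
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((k * r, k * r))
        V = A @ A.T
        effect = rng.standard_normal((k, r))
        res = wald_test(effect, V, n=50)
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0
        assert res.df == np.linalg.matrix_rank(V)


class TestAsymptoticCov:
    def _fit(self, rng, n=400):
        data = random_dataset(rng, n=n, r=2, p=4, k=2, q=1)
        return fit_esplsm(data, d=2, seed=0, tune_lambda=False, sparse=False)

    def test_symmetric_psd(self, rng):
        for _ in range(3):
            fit = self._fit(rng)
            cov = asymptotic_cov(fit)
            for V in (cov.V_direct, cov.V_indirect):
                assert np.allclose(V, V.T)
                assert np.linalg.eigvalsh(V).min() > -1e-8

    def test_full_dimension_drops_complement_term(self, rng):
        data = random_dataset(rng, n=300, r=2, p=3, k=1, q=1)
        fit = fit_esplsm(data, d=3, seed=0, sparse=False)
        cov = asymptotic_cov(fit)
        core = fit.gamma_X @ fit.basis.Gamma @ np.linalg.solve(
            fit.Omega, fit.basis.Gamma.T @ fit.gamma_X.T
        )
        expect = np.kron(
            fit.Sigma_Y_given_MXZ,
            core + np.linalg.inv(fit.S_X_given_Z),
        )
        assert np.allclose(cov.V_direct, expect, atol=1e-8)

    def test_eta_zero_reduction(self):
        # with eta = 0 the indirect covariance collapses to its first term
        Sigma_Y = np.array([[2.0]])
        Gamma = np.array([[1.0], [0.0], [0.0]])
        Gamma0 = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        Omega = np.array([[1.5]])
        Omega0 = np.diag([0.7, 0.9])
        eta = np.zeros((1, 1))
        gamma_X = np.array([[1.0, 0.5, -0.3]])
        SXZ = np.array([[0.25]])
        cov = asymptotic_cov_params(
            Sigma_Y, Gamma, Gamma0, Omega, Omega0, eta, gamma_X, SXZ
        )
        core = gamma_X @ Gamma @ np.linalg.solve(Omega, Gamma.T @ gamma_X.T)
        assert np.allclose(cov.V_indirect, np.kron(Sigma_Y, core), atol=1e-12)

    def test_monte_carlo_validation_of_direct_covariance(self):
        # empirical covariance of sqrt(n) vec(beta_X_hat) vs the formula
        design = make_design("main", seed_design=5, n=2000)
        reps = 400
        draws = []
        for i in range(reps):
            data, truth = generate_dataset(design, seed_data=i)
            fit = fit_esplsm(data, d=1, seed=i, sparse=False)
            draws.append(np.sqrt(design.n)
                         * (fit.beta_X - truth["beta_X"]).flatten(order="F"))
        emp = np.cov(np.stack(draws).T, ddof=1).reshape(1, 1)
        V = asymptotic_cov_params(
            design.Sigma_Y, design.Gamma, design.Gamma0, design.Omega,
            design.Omega0, design.eta, design.gamma_X,
            0.25 * np.eye(1),  # Var Bernoulli(0.5) exposure given Z
        ).V_direct
        rel = np.linalg.norm(emp - V) / np.linalg.norm(V)
        assert rel < 0.15


class TestBootstrap:
    def test_identical_seed_identical_output(self):
        design = make_design("main", seed_design=9, n=150)
        data, _ = generate_dataset(design, seed_data=0)
        a = bootstrap_inference(data, d=1, B=100, seed=42, tune_lambda=False)
        b = bootstrap_inference(data, d=1, B=100, seed=42, tune_lambda=False)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.ci_lower, rb.ci_lower)
            assert np.array_equal(ra.ci_upper, rb.ci_upper)
            assert ra.p_value == rb.p_value

    def test_minimum_replicates_enforced(self):
        design = make_design("main", seed_design=9, n=150)
        data, _ = generate_dataset(design, seed_data=0)
        with pytest.raises(ValueError):
            bootstrap_inference(data, d=1, B=50)

    def test_strong_signal_hits_p_value_floor(self):
        design = make_design("main", seed_design=9, n=400, c1=4.0)
        data, _ = generate_dataset(design, seed_data=1)
        direct, _ = bootstrap_inference(
            data, d=1, B=100, seed=0, tune_lambda=False
        )
        assert np.isclose(direct.p_value, 1.0 / 101.0)

    def test_bootstrap_se_close_to_asymptotic_se(self):
        # the closed-form covariance describes the envelope estimator; the
        # case-resampling bootstrap of that same estimator must agree
        design = make_design("main", seed_design=5, n=1000)
        data, _ = generate_dataset(design, seed_data=7)
        fit = fit_esplsm(data, d=1, seed=0, sparse=False)
        V = asymptotic_cov(fit).V_direct
        se_asy = float(np.sqrt(V[0, 0] / design.n))
        rng = np.random.default_rng(3)
        draws = []
        for b in range(300):
            idx = rng.integers(0, design.n, design.n)
            from esplsm import MediationDataset

            boot = MediationDataset(data.Y[idx], data.M[idx], data.X[idx],
                                    data.Z[idx])
            fb = fit_esplsm(boot, d=1, seed=b, sparse=False)
            draws.append(fb.beta_X[0, 0])
        se_boot = float(np.std(draws, ddof=1))
        assert abs(se_boot - se_asy) / se_asy < 0.20
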