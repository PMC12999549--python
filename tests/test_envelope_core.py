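"""Envelope objective, Grassmann optimization and dimension selection."""

import warnings

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from esplsm import (
    EnvelopeBasis,
    MediationDataset,
    compute_moments,
    envelope_objective,
    estimate_parameters,
    fit_envelope,
    generate_dataset,
    make_design,
    select_dimension,
)
from esplsm.envelope_core import complete_basis

from conftest import random_dataset


def _identity_basis(p):
    return EnvelopeBasis(np.eye(p), np.empty((p, 0)), p)


class TestObjective:
    def test_full_dimension_value(self, small_moments):
        m = small_moments
        p = m.p
        val = envelope_objective(_identity_basis(p), m)
        _, ld_y = np.linalg.slogdet(m.S_Y_given_XZ)
        _, ld_m = np.linalg.slogdet(m.S_M_given_XZ)
        _, ld_my = np.linalg.slogdet(m.S_M_given_YXZ)
        assert abs(val - (ld_y - ld_m + ld_my)) < 1e-10

    def test_rotation_invariance(self, small_moments, rng):
        p = small_moments.p
        G = np.linalg.qr(rng.standard_normal((p, 2)))[0]
        basis = EnvelopeBasis(G, complete_basis(G), 2)
        theta = 0.83
        O = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = EnvelopeBasis(G @ O, complete_basis(G @ O), 2)
        assert abs(
            envelope_objective(basis, small_moments)
            - envelope_objective(rotated, small_moments)
        ) < 1e-10


def _grid_minimum_2d(moments, n_grid=62832):
    """Independent oracle: exhaustive theta-grid for p=2, d=1."""
    thetas = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    V = np.vstack([np.cos(thetas), np.sin(thetas)])  # 2 x n_grid
    A = np.linalg.inv(moments.S_M_given_XZ)
    B = moments.S_M_given_YXZ
    vals = np.log(np.einsum("ij,ij->j", V, A @ V)) + np.log(
        np.einsum("ij,ij->j", V, B @ V)
    )
    _, ld_y = np.linalg.slogdet(moments.S_Y_given_XZ)
    j = int(np.argmin(vals))
    return vals[j] + ld_y, V[:, j]


class TestFitEnvelope:
    def test_grid_oracle_p2(self, rng):
        data = random_dataset(rng, n=20, r=1, p=2, k=1, q=0)
        mom = compute_moments(data)
        basis = fit_envelope(mom, 1, seed=0)
        f_grid, v_grid = _grid_minimum_2d(mom)
        assert envelope_objective(basis, mom) <= f_grid + 1e-6
        ang = subspace_angles(basis.Gamma, v_grid[:, None])[0]
        assert ang < 1e-3

    def test_grid_oracle_p3(self, rng):
        # two-stage spherical grid oracle for p=3, d=1
        data = random_dataset(rng, n=30, r=2, p=3, k=1, q=0)
        mom = compute_moments(data)
        A = np.linalg.inv(mom.S_M_given_XZ)
        B = mom.S_M_given_YXZ

        def phi(V):
            return np.log(np.einsum("ij,ij->j", V, A @ V)) + np.log(
                np.einsum("ij,ij->j", V, B @ V)
            )

        th = np.linspace(0, np.pi, 400)
        ph = np.linspace(0, np.pi, 400)
        T, P = np.meshgrid(th, ph)
        best = None
        for _ in range(3):  # refine around the coarse minimum
            V = np.vstack([
                (np.sin(T) * np.cos(P)).ravel(),
                (np.sin(T) * np.sin(P)).ravel(),
                np.cos(T).ravel(),
            ])
            vals = phi(V)
            j = int(np.argmin(vals))
            best = V[:, j]
            t0, p0 = T.ravel()[j], P.ravel()[j]
            span = (th[1] - th[0]) * 2
            th = np.linspace(t0 - span, t0 + span, 200)
            ph = np.linspace(p0 - span, p0 + span, 200)
            T, P = np.meshgrid(th, ph)
        basis = fit_envelope(mom, 1, seed=0)
        _, ld_y = np.linalg.slogdet(mom.S_Y_given_XZ)
        assert envelope_objective(basis, mom) <= phi(best[:, None])[0] + ld_y + 1e-6
        assert subspace_angles(basis.Gamma, best[:, None])[0] < 1e-3

    def test_full_dimension_reduces_to_ols(self, small_moments):
        basis = fit_envelope(small_moments, small_moments.p)
        fit = estimate_parameters(small_moments, basis)
        beta_ols = np.linalg.solve(
            small_moments.S_M_given_XZ, small_moments.S_YM_given_XZ.T
        )
        assert np.allclose(fit.beta_M, beta_ols, atol=1e-8)

    def test_consistency_at_large_n(self):
        design = make_design("main", seed_design=7, n=100000)
        data, _ = generate_dataset(design, seed_data=1)
        mom = compute_moments(data)
        basis = fit_envelope(mom, 1, seed=0)
        ang = subspace_angles(basis.Gamma, design.Gamma)[0]
        assert ang < 0.05

    def test_objective_monotone_in_d(self, rng):
        data = random_dataset(rng, n=60, r=3, p=5, k=1, q=1)
        mom = compute_moments(data)
        vals = [fit_envelope(mom, d, seed=0).objective
                for d in range(1, 6)]
        assert all(vals[i + 1] <= vals[i] + 1e-6 for i in range(4))

    def test_d_bounds(self, small_moments):
        with pytest.raises(ValueError):
            fit_envelope(small_moments, small_moments.p + 1)
        b0 = fit_envelope(small_moments, 0)
        assert b0.Gamma.shape == (small_moments.p, 0)
        bp = fit_envelope(small_moments, small_moments.p)
        assert np.allclose(bp.Gamma, np.eye(small_moments.p))


class TestSelectDimension:
    def test_range_contract_and_majority_on_main_design(self):
        hits = 0
        n_sets = 6
        for i in range(n_sets):
            design = make_design("main", seed_design=40 + i, n=500)
            data, _ = generate_dataset(design, seed_data=i)
            d = select_dimension(data, d_max=3, folds=3, seed=i)
            assert 0 <= d <= 3
            hits += d == 1
        assert hits >= n_sets - 1  # true d=1 recovered in a clear majority

    def test_pure_noise_flags_or_returns_zero(self, rng):
        n = 120
        M = rng.standard_normal((n, 4))
        X = rng.standard_normal((n, 1))
        Y = rng.standard_normal((n, 1))  # independent of everything
        data = MediationDataset(Y, M, X, None)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            d = select_dimension(data, d_max=3, folds=3, seed=0)
        flat = any("flat" in str(w.message) for w in rec)
        assert d == 0 or flat

    def test_folds_validation(self, small_data):
        with pytest.raises(ValueError):
            select_dimension(small_data, folds=1)
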