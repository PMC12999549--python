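"""Centering, residualization and conditional covariance blocks."""

import numpy as np
import pytest

from esplsm import MediationDataset, center_and_residualize, compute_moments
from esplsm.data_moments import SampleSizeError, SingularDesignError

from conftest import random_dataset


def _lstsq_residuals(A, W):
    """Independent per-column least-squares oracle (centered inputs)."""
    Ac = A - A.mean(axis=0)
    if W.shape[1] == 0:
        return Ac
    Wc = W - W.mean(axis=0)
    out = np.empty_like(Ac)
    for j in range(Ac.shape[1]):
        coef, *_ = np.linalg.lstsq(Wc, Ac[:, j], rcond=None)
        out[:, j] = Ac[:, j] - Wc @ coef
    return out


class TestResidualization:
    def test_no_covariates_residuals_are_centered_m(self, rng):
        M = rng.standard_normal((10, 3))
        data = MediationDataset(rng.standard_normal((10, 1)), M,
                                np.zeros((10, 0)), None)
        mom = center_and_residualize(data)
        assert np.allclose(mom.R_M, M - M.mean(axis=0))

    def test_residuals_orthogonal_to_design(self, small_data):
        mom = center_and_residualize(small_data)
        scale = np.linalg.norm(mom.R_M) * np.linalg.norm(mom.Wc) + 1e-300
        assert np.max(np.abs(mom.R_M.T @ mom.Wc)) / scale < 1e-8
        assert np.max(np.abs(mom.R_Y.T @ mom.Wc)) / scale < 1e-8

    def test_six_observation_toy_matches_lstsq_oracle(self):
        # fixed values, k=1, q=1
        Y = np.array([[1.0], [2.0], [0.5], [3.0], [2.5], [1.5]])
        M = np.array([[0.2, 1.0], [1.1, 0.4], [-0.3, 0.9], [2.0, -1.0],
                      [1.4, 0.1], [0.6, 2.2]])
        X = np.array([[0.0], [1.0], [0.0], [1.0], [1.0], [0.0]])
        Z = np.array([[0.3], [-0.2], [1.1], [0.4], [-0.9], [0.5]])
        data = MediationDataset(Y, M, X, Z)
        mom = center_and_residualize(data)
        W = np.hstack([X, Z])
        assert np.allclose(mom.R_M, _lstsq_residuals(M, W), atol=1e-10)
        assert np.allclose(mom.R_Y, _lstsq_residuals(Y, W), atol=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.standard_normal((12, 1))
        Z = np.hstack([X, rng.standard_normal((12, 1))])  # Z[0] == X[0]
        data = MediationDataset(rng.standard_normal((12, 1)),
                                rng.standard_normal((12, 2)), X, Z)
        with pytest.raises(SingularDesignError, match=r"Z\[0\]|X\[0\]"):
            center_and_residualize(data)

    def test_sample_too_small(self, rng):
        data = MediationDataset(rng.standard_normal((4, 1)),
                                rng.standard_normal((4, 2)),
                                rng.standard_normal((4, 2)),
                                rng.standard_normal((4, 1)))
        with pytest.raises(SampleSizeError):
            center_and_residualize(data)


def _oracle_blocks(data):
    """Brute-force covariance oracle from explicit residual outer products."""
    n = data.n
    X, Z, M, Y = data.X, data.Z, data.M, data.Y
    W = np.hstack([X, Z])
    RM = _lstsq_residuals(M, W)
    RY = _lstsq_residuals(Y, W)
    RX_Z = _lstsq_residuals(X, Z)
    RZ_X = _lstsq_residuals(Z, X)
    Mc = M - M.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S_M = RM.T @ RM / n
    S_Y = RY.T @ RY / n
    S_YM = RY.T @ RM / n
    return {
        "S_M_given_XZ": S_M,
        "S_Y_given_XZ": S_Y,
        "S_YM_given_XZ": S_YM,
        "S_M_given_YXZ": S_M - S_YM.T @ np.linalg.solve(S_Y, S_YM),
        "S_X_given_Z": RX_Z.T @ RX_Z / n,
        "S_Z_given_X": RZ_X.T @ RZ_X / n,
        "S_XM_given_Z": RX_Z.T @ Mc / n,
        "S_ZM_given_X": RZ_X.T @ Mc / n,
        "S_XY_given_Z": RX_Z.T @ Yc / n,
        "S_ZY_given_X": RZ_X.T @ Yc / n,
    }


class TestConditionalCovariances:
    def test_all_blocks_match_brute_force_oracle(self, rng):
        for trial in range(3):
            data = random_dataset(rng, n=18, r=2, p=3, k=2, q=1)
            mom = compute_moments(data)
            oracle = _oracle_blocks(data)
            for name, expect in oracle.items():
                got = getattr(mom, name)
                denom = max(1.0, np.linalg.norm(expect))
                assert np.linalg.norm(got - expect) / denom < 1e-10, name

    def test_schur_identity_and_psd_order(self, small_moments):
        m = small_moments
        diff = m.S_M_given_XZ - m.S_M_given_YXZ
        eigs = np.linalg.eigvalsh((diff + diff.T) / 2)
        assert eigs.min() > -1e-10  # S_{M|Y,X,Z} <= S_{M|X,Z} in PSD order
        direct = m.S_M_given_XZ - m.S_YM_given_XZ.T @ np.linalg.solve(
            m.S_Y_given_XZ, m.S_YM_given_XZ
        )
        assert np.allclose(m.S_M_given_YXZ, direct, atol=1e-12)

    def test_independent_mediator_limit(self, rng):
        # p=1 mediator independent of Y: cross term vanishes with n
        n = 4000
        M = rng.standard_normal((n, 1))
        Y = rng.standard_normal((n, 1))
        data = MediationDataset(Y, M, np.zeros((n, 0)), None)
        mom = compute_moments(data)
        assert abs(mom.S_M_given_YXZ[0, 0] - mom.S_M_given_XZ[0, 0]) < 0.01

    def test_scale_equivariance(self, small_data):
        mom1 = compute_moments(small_data)
        c = 3.7
        M2 = small_data.M.copy()
        M2[:, 1] *= c
        mom2 = compute_moments(
            MediationDataset(small_data.Y, M2, small_data.X, small_data.Z)
        )
        expect = mom1.S_M_given_XZ.copy()
        expect[1, :] *= c
        expect[:, 1] *= c
        assert np.allclose(mom2.S_M_given_XZ, expect, atol=1e-12)

    def test_permutation_consistency(self, small_data):
        perm = np.array([2, 0, 3, 1])
        mom1 = compute_moments(small_data)
        mom2 = compute_moments(MediationDataset(
            small_data.Y, small_data.M[:, perm], small_data.X, small_data.Z
        ))
        assert np.allclose(
            mom2.S_M_given_XZ, mom1.S_M_given_XZ[np.ix_(perm, perm)]
        )
        assert np.allclose(
            mom2.S_YM_given_XZ, mom1.S_YM_given_XZ[:, perm]
        )


class TestDatasetValidation:
    def test_row_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="rows"):
            MediationDataset(rng.standard_normal((5, 1)),
                             rng.standard_normal((6, 2)),
                             rng.standard_normal((5, 1)))

    def test_nonfinite_rejected(self, rng):
        M = rng.standard_normal((5, 2))
        M[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            MediationDataset(rng.standard_normal((5, 1)), M,
                             rng.standard_normal((5, 1)))
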