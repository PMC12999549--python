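"""Closed-form parameter estimates given an envelope basis.

Once the envelope subspace is fixed, every remaining parameter of the
mediation model has an explicit expression in the conditional sample moments:

    gamma_X = S_{X|Z}^{-1} S_{(X,M)|Z}            (exposure -> mediator)
    eta     = (G' S_{M|X,Z} G)^{-1} G' S_{(M,Y)|X,Z}
    beta_M  = G eta                               (mediator -> outcome)
    beta_X  = S_{X|Z}^{-1} (S_{(X,Y)|Z} - S_{(X,M)|Z} beta_M)   (direct)
    Omega   = G' S_{M|X,Z} G,   Omega0 = G0' S_{M|X,Z} G0
    Sigma_{Y|M,X,Z} = (1/n) R_Y' Q_{R_M G} R_Y

Equivalently beta_M is the projection of the OLS coefficient onto span(G) in
the S_{M|X,Z} inner product; with d = p everything reduces to OLS, with d = 0
to the no-mediation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_moments import ConditionalMoments, SingularDesignError
from .envelope_core import EnvelopeBasis
from .sparse_envelope import SparseConfig, SparsityPattern


@dataclass
class ESPLSMFit:
    """Complete set of model estimates for one dataset and basis."""

    mu_Y: np.ndarray
    mu_M: np.ndarray
    mu_X: np.ndarray
    mu_Z: np.ndarray
    gamma_X: np.ndarray  # (k, p)
    gamma_Z: np.ndarray  # (q, p)
    eta: np.ndarray  # (d, r)
    beta_M: np.ndarray  # (p, r)
    beta_X: np.ndarray  # (k, r)
    beta_Z: np.ndarray  # (q, r)
    Omega: np.ndarray  # (d, d)
    Omega0: np.ndarray  # (p-d, p-d)
    Sigma_Y_given_MXZ: np.ndarray  # (r, r)
    Sigma_M_given_XZ: np.ndarray  # (p, p)
    basis: EnvelopeBasis
    pattern: SparsityPattern
    config: SparseConfig | None = None
    objective_value: float = np.nan
    n: int = 0
    S_X_given_Z: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.basis.d

    @property
    def indirect_effect(self) -> np.ndarray:
        """gamma_X beta_M, the (k, r) indirect-effect matrix."""
        return self.gamma_X @ self.beta_M


def project_ols(
    beta_ols: np.ndarray, basis: EnvelopeBasis, S: np.ndarray
) -> np.ndarray:
    """Project a p x r coefficient matrix onto span(Gamma) in the S metric.

    Returns Gamma (Gamma' S Gamma)^{-1} Gamma' S beta_ols; idempotent in the
    S inner product.
    """
    G = basis.Gamma
    if basis.d == 0:
        return np.zeros_like(beta_ols)
    inner = G.T @ S @ G
    return G @ np.linalg.solve(inner, G.T @ S @ beta_ols)


def _solve_psd(S: np.ndarray, B: np.ndarray, label: str) -> np.ndarray:
    if S.shape[0] == 0:
        return np.zeros((0, B.shape[1]))
    try:
        c, low = np.linalg.cholesky(S), True
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(
            f"{label} is singular (collinear exposures/confounders)"
        ) from exc
    y = np.linalg.solve(c, B)
    return np.linalg.solve(c.T, y)


def estimate_parameters(
    moments: ConditionalMoments,
    basis: EnvelopeBasis,
    pattern: SparsityPattern | None = None,
    config: SparseConfig | None = None,
    S_complement: np.ndarray | None = None,
) -> ESPLSMFit:
    """Assemble the full fit from moments and a (possibly sparse) basis.

    ``S_complement`` optionally substitutes a positive-definite surrogate for
    S_{M|X,Z} when forming Omega0 on the p > n path.
    """
    G, G0, d = basis.Gamma, basis.Gamma0, basis.d
    p, r, n = moments.p, moments.r, moments.n
    k, q = moments.k, moments.q
    S = moments.S_M_given_XZ
    S_MY = moments.S_YM_given_XZ.T  # (p, r)

    if pattern is None:
        pattern = (
            SparsityPattern.from_basis(G) if d else SparsityPattern.dense(p)
        )

    gamma_X = _solve_psd(moments.S_X_given_Z, moments.S_XM_given_Z,
                         "S_{X|Z}")
    gamma_Z = _solve_psd(moments.S_Z_given_X, moments.S_ZM_given_X,
                         "S_{Z|X}")

    if d:
        Omega = G.T @ S @ G
        eta = np.linalg.solve(Omega, G.T @ S_MY)
        beta_M = G @ eta
        beta_M[pattern.excluded] = 0.0  # exact zeros from the sparse rows
    else:
        Omega = np.empty((0, 0))
        eta = np.empty((0, r))
        beta_M = np.zeros((p, r))

    beta_X = _solve_psd(
        moments.S_X_given_Z,
        moments.S_XY_given_Z - moments.S_XM_given_Z @ beta_M,
        "S_{X|Z}",
    )
    beta_Z = _solve_psd(
        moments.S_Z_given_X,
        moments.S_ZY_given_X - moments.S_ZM_given_X @ beta_M,
        "S_{Z|X}",
    )

    S_cmp = S if S_complement is None else S_complement
    Omega0 = G0.T @ S_cmp @ G0

    # Sigma_{Y|M,X,Z} = (1/n) R_Y' Q_{R_M Gamma} R_Y
    if d:
        F = moments.R_M @ G  # (n, d)
        FtF = F.T @ F
        R_Y_adj = moments.R_Y - F @ np.linalg.solve(FtF, F.T @ moments.R_Y)
        Sigma_Y = R_Y_adj.T @ moments.R_Y / n
    else:
        Sigma_Y = moments.S_Y_given_XZ.copy()
    Sigma_Y = (Sigma_Y + Sigma_Y.T) / 2.0

    if d and p - d:
        Sigma_M = G @ Omega @ G.T + G0 @ Omega0 @ G0.T
    elif d:
        Sigma_M = G @ Omega @ G.T
    else:
        Sigma_M = G0 @ Omega0 @ G0.T

    return ESPLSMFit(
        mu_Y=moments.mu_Y, mu_M=moments.mu_M, mu_X=moments.mu_X,
        mu_Z=moments.mu_Z,
        gamma_X=gamma_X, gamma_Z=gamma_Z, eta=eta, beta_M=beta_M,
        beta_X=beta_X, beta_Z=beta_Z, Omega=Omega, Omega0=Omega0,
        Sigma_Y_given_MXZ=Sigma_Y, Sigma_M_given_XZ=Sigma_M,
        basis=basis, pattern=pattern, config=config,
        objective_value=basis.objective, n=n,
        S_X_given_Z=moments.S_X_given_Z,
    )
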