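"""Positive-definite covariance surrogates for the p > n path.

When the number of mediators exceeds the sample size, S_{M|X,Z} and
S_{M|Y,X,Z} are singular and their inverses, required by the envelope
objective, do not exist.  Sparse permutation-invariant covariance estimation
(SPICE) replaces them: minimize

    tr(S Theta) - log|Theta| + penalty * sum_{i != j} |Theta_ij|

over positive-definite Theta, which is convex and yields a PD inverse (and
covariance) even for rank-deficient S.  The solve is delegated to the
graphical-lasso routine of scikit-learn; the default penalty follows the
theoretical rate c * sqrt(log p / n) with c = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso

from .data_moments import MediationDataset, compute_moments
from .estimators import ESPLSMFit, estimate_parameters
from .sparse_envelope import (
    SparseConfig,
    fit_sparse_envelope,
    select_lambda,
)
from .envelope_core import fit_envelope

DEFAULT_RATE_CONSTANT = 0.5


@dataclass
class SpiceEstimate:
    """PD covariance / inverse pair from the penalized log-det program."""

    Sigma: np.ndarray
    Theta: np.ndarray
    penalty: float
    converged: bool

    def __post_init__(self):
        self.Sigma = (self.Sigma + self.Sigma.T) / 2.0
        self.Theta = (self.Theta + self.Theta.T) / 2.0


def default_penalty(n: int, p: int) -> float:
    """Theoretical-rate default: 0.5 * sqrt(log p / n)."""
    return DEFAULT_RATE_CONSTANT * np.sqrt(np.log(max(p, 2)) / n)


def spice_covariance(
    residuals: np.ndarray,
    penalty: float | str = "auto",
    max_iter: int = 200,
) -> SpiceEstimate:
    """PD covariance surrogate from an n x p (centered) residual matrix.

    The sample covariance uses the 1/n convention.  The penalized inverse is
    positive definite for every penalty > 0 regardless of rank(S).
    """
    R = np.asarray(residuals, dtype=float)
    n, p = R.shape
    if n < 2:
        raise ValueError("need at least two observations")
    S = R.T @ R / n
    S = (S + S.T) / 2.0
    if penalty == "auto":
        penalty = default_penalty(n, p)
    penalty = float(penalty)
    if penalty <= 0:
        # unpenalized: only valid when S is PD
        return SpiceEstimate(S, np.linalg.inv(S), 0.0, True)
    # solve on the correlation scale (numerically far better conditioned),
    # then map back: Sigma = D C D with D = diag(sd)
    sd = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    Corr = S / np.outer(sd, sd)
    np.fill_diagonal(Corr, 1.0)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Sigma_c, Theta_c = graphical_lasso(
                Corr, alpha=penalty, max_iter=max_iter, tol=1e-8,
                enet_tol=1e-10,
            )
    except Exception:
        converged = False
        # shrinkage fallback keeps the PD guarantee
        a = min(0.9, max(0.05, penalty))
        Sigma_c = (1.0 - a) * Corr + a * np.eye(p)
        Theta_c = np.linalg.inv(Sigma_c)
    Sigma = Sigma_c * np.outer(sd, sd)
    Theta = Theta_c / np.outer(sd, sd)
    return SpiceEstimate(Sigma, Theta, penalty, converged)


def spice_surrogates(
    moments, penalty: float | str = "auto"
) -> dict:
    """Surrogate blocks for the envelope objective on the p > n path.

    S_{M|Y,X,Z} is estimated by applying the same machinery to the residuals
    of M after additionally projecting off R_Y (guaranteed PD), rather than
    by differencing two surrogates.
    """
    est_m = spice_covariance(moments.R_M, penalty)
    # residuals of R_M on R_Y: Y-adjusted mediator residuals
    R_Y = moments.R_Y
    if R_Y.shape[1]:
        Q, _ = np.linalg.qr(R_Y)
        R_MY = moments.R_M - Q @ (Q.T @ moments.R_M)
    else:
        R_MY = moments.R_M
    est_my = spice_covariance(R_MY, penalty)
    return {
        "inv_S_M_given_XZ": est_m.Theta,
        "S_M_given_XZ": est_m.Sigma,
        "S_M_given_YXZ": est_my.Sigma,
        "inv_S_M_given_YXZ": est_my.Theta,
        "spice_M": est_m,
        "spice_MY": est_my,
    }


def fit_highdim(
    data: MediationDataset,
    d: int,
    config: SparseConfig | None = None,
    seed: int = 0,
    penalty: float | str = "auto",
    tune_lambda: bool = True,
) -> ESPLSMFit:
    """Sparse-envelope pipeline with SPICE surrogates (p > n or forced).

    The surrogates replace S_{M|X,Z}^{-1} and S_{M|Y,X,Z} exactly where the
    objective and the algorithm need an inverse of a singular block; all
    downstream closed-form estimates that only need d x d or k x k inverses
    use the raw moments.
    """
    moments = compute_moments(data)
    sur = spice_surrogates(moments, penalty)
    pilot = fit_envelope(moments, d, seed=seed, surrogates=sur)
    if config is None or config.weights is None:
        from .sparse_envelope import adaptive_weights

        base = adaptive_weights(pilot)
        if config is not None:
            base.lam = config.lam
            base.lam_grid = config.lam_grid
        config = base
    if tune_lambda:
        config = select_lambda(
            moments, d, config, criterion="bic", seed=seed, pilot=pilot,
            surrogates=sur,
        )
    basis, pattern = fit_sparse_envelope(
        moments, d, config, seed=seed, pilot=pilot, surrogates=sur
    )
    fit = estimate_parameters(
        moments, basis, pattern, config,
        S_complement=sur["S_M_given_XZ"],
    )
    fit.diagnostics["spice_penalty"] = sur["spice_M"].penalty
    fit.diagnostics["highdim"] = True
    return fit
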