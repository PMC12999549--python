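"""Row-sparse envelope estimation with an adaptive group lasso penalty.

Mediator selection works through the envelope basis: a mediator whose row of
``Gamma`` is zero has exactly zero outcome-side coefficients (beta_M = Gamma
eta inherits the zero row) and is *sparsity-excluded*.  The penalized
objective adds weighted row-wise Euclidean norms of Gamma to the envelope
objective, with data-adaptive weights from an unpenalized pilot fit so that
rows the pilot already estimates near zero are shrunk hardest.

Because the objective lives on the Grassmannian, the penalty is applied in an
anchored coordinate system: the d rows with the largest pilot norms are fixed
to the identity block (unpenalized anchors) and the remaining p - d free rows
``C`` carry the group penalty.  For a non-orthonormal basis G the span-only
part of the objective is

    log|G' S^{-1} G| + log|G' S_{M|Y} G| - 2 log|G' G|,

minimized by proximal-gradient steps with row-wise group soft-thresholding,
warm-started along a decreasing lambda path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_moments import ConditionalMoments, MediationDataset
from .envelope_core import (
    EnvelopeBasis,
    canonicalize,
    complete_basis,
    envelope_objective,
    fit_envelope,
    _objective_matrices,
)

HARD_ZERO = 1e-6  # row-norm threshold below which a row is exactly zero
WEIGHT_EPS = 1e-8


class OverShrinkageError(ValueError):
    """The penalty removed so many rows that fewer than d survive."""


@dataclass
class SparsityPattern:
    """Selected / excluded mediator index sets (0-based)."""

    selected: np.ndarray
    excluded: np.ndarray
    p: int

    def __post_init__(self):
        self.selected = np.asarray(sorted(self.selected), dtype=int)
        self.excluded = np.asarray(sorted(self.excluded), dtype=int)
        union = np.union1d(self.selected, self.excluded)
        if len(union) != self.p or (
            len(self.selected) + len(self.excluded) != self.p
        ):
            raise ValueError("selected/excluded must partition {0..p-1}")

    @property
    def p_selected(self) -> int:
        return len(self.selected)

    @property
    def p_excluded(self) -> int:
        return len(self.excluded)

    @classmethod
    def dense(cls, p: int) -> "SparsityPattern":
        return cls(np.arange(p), np.empty(0, dtype=int), p)

    @classmethod
    def from_basis(cls, Gamma: np.ndarray) -> "SparsityPattern":
        norms = np.linalg.norm(Gamma, axis=1) if Gamma.size else np.zeros(
            Gamma.shape[0]
        )
        sel = np.where(norms > 0)[0]
        return cls(sel, np.setdiff1d(np.arange(Gamma.shape[0]), sel),
                   Gamma.shape[0])


@dataclass
class SparseConfig:
    """Penalty level, adaptive weights and the tuning grid."""

    lam: float = 0.0
    weights: np.ndarray | None = None  # length p; anchors are ignored
    weight_exponent: float = 2.0
    lam_grid: np.ndarray | None = None
    n_grid: int = 20
    criterion_path: list = field(default_factory=list)  # tuning diagnostics
    warm_C: np.ndarray | None = None  # path solution at the selected lambda
    null_preferred: bool = False  # tuning favored the no-mediation model

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("adaptive weights must be positive")


def adaptive_weights(
    pilot: EnvelopeBasis, exponent: float = 2.0
) -> SparseConfig:
    """Weights w_i = (||pilot Gamma row i|| + eps)^(-exponent).

    Rows the unpenalized pilot estimates near zero get large weights and are
    shrunk hardest; the epsilon floor keeps every weight finite.
    """
    if exponent <= 0:
        raise ValueError("weight exponent must be positive")
    norms = np.linalg.norm(pilot.Gamma, axis=1)
    w = (norms + WEIGHT_EPS) ** (-exponent)
    return SparseConfig(weights=w, weight_exponent=exponent)


def _anchor_split(
    pilot: EnvelopeBasis, diag_S: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Anchor rows = the d largest scale-weighted pilot row norms.

    Ranking by ||pilot row i|| * sd(M_i | X, Z) prefers well-measured
    mediators as the unpenalized coordinate frame; anchoring a
    tiny-variance mediator would let pure noise in its coordinate leak
    into the outcome-side coefficients with a huge lever arm.
    """
    norms = np.linalg.norm(pilot.Gamma, axis=1)
    if diag_S is not None:
        norms = norms * np.sqrt(np.clip(diag_S, 0.0, None))
    order = np.argsort(norms)[::-1]
    anchors = np.sort(order[: pilot.d])
    free = np.sort(order[pilot.d:])
    return anchors, free


def _build_G(C, anchors, free, p, d):
    G = np.zeros((p, d))
    G[anchors] = np.eye(d)
    G[free] = C
    return G


def _span_value_grad(G, A, B):
    """Value/gradient of the span objective for a non-orthonormal basis."""
    MA = G.T @ A @ G
    MB = G.T @ B @ G
    MG = G.T @ G
    sa, la = np.linalg.slogdet(MA)
    sb, lb = np.linalg.slogdet(MB)
    sg, lg = np.linalg.slogdet(MG)
    if min(sa, sb, sg) <= 0:
        return np.inf, None
    val = la + lb - 2.0 * lg
    grad = (
        2.0 * A @ G @ np.linalg.inv(MA)
        + 2.0 * B @ G @ np.linalg.inv(MB)
        - 4.0 * G @ np.linalg.inv(MG)
    )
    return val, grad


def _prox_rows(C, thresh):
    """Row-wise group soft-threshold: c_i <- (1 - t_i/||c_i||)_+ c_i."""
    norms = np.linalg.norm(C, axis=1)
    scale = np.where(norms > thresh, 1.0 - thresh / np.maximum(norms, 1e-300),
                     0.0)
    return C * scale[:, None]


def _penalized_descent(
    C0, anchors, free, p, d, A, B, lam, w_free,
    max_iter=300, tol=1e-8,
):
    """Proximal gradient with backtracking on the free-row block."""
    C = C0.copy()
    G = _build_G(C, anchors, free, p, d)
    g, grad = _span_value_grad(G, A, B)
    pen = lam * float(w_free @ np.linalg.norm(C, axis=1)) if len(free) else 0.0
    F = g + pen
    step = 1.0
    for _ in range(max_iter):
        if len(free) == 0:
            break
        gC = grad[free]
        t = step
        accepted = False
        for _ in range(40):
            C_new = _prox_rows(C - t * gC, t * lam * w_free)
            G_new = _build_G(C_new, anchors, free, p, d)
            g_new, grad_new = _span_value_grad(G_new, A, B)
            if np.isfinite(g_new):
                diff = C_new - C
                quad = g + float(np.sum(gC * diff)) + float(
                    np.sum(diff * diff)
                ) / (2.0 * t)
                if g_new <= quad + 1e-12:
                    accepted = True
                    break
            t *= 0.5
        if not accepted:
            break
        pen_new = lam * float(w_free @ np.linalg.norm(C_new, axis=1))
        F_new = g_new + pen_new
        rel = abs(F - F_new) / max(1.0, abs(F))
        C, g, grad, F = C_new, g_new, grad_new, F_new
        step = min(t * 2.0, 1.0)
        if rel < tol:
            break
    return C, F


def fit_sparse_envelope(
    moments: ConditionalMoments,
    d: int,
    config: SparseConfig | None = None,
    seed: int = 0,
    pilot: EnvelopeBasis | None = None,
    surrogates: dict | None = None,
    n_starts: int = 5,
    C0: np.ndarray | None = None,
    return_C: bool = False,
):
    """Minimize the penalized envelope objective; returns basis + pattern.

    Rows of the solution with norm below ``HARD_ZERO`` are set exactly to
    zero; the basis is re-orthonormalized on its nonzero rows so that
    Gamma = (Gamma_A', 0')' with Gamma_A' Gamma_A = I_d.  With lam = 0 the
    result coincides with :func:`fit_envelope` up to canonicalization.
    """
    p = moments.p
    if not 1 <= d <= p:
        raise ValueError(f"d must be in [1, {p}] for the sparse fit, got {d}")
    if pilot is None:
        pilot = fit_envelope(moments, d, n_starts=n_starts, seed=seed,
                             surrogates=surrogates)
    if config is None:
        config = adaptive_weights(pilot)
    if config.weights is None:
        config = adaptive_weights(pilot, config.weight_exponent)
        config.lam = config.lam if config.lam else 0.0

    A, B, const = _objective_matrices(moments, surrogates)
    anchors, free = _anchor_split(pilot, np.diag(moments.S_M_given_XZ))
    if C0 is None and config.warm_C is not None and config.warm_C.shape == (
        len(free), d
    ):
        C0 = config.warm_C
    if C0 is None:
        G_anchor = pilot.Gamma[anchors]
        try:
            C0 = pilot.Gamma[free] @ np.linalg.inv(G_anchor)
        except np.linalg.LinAlgError:
            C0 = np.linalg.lstsq(
                G_anchor.T, pilot.Gamma[free].T, rcond=None
            )[0].T

    w_free = config.weights[free] if len(free) else np.empty(0)
    C, _ = _penalized_descent(
        C0, anchors, free, p, d, A, B, config.lam, w_free
    )

    row_norms = np.linalg.norm(C, axis=1) if len(free) else np.empty(0)
    keep_free = free[row_norms > HARD_ZERO] if len(free) else free
    selected = np.union1d(anchors, keep_free)
    if len(selected) < d:
        raise OverShrinkageError(
            f"only {len(selected)} mediators survive at lambda={config.lam}; "
            "need at least d; use a smaller lambda"
        )
    G = _build_G(C, anchors, free, p, d)
    G[np.setdiff1d(np.arange(p), selected)] = 0.0

    Gamma = np.zeros((p, d))
    Gamma[selected] = np.linalg.qr(G[selected])[0]
    Gamma = canonicalize(Gamma, moments.S_M_given_XZ)
    Gamma[np.setdiff1d(np.arange(p), selected)] = 0.0  # exact zeros survive

    basis = EnvelopeBasis(Gamma, complete_basis(Gamma), d)
    basis.objective = envelope_objective(basis, moments, surrogates)
    pattern = SparsityPattern(
        selected, np.setdiff1d(np.arange(p), selected), p
    )
    if return_C:
        return basis, pattern, C
    return basis, pattern


def default_lambda_grid(
    moments: ConditionalMoments,
    d: int,
    config: SparseConfig,
    pilot: EnvelopeBasis,
    surrogates: dict | None = None,
    n_grid: int | None = None,
) -> np.ndarray:
    """Decreasing log-spaced grid from a data-driven lambda_max.

    lambda_max is the smallest penalty at which the gradient of the smooth
    part at the all-zero free block is dominated row-wise by the penalty.
    """
    A, B, _ = _objective_matrices(moments, surrogates)
    anchors, free = _anchor_split(pilot, np.diag(moments.S_M_given_XZ))
    p = moments.p
    if len(free) == 0:
        return np.array([0.0])
    G = _build_G(np.zeros((len(free), d)), anchors, free, p, d)
    _, grad = _span_value_grad(G, A, B)
    if grad is None:
        lam_max = 1.0
    else:
        norms = np.linalg.norm(grad[free], axis=1)
        lam_max = float(np.max(norms / config.weights[free]))
    lam_max = max(lam_max, 1e-8)
    ng = n_grid or config.n_grid
    return np.geomspace(lam_max, lam_max * 1e-4, ng)


def _bic(objective_value, logdet_S, n, d, p_sel, r, p, gamma=1.0):
    """Extended BIC for the penalized envelope fit.

    -2 x maximized Gaussian log-likelihood plus an effective-parameter
    penalty (log n + 2 gamma log p per parameter, the high-dimensional BIC
    correction) with d(p_A - d) + d r parameters when p_A rows are active.
    """
    loglik = -0.5 * n * (objective_value + logdet_S)
    n_par = d * (p_sel - d) + d * r
    return -2.0 * loglik + (np.log(n) + 2.0 * gamma * np.log(p)) * n_par


def select_lambda(
    moments: ConditionalMoments,
    d: int,
    config: SparseConfig | None = None,
    criterion: str = "bic",
    seed: int = 0,
    pilot: EnvelopeBasis | None = None,
    surrogates: dict | None = None,
    data: MediationDataset | None = None,
    folds: int = 5,
    ebic_gamma: float = 1.0,
) -> SparseConfig:
    """Pick lambda on a decreasing grid by BIC (default) or K-fold CV.

    BIC uses -2 x (maximized envelope log-likelihood) + log(n) x effective
    parameter count with p_A active rows.  CV uses held-out outcome
    prediction error and requires ``data``.
    """
    if criterion not in ("bic", "cv"):
        raise ValueError("criterion must be 'bic' or 'cv'")
    if pilot is None:
        pilot = fit_envelope(moments, d, seed=seed, surrogates=surrogates)
    if config is None:
        config = adaptive_weights(pilot)
    grid = config.lam_grid
    if grid is None:
        grid = default_lambda_grid(moments, d, config, pilot, surrogates)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if grid.size > 1 and np.any(np.diff(grid) > 0):
        grid = np.sort(grid)[::-1]

    if surrogates and "S_M_given_XZ" in surrogates:
        _, logdet_S = np.linalg.slogdet(surrogates["S_M_given_XZ"])
    else:
        _, logdet_S = np.linalg.slogdet(moments.S_M_given_XZ)

    config.criterion_path = []
    if criterion == "bic":
        scores = np.full(grid.size, np.inf)
        objs = np.full(grid.size, np.inf)
        p_sels = np.zeros(grid.size, dtype=int)
        C_path = [None] * grid.size
        C_warm = None  # thread the solution along the decreasing path
        for i, lam in enumerate(grid):
            cfg = SparseConfig(lam=float(lam), weights=config.weights,
                               weight_exponent=config.weight_exponent)
            try:
                basis, pattern, C_warm = fit_sparse_envelope(
                    moments, d, cfg, seed=seed, pilot=pilot,
                    surrogates=surrogates, C0=C_warm, return_C=True,
                )
            except OverShrinkageError:
                continue
            scores[i] = _bic(basis.objective, logdet_S, moments.n, d,
                             pattern.p_selected, moments.r, moments.p,
                             gamma=ebic_gamma)
            p_sels[i] = pattern.p_selected
            objs[i] = basis.objective
            C_path[i] = C_warm.copy()
    else:
        scores, p_sels = _cv_path(data, d, config, grid, folds, seed,
                                  surrogates)
    config.criterion_path = [
        (float(lam), float(s), int(ps))
        for lam, s, ps in zip(grid, scores, p_sels)
    ]
    if not np.any(np.isfinite(scores)):
        raise OverShrinkageError("no lambda on the grid is feasible")
    best = int(np.argmin(scores))
    config.lam = float(grid[best])
    config.lam_grid = grid
    if criterion == "bic" and C_path[best] is not None:
        config.warm_C = C_path[best]
    return config


def mediation_evidence(
    moments: ConditionalMoments, alpha: float = 1e-3
) -> tuple[float, float]:
    """Wilks likelihood-ratio evidence that the mediators predict the
    outcomes at all, i.e., a test of Y independent of M given (X, Z).

    Returns ``(statistic, critical)``: the Bartlett-corrected statistic
    (n - k - q - (p + r + 3)/2) log(|S_{Y|X,Z}| / |S_{Y|M,X,Z}|), referred
    to a chi-square with p*r degrees of freedom at level ``alpha``.  Its
    null distribution does not depend on the mediator covariance, so the
    check is immune to ill-conditioning of S_{M|X,Z}.  When the statistic
    falls below the critical value the no-mediation model (beta_M = 0) is
    the better-supported description.  Requires n > p + k + q + 1; callers
    should skip the test otherwise.
    """
    from scipy import stats

    n, p, r = moments.n, moments.p, moments.r
    k, q = moments.k, moments.q
    if n <= p + k + q + 1:
        return np.inf, 0.0
    Q, _ = np.linalg.qr(moments.R_M)
    R_adj = moments.R_Y - Q @ (Q.T @ moments.R_Y)
    Sigma = (R_adj.T @ moments.R_Y) / n
    _, ld0 = np.linalg.slogdet(moments.S_Y_given_XZ)
    _, ld1 = np.linalg.slogdet((Sigma + Sigma.T) / 2.0)
    bartlett = n - k - q - (p + r + 3) / 2.0
    stat = max(bartlett, 1.0) * (ld0 - ld1)
    critical = float(stats.chi2.ppf(1.0 - alpha, df=p * r))
    return float(stat), critical


def _cv_path(data, d, config, grid, folds, seed, surrogates):
    """Held-out outcome prediction error for every lambda on the grid.

    One pilot fit per fold; the lambda path is warm-started within a fold.
    """
    from .estimators import estimate_parameters
    from .data_moments import compute_moments

    if data is None:
        raise ValueError("criterion='cv' requires the raw dataset")
    n = data.n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, min(max(folds, 2), n))
    err = np.zeros(grid.size)
    feasible = np.ones(grid.size, dtype=bool)
    p_sels = np.zeros(grid.size, dtype=int)
    for test_idx in fold_ids:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train = MediationDataset(
            data.Y[mask], data.M[mask], data.X[mask], data.Z[mask]
        )
        mom = compute_moments(train)
        sur = None
        if surrogates is not None:
            from .highdim import spice_surrogates

            sur = spice_surrogates(mom)
        pilot_f = fit_envelope(mom, d, seed=seed, surrogates=sur)
        cfg_f = adaptive_weights(pilot_f, config.weight_exponent)
        C_warm = None
        for i, lam in enumerate(grid):
            cfg = SparseConfig(lam=float(lam), weights=cfg_f.weights,
                               weight_exponent=config.weight_exponent)
            try:
                basis, pattern, C_warm = fit_sparse_envelope(
                    mom, d, cfg, seed=seed, pilot=pilot_f,
                    surrogates=sur, C0=C_warm, return_C=True,
                )
            except OverShrinkageError:
                feasible[i] = False
                continue
            fit = estimate_parameters(mom, basis, pattern)
            Yhat = (
                fit.mu_Y
                + (data.M[test_idx] - fit.mu_M) @ fit.beta_M
                + (data.X[test_idx] - fit.mu_X) @ fit.beta_X
                + (data.Z[test_idx] - fit.mu_Z) @ fit.beta_Z
            )
            err[i] += float(np.sum((data.Y[test_idx] - Yhat) ** 2))
            p_sels[i] = pattern.p_selected
    err /= n * data.r
    err[~feasible] = np.inf
    return err, p_sels
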