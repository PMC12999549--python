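"""Envelope subspace estimation on the Grassmann manifold.

The predictor-envelope idea applied to mediation: the mediator conditional
covariance ``Sigma_{M|X,Z}`` decomposes into a *material* part (a d-dimensional
subspace spanned by an orthonormal ``Gamma`` that carries all outcome-relevant
mediator variation) and an *immaterial* complement spanned by ``Gamma0``.
For a fixed dimension d the maximum-likelihood subspace minimizes

    f(Gamma) = log|S_{Y|X,Z}| + log|Gamma' S_{M|X,Z}^{-1} Gamma|
                                + log|Gamma' S_{M|Y,X,Z} Gamma|

over the Grassmannian of d-planes in R^p.  The objective depends on Gamma
only through its span, so the minimizer is a subspace; the returned basis is
canonicalized for reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_moments import ConditionalMoments, MediationDataset, compute_moments


class NumericalDegeneracyError(ArithmeticError):
    """An inner determinant of the envelope objective is not positive."""


@dataclass
class EnvelopeBasis:
    """Orthonormal basis pair for the envelope and its complement.

    ``Gamma`` is p x d with orthonormal columns, ``Gamma0`` is p x (p - d).
    d = 0 gives an empty ``Gamma`` (no mediation subspace); d = p gives an
    empty ``Gamma0``.
    """

    Gamma: np.ndarray
    Gamma0: np.ndarray
    d: int
    converged: bool = True
    n_iter: int = 0
    objective: float = np.nan

    def __post_init__(self):
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        self.Gamma0 = np.atleast_2d(np.asarray(self.Gamma0, dtype=float))
        p = max(self.Gamma.shape[0], self.Gamma0.shape[0])
        if self.Gamma.size == 0:
            self.Gamma = self.Gamma.reshape(p, 0)
        if self.Gamma0.size == 0:
            self.Gamma0 = self.Gamma0.reshape(p, 0)

    @property
    def p(self) -> int:
        return self.Gamma.shape[0] if self.Gamma.size else self.Gamma0.shape[0]

    def check(self, atol: float = 1e-10) -> None:
        d, p = self.d, self.p
        assert self.Gamma.shape == (p, d)
        assert self.Gamma0.shape == (p, p - d)
        if d:
            assert np.allclose(self.Gamma.T @ self.Gamma, np.eye(d), atol=atol)
        if p - d:
            assert np.allclose(
                self.Gamma0.T @ self.Gamma0, np.eye(p - d), atol=atol
            )
        if d and p - d:
            assert np.allclose(self.Gamma.T @ self.Gamma0, 0.0, atol=atol)


def complete_basis(Gamma: np.ndarray) -> np.ndarray:
    """Orthonormal completion of a p x d orthonormal matrix to a full basis."""
    p, d = Gamma.shape
    if d == 0:
        return np.eye(p)
    if d == p:
        return np.empty((p, 0))
    # null space of Gamma' via full QR
    Q, _ = np.linalg.qr(Gamma, mode="complete")
    return Q[:, d:]


def _objective_matrices(
    moments: ConditionalMoments, surrogates: dict | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (A, B, const) with A ~ S_{M|X,Z}^{-1}, B ~ S_{M|Y,X,Z}.

    ``surrogates`` may supply positive-definite replacements
    {"inv_S_M_given_XZ": ..., "S_M_given_YXZ": ...} for the p > n path.
    """
    sign, logdet_Y = np.linalg.slogdet(moments.S_Y_given_XZ)
    if sign <= 0:
        raise NumericalDegeneracyError("S_{Y|X,Z} has non-positive determinant")
    if surrogates and "inv_S_M_given_XZ" in surrogates:
        A = surrogates["inv_S_M_given_XZ"]
    else:
        A = np.linalg.inv(moments.S_M_given_XZ)
        A = (A + A.T) / 2.0
    if surrogates and "S_M_given_YXZ" in surrogates:
        B = surrogates["S_M_given_YXZ"]
    else:
        B = moments.S_M_given_YXZ
    return A, B, logdet_Y


def _logdet_quadratic(Gamma: np.ndarray, Mat: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(Gamma.T @ Mat @ Gamma)
    if sign <= 0:
        raise NumericalDegeneracyError(
            "inner determinant of the envelope objective is not positive"
        )
    return val


def envelope_objective(
    basis: EnvelopeBasis,
    moments: ConditionalMoments,
    surrogates: dict | None = None,
) -> float:
    """Evaluate the envelope objective at a basis (invariant to rotation)."""
    A, B, const = _objective_matrices(moments, surrogates)
    if basis.d == 0:
        return const
    return const + _logdet_quadratic(basis.Gamma, A) + _logdet_quadratic(
        basis.Gamma, B
    )


def _smooth_value_grad(Gamma, A, B):
    """Value and Euclidean gradient of logdet(G'AG) + logdet(G'BG)."""
    GA = A @ Gamma
    GB = B @ Gamma
    MA = Gamma.T @ GA
    MB = Gamma.T @ GB
    sa, la = np.linalg.slogdet(MA)
    sb, lb = np.linalg.slogdet(MB)
    if sa <= 0 or sb <= 0:
        return np.inf, None
    grad = 2.0 * GA @ np.linalg.inv(MA) + 2.0 * GB @ np.linalg.inv(MB)
    return la + lb, grad


def _grassmann_descent(
    Gamma0: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool, int]:
    """Projected-gradient descent with QR retraction and Armijo backtracking."""
    Gamma = np.linalg.qr(Gamma0)[0]
    f, grad = _smooth_value_grad(Gamma, A, B)
    if not np.isfinite(f):
        return Gamma, np.inf, False, 0
    step = 1.0
    it = 0
    for it in range(1, max_iter + 1):
        rgrad = grad - Gamma @ (Gamma.T @ grad)
        gnorm2 = float(np.sum(rgrad * rgrad))
        if gnorm2 < 1e-20:
            return Gamma, f, True, it
        # Armijo backtracking on the retracted iterate
        t = step
        accepted = False
        for _ in range(40):
            cand = np.linalg.qr(Gamma - t * rgrad)[0]
            f_new, grad_new = _smooth_value_grad(cand, A, B)
            if np.isfinite(f_new) and f_new <= f - 1e-4 * t * gnorm2:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            return Gamma, f, True, it  # no descent direction left
        rel = abs(f - f_new) / max(1.0, abs(f))
        Gamma, f, grad = cand, f_new, grad_new
        step = min(t * 2.0, 1.0)
        if rel < tol:
            return Gamma, f, True, it
    return Gamma, f, False, max_iter


def _phi_1d(w, A, B):
    """One-direction objective log(w'Aw) + log(w'Bw) - 2 log(w'w)."""
    wa = float(w @ A @ w)
    wb = float(w @ B @ w)
    ww = float(w @ w)
    if wa <= 0 or wb <= 0 or ww <= 0:
        return np.inf
    return np.log(wa) + np.log(wb) - 2.0 * np.log(ww)


def _solve_1d(A, B, starts, max_iter=200, tol=1e-10):
    """Minimize the one-direction objective by an eigenvector fixed point.

    Stationarity of phi requires (A/(w'Aw) + B/(w'Bw)) w = 2w for unit w;
    iterating 'w <- smallest eigenvector of the current weighted sum' is the
    standard self-consistent scheme for envelope objectives and is robust to
    ill-conditioning where plain gradient descent stalls.  The best iterate
    across starts (by phi) is returned.
    """
    best_w, best_phi = None, np.inf
    for w0 in starts:
        w = w0 / np.linalg.norm(w0)
        prev = _phi_1d(w, A, B)
        if not np.isfinite(prev):
            continue
        track_w, track_phi = w, prev
        for _ in range(max_iter):
            H = A / float(w @ A @ w) + B / float(w @ B @ w)
            vals, vecs = np.linalg.eigh((H + H.T) / 2.0)
            w_new = vecs[:, 0]
            cur = _phi_1d(w_new, A, B)
            if cur < track_phi:
                track_w, track_phi = w_new, cur
            if abs(prev - cur) < tol * max(1.0, abs(prev)):
                w = w_new
                break
            w, prev = w_new, cur
        if track_phi < best_phi:
            best_w, best_phi = track_w, track_phi
    return best_w, best_phi


def _schur_compress(Mat, G, P):
    """P' (Mat - Mat G (G'Mat G)^{-1} G'Mat) P, PD on the complement."""
    if G.shape[1] == 0:
        return P.T @ Mat @ P
    MG = Mat @ G
    Sc = Mat - MG @ np.linalg.solve(G.T @ MG, MG.T)
    out = P.T @ Sc @ P
    return (out + out.T) / 2.0


def _sequential_basis(A, B, moments, d, seed):
    """Greedy one-direction-at-a-time envelope construction.

    Each new direction exactly minimizes the increment of the joint
    objective given the directions found so far (Schur-complement
    compression onto the orthocomplement).
    """
    p = A.shape[0]
    rng = np.random.default_rng(seed)
    G = np.empty((p, 0))
    for _ in range(d):
        P = complete_basis(G) if G.shape[1] else np.eye(p)
        Aj = _schur_compress(A, G, P)
        Bj = _schur_compress(B, G, P)
        # candidate starts in the compressed space
        S_c = P.T @ moments.S_M_given_XZ @ P
        pool = [np.linalg.eigh(Aj)[1][:, 0], np.linalg.eigh(Bj)[1][:, 0],
                np.linalg.eigh((S_c + S_c.T) / 2)[1][:, -1]]
        bols = P.T @ np.linalg.solve(
            moments.S_M_given_XZ, moments.S_YM_given_XZ.T
        )
        U = np.linalg.svd(P.T @ moments.S_YM_given_XZ.T,
                          full_matrices=False)[0]
        pool.extend(list(U.T[: min(3, U.shape[1])]))
        if bols.shape[1]:
            pool.append(bols[:, 0])
        pool.append(rng.standard_normal(P.shape[1]))
        v, _ = _solve_1d(Aj, Bj, pool)
        if v is None:
            v = rng.standard_normal(P.shape[1])
            v /= np.linalg.norm(v)
        w = P @ v
        G = np.linalg.qr(np.hstack([G, w[:, None]]))[0]
    return G


def canonicalize(Gamma: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Rotate a basis to a reproducible representative of its span.

    Columns are rotated to the eigenvectors of ``Gamma' S Gamma`` (decreasing
    eigenvalue order) and each column's sign is fixed so its first entry of
    largest magnitude is positive.
    """
    d = Gamma.shape[1]
    if d == 0:
        return Gamma
    Msub = Gamma.T @ S @ Gamma
    vals, vecs = np.linalg.eigh((Msub + Msub.T) / 2.0)
    order = np.argsort(vals)[::-1]
    G = Gamma @ vecs[:, order]
    for j in range(d):
        i = int(np.argmax(np.abs(G[:, j])))
        if G[i, j] < 0:
            G[:, j] = -G[:, j]
    return G


def _starting_values(
    A: np.ndarray,
    B: np.ndarray,
    moments: ConditionalMoments,
    d: int,
    n_starts: int,
    seed: int,
) -> list[np.ndarray]:
    """Deterministic + seeded random starting bases.

    (a) span of the OLS coefficient of Y on M (padded with leading
    eigenvectors of the 'signal' matrix S_{M|X,Z} - S_{M|Y,X,Z});
    (b) leading eigenvectors of the signal matrix alone;
    (c) seeded Gaussian starts.
    """
    p = moments.p
    S = moments.S_M_given_XZ
    signal = (S - B + (S - B).T) / 2.0
    vals, vecs = np.linalg.eigh(signal)
    eig_top = vecs[:, np.argsort(vals)[::-1]]
    beta_ols = np.linalg.solve(S, moments.S_YM_given_XZ.T)  # p x r

    # pool of unit candidate directions, ranked by the one-direction
    # objective phi(v) = log(v'Av) + log(v'Bv); robust to ill-conditioned S
    pool = [np.linalg.eigh(S)[1], np.linalg.eigh((B + B.T) / 2.0)[1],
            eig_top]
    norms = np.linalg.norm(beta_ols, axis=0)
    keep = norms > 1e-12 * max(1.0, norms.max())
    if keep.any():
        pool.append(beta_ols[:, keep] / norms[keep])
    V = np.hstack(pool)
    with np.errstate(all="ignore"):
        phi = np.log(np.einsum("ij,ij->j", V, A @ V)) + np.log(
            np.einsum("ij,ij->j", V, B @ V)
        )
    phi[~np.isfinite(phi)] = np.inf
    ranked = V[:, np.argsort(phi)]

    starts: list[np.ndarray] = []
    # greedy: top-ranked directions, orthonormalized, padded if collinear
    starts.append(np.linalg.qr(np.hstack([ranked[:, : 3 * d], eig_top]))[0][:, :d])
    starts.append(ranked[:, :d] if d > 1 else ranked[:, :1])
    cand = np.hstack([beta_ols, eig_top])[:, : max(d, 1)]
    starts.append(np.linalg.qr(np.hstack([cand, eig_top]))[0][:, :d])
    starts.append(eig_top[:, :d])
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - len(starts))):
        starts.append(rng.standard_normal((p, d)))
    return starts[: max(n_starts, 2)]


def fit_envelope(
    moments: ConditionalMoments,
    d: int,
    n_starts: int = 5,
    seed: int = 0,
    surrogates: dict | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> EnvelopeBasis:
    """Minimize the envelope objective over d-planes, multi-start.

    d = 0 returns the empty basis (no mediation subspace); d = p returns the
    identity basis, under which all downstream estimates reduce to OLS.
    """
    p = moments.p
    if not 0 <= d <= p:
        raise ValueError(f"d must be in [0, {p}], got {d}")
    if d == 0:
        basis = EnvelopeBasis(np.empty((p, 0)), np.eye(p), 0)
        basis.objective = envelope_objective(basis, moments, surrogates)
        return basis
    if d == p:
        basis = EnvelopeBasis(np.eye(p), np.empty((p, 0)), p)
        basis.objective = envelope_objective(basis, moments, surrogates)
        return basis

    A, B, const = _objective_matrices(moments, surrogates)
    starts = _starting_values(A, B, moments, d, n_starts, seed)
    starts.insert(0, _sequential_basis(A, B, moments, d, seed))
    best = (None, np.inf, False, 0)
    for G0 in starts:
        G, f, ok, it = _grassmann_descent(G0, A, B, max_iter=max_iter, tol=tol)
        if f < best[1]:
            best = (G, f, ok, it)
    if best[0] is None:
        raise NumericalDegeneracyError("all envelope starts failed")
    G = canonicalize(best[0], moments.S_M_given_XZ)
    basis = EnvelopeBasis(G, complete_basis(G), d,
                          converged=best[2], n_iter=best[3])
    if not best[2]:
        warnings.warn(
            "envelope optimization did not converge; best iterate returned",
            RuntimeWarning,
        )
    basis.objective = const + best[1]
    return basis


def select_dimension(
    data: MediationDataset,
    d_max: int | None = None,
    folds: int = 5,
    seed: int = 0,
    n_starts: int = 3,
) -> int:
    """Choose the envelope dimension by K-fold cross-validated prediction.

    For each candidate d in {0, ..., d_max} the model is fit on the training
    folds and Y is predicted from (M, X, Z) on the held-out fold; the d with
    the smallest mean squared prediction error wins, ties toward smaller d.
    """
    from .estimators import estimate_parameters  # local import: no cycle

    if folds < 2:
        raise ValueError("folds must be >= 2")
    n, p = data.n, data.p
    folds = min(folds, n)
    if d_max is None:
        d_max = p
    d_max = min(d_max, p)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_ids = np.array_split(perm, folds)

    cv_err = np.zeros(d_max + 1)
    for test_idx in fold_ids:
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train = MediationDataset(
            data.Y[mask], data.M[mask], data.X[mask], data.Z[mask]
        )
        mom = compute_moments(train)
        for d in range(d_max + 1):
            basis = fit_envelope(mom, d, n_starts=n_starts, seed=seed)
            fit = estimate_parameters(mom, basis)
            Yhat = (
                fit.mu_Y
                + (data.M[test_idx] - fit.mu_M) @ fit.beta_M
                + (data.X[test_idx] - fit.mu_X) @ fit.beta_X
                + (data.Z[test_idx] - fit.mu_Z) @ fit.beta_Z
            )
            cv_err[d] += float(np.sum((data.Y[test_idx] - Yhat) ** 2))
    cv_err /= n * data.r

    spread = cv_err.max() - cv_err.min()
    if spread < 1e-3 * max(1.0, abs(cv_err.mean())):
        warnings.warn(
            "flat cross-validation profile across d; selection is weak",
            RuntimeWarning,
        )
    return int(np.argmin(cv_err))
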