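"""Observed data containers and conditional sample moments.

The mediation model regresses a multivariate outcome ``Y`` (n x r) on
mediators ``M`` (n x p), exposures ``X`` (n x k) and optional confounders
``Z`` (n x q).  Every downstream objective and closed-form estimator is a
function of centered residuals and conditional covariance blocks computed
here.

All covariances use the 1/n normalization (maximum-likelihood convention),
not 1/(n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SingularDesignError(ValueError):
    """Centered (X, Z) design is rank deficient."""


class SampleSizeError(ValueError):
    """Too few observations for the requested decomposition."""


def _as_block(a, name: str, n_expected: int | None) -> np.ndarray:
    if a is None:
        a = np.empty((0 if n_expected is None else n_expected, 0))
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")
    return a


@dataclass
class MediationDataset:
    """Aligned (Y, M, X, Z) blocks sharing the sample index.

    Parameters
    ----------
    Y : (n, r) outcome matrix
    M : (n, p) mediator matrix
    X : (n, k) exposure matrix (binary coding allowed)
    Z : (n, q) confounder matrix; ``None`` or zero columns means no confounders
    column_names : optional dict mapping block letter -> list of names
    """

    Y: np.ndarray
    M: np.ndarray
    X: np.ndarray
    Z: np.ndarray | None = None
    column_names: dict | None = None

    def __post_init__(self):
        self.Y = _as_block(self.Y, "Y", None)
        n = self.Y.shape[0]
        self.M = _as_block(self.M, "M", n)
        self.X = _as_block(self.X, "X", n)
        self.Z = _as_block(self.Z, "Z", n)
        for name, blk in (("M", self.M), ("X", self.X), ("Z", self.Z)):
            if blk.shape[0] != n:
                raise ValueError(
                    f"block {name} has {blk.shape[0]} rows, expected {n}"
                )
        if n < 2:
            raise SampleSizeError(f"need n >= 2 observations, got {n}")
        if self.column_names:
            for key, names in self.column_names.items():
                if len(names) != len(set(names)):
                    raise ValueError(f"duplicate column names in block {key}")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def r(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        return self.M.shape[1]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def mediator_names(self) -> list[str]:
        if self.column_names and "M" in self.column_names:
            return list(self.column_names["M"])
        return [f"M{i + 1}" for i in range(self.p)]


@dataclass
class ConditionalMoments:
    """Centered residuals and every conditional covariance block.

    Residuals ``R_M`` and ``R_Y`` are the centered mediator/outcome matrices
    projected off the column space of the centered (X, Z) design.  Blocks are
    named ``S_<a>_given_<b>`` for the sample conditional (co)variance of block
    a given block b, always with 1/n normalization.
    """

    n: int
    mu_Y: np.ndarray
    mu_M: np.ndarray
    mu_X: np.ndarray
    mu_Z: np.ndarray
    R_M: np.ndarray  # (n, p) residuals of M | X, Z
    R_Y: np.ndarray  # (n, r) residuals of Y | X, Z
    Mc: np.ndarray
    Yc: np.ndarray
    Wc: np.ndarray  # centered (X, Z), X first
    k: int
    q: int
    # conditional blocks (filled by conditional_covariances)
    S_M_given_XZ: np.ndarray | None = None
    S_Y_given_XZ: np.ndarray | None = None
    S_YM_given_XZ: np.ndarray | None = None  # (r, p) cross-cov of (Y, M) | X,Z
    S_M_given_YXZ: np.ndarray | None = None
    S_X_given_Z: np.ndarray | None = None
    S_Z_given_X: np.ndarray | None = None
    S_XM_given_Z: np.ndarray | None = None  # (k, p)
    S_ZM_given_X: np.ndarray | None = None  # (q, p)
    S_XY_given_Z: np.ndarray | None = None  # (k, r)
    S_ZY_given_X: np.ndarray | None = None  # (q, r)
    # marginal blocks used by the dual Eq-(8) expressions
    raw: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.R_M.shape[1]

    @property
    def r(self) -> int:
        return self.R_Y.shape[1]


def center_and_residualize(data: MediationDataset) -> ConditionalMoments:
    """Center all blocks and project M, Y off the centered (X, Z) design.

    Uses an orthogonal (QR) decomposition of the centered design for numerical
    stability.  With k = q = 0 the residuals are simply the centered matrices.

    Raises
    ------
    SingularDesignError
        if the centered (X, Z) design is rank deficient.
    SampleSizeError
        if n <= k + q + 1.
    """
    n, k, q = data.n, data.k, data.q
    if n <= k + q + 1:
        raise SampleSizeError(
            f"n={n} is too small for k+q={k + q} covariates; need n > k+q+1"
        )
    mu_Y = data.Y.mean(axis=0)
    mu_M = data.M.mean(axis=0)
    mu_X = data.X.mean(axis=0)
    mu_Z = data.Z.mean(axis=0)
    Yc = data.Y - mu_Y
    Mc = data.M - mu_M
    Wc = np.hstack([data.X - mu_X, data.Z - mu_Z])  # X first

    if Wc.shape[1] == 0:
        R_M, R_Y = Mc.copy(), Yc.copy()
    else:
        Q, R = np.linalg.qr(Wc)
        diag = np.abs(np.diag(R))
        tol = max(Wc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
        bad = np.where(diag <= tol)[0]
        if bad.size:
            labels = []
            for j in bad:
                labels.append(f"X[{j}]" if j < k else f"Z[{j - k}]")
            raise SingularDesignError(
                "centered (X, Z) design is rank deficient; offending columns: "
                + ", ".join(labels)
            )
        R_M = Mc - Q @ (Q.T @ Mc)
        R_Y = Yc - Q @ (Q.T @ Yc)

    return ConditionalMoments(
        n=n, mu_Y=mu_Y, mu_M=mu_M, mu_X=mu_X, mu_Z=mu_Z,
        R_M=R_M, R_Y=R_Y, Mc=Mc, Yc=Yc, Wc=Wc, k=k, q=q,
    )


def _residual_on(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Residual of A after projecting off span(B) (both centered)."""
    if B.shape[1] == 0:
        return A
    Q, _ = np.linalg.qr(B)
    return A - Q @ (Q.T @ A)


def conditional_covariances(moments: ConditionalMoments) -> ConditionalMoments:
    """Fill every conditional covariance block (1/n normalization).

    ``S_M_given_YXZ`` is computed exactly by the Schur-complement identity
    S_{M|Y,X,Z} = S_{M|X,Z} - S_{(Y,M)|X,Z}^T S_{Y|X,Z}^{-1} S_{(Y,M)|X,Z}.
    """
    n = moments.n
    k, q = moments.k, moments.q
    Xc = moments.Wc[:, :k]
    Zc = moments.Wc[:, k:]

    m = moments
    m.S_M_given_XZ = m.R_M.T @ m.R_M / n
    m.S_Y_given_XZ = m.R_Y.T @ m.R_Y / n
    m.S_YM_given_XZ = m.R_Y.T @ m.R_M / n

    S_Y = m.S_Y_given_XZ
    if m.r > 0:
        try:
            sol = np.linalg.solve(S_Y, m.S_YM_given_XZ)
        except np.linalg.LinAlgError as exc:
            raise SingularDesignError(
                "S_{Y|X,Z} is singular on the low-dimensional path; "
                "use the high-dimensional (SPICE) path instead"
            ) from exc
        m.S_M_given_YXZ = m.S_M_given_XZ - m.S_YM_given_XZ.T @ sol
        m.S_M_given_YXZ = (m.S_M_given_YXZ + m.S_M_given_YXZ.T) / 2.0
    else:
        m.S_M_given_YXZ = m.S_M_given_XZ.copy()

    RX_Z = _residual_on(Xc, Zc)  # X residualized on Z
    RZ_X = _residual_on(Zc, Xc)
    m.S_X_given_Z = RX_Z.T @ RX_Z / n
    m.S_Z_given_X = RZ_X.T @ RZ_X / n
    m.S_XM_given_Z = RX_Z.T @ m.Mc / n
    m.S_ZM_given_X = RZ_X.T @ m.Mc / n
    m.S_XY_given_Z = RX_Z.T @ m.Yc / n
    m.S_ZY_given_X = RZ_X.T @ m.Yc / n

    # marginal blocks (for the dual printed expressions and diagnostics)
    m.raw = {
        "S_X": Xc.T @ Xc / n,
        "S_Z": Zc.T @ Zc / n,
        "S_XZ": Xc.T @ Zc / n,
        "S_XM": Xc.T @ m.Mc / n,
        "S_ZM": Zc.T @ m.Mc / n,
        "S_XY": Xc.T @ m.Yc / n,
        "S_ZY": Zc.T @ m.Yc / n,
    }
    return m


def compute_moments(data: MediationDataset) -> ConditionalMoments:
    """Convenience: center, residualize and fill all covariance blocks."""
    return conditional_covariances(center_and_residualize(data))
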