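"""Inference for the direct and indirect effects.

Two routes are provided.  The asymptotic route plugs the model estimates into
the closed-form covariances of sqrt(n) vec(beta_X_hat) and
sqrt(n) vec((gamma_X beta_M)_hat) implied by the envelope parameterization,
yielding joint Wald chi-square tests.  The nonparametric route resamples
observations with replacement, refits the full pipeline per resample, and
reports percentile confidence intervals and sign-based p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_moments import MediationDataset, compute_moments
from .envelope_core import envelope_objective, fit_envelope
from .estimators import ESPLSMFit, estimate_parameters
from .sparse_envelope import (
    SparseConfig,
    SparsityPattern,
    adaptive_weights,
    fit_sparse_envelope,
    mediation_evidence,
    select_lambda,
)

PINV_RTOL = 1e-8


@dataclass
class AsymptoticCov:
    """Asymptotic covariances of the scaled effect estimators."""

    V_direct: np.ndarray  # (kr, kr)
    V_indirect: np.ndarray  # (kr, kr)
    S_X_given_Z: np.ndarray  # (k, k)


@dataclass
class TestResult:
    """Outcome of a Wald or bootstrap test for one effect matrix."""

    effect_name: str
    estimate: np.ndarray  # (k, r)
    statistic: float
    df: int
    p_value: float
    method: str
    p_values: np.ndarray | None = None  # per-entry (k, r), bootstrap
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    B: int = 0
    seed: int | None = None
    n_failed: int = 0


def asymptotic_cov_params(
    Sigma_Y: np.ndarray,
    Gamma: np.ndarray,
    Gamma0: np.ndarray,
    Omega: np.ndarray,
    Omega0: np.ndarray,
    eta: np.ndarray,
    gamma_X: np.ndarray,
    S_X_given_Z: np.ndarray,
) -> AsymptoticCov:
    """Effect covariances from explicit (estimated or true) parameters.

    The shared middle term involves the inverse of
    T = eta Sigma_Y^{-1} eta' (x) Omega0 + Omega (x) Omega0^{-1}
        + Omega^{-1} (x) Omega0 - 2 I,
    which is PSD but can be singular; the Moore-Penrose inverse is used.
    """
    k = gamma_X.shape[0]
    r = Sigma_Y.shape[0]
    d = Gamma.shape[1] if Gamma.size else 0
    p0 = Gamma0.shape[1] if Gamma0.size else 0

    SXZ_inv = np.linalg.inv(S_X_given_Z) if k else np.zeros((0, 0))

    if d:
        core = gamma_X @ Gamma @ np.linalg.solve(Omega, Gamma.T @ gamma_X.T)
        core = (core + core.T) / 2.0
    else:
        core = np.zeros((k, k))

    if d and p0:
        T = (
            np.kron(eta @ np.linalg.solve(Sigma_Y, eta.T), Omega0)
            + np.kron(Omega, np.linalg.inv(Omega0))
            + np.kron(np.linalg.inv(Omega), Omega0)
            - 2.0 * np.eye(d * p0)
        )
        T_pinv = np.linalg.pinv((T + T.T) / 2.0, rcond=PINV_RTOL)
        L = np.kron(eta.T, gamma_X @ Gamma0)  # (rk, d*p0)
        middle = L @ T_pinv @ L.T
        middle = (middle + middle.T) / 2.0
    else:
        middle = np.zeros((r * k, r * k))

    V_direct = np.kron(Sigma_Y, core + SXZ_inv) + middle
    if d:
        V_indirect = (
            np.kron(Sigma_Y, core)
            + middle
            + np.kron(eta.T @ Omega @ eta, SXZ_inv)
        )
    else:
        V_indirect = np.zeros((r * k, r * k))

    V_direct = (V_direct + V_direct.T) / 2.0
    V_indirect = (V_indirect + V_indirect.T) / 2.0
    if not (np.all(np.isfinite(V_direct)) and np.all(np.isfinite(V_indirect))):
        raise ArithmeticError(
            "non-finite entries in the asymptotic covariance; "
            "check conditioning of Omega, Omega0 and S_{X|Z}"
        )
    return AsymptoticCov(V_direct, V_indirect, S_X_given_Z)


def asymptotic_cov(fit: ESPLSMFit) -> AsymptoticCov:
    """Plug-in asymptotic covariances from a fitted model (low-dim path)."""
    return asymptotic_cov_params(
        fit.Sigma_Y_given_MXZ, fit.basis.Gamma, fit.basis.Gamma0,
        fit.Omega, fit.Omega0, fit.eta, fit.gamma_X, fit.S_X_given_Z,
    )


def wald_test(
    effect: np.ndarray, V: np.ndarray, n: int,
    effect_name: str = "effect",
) -> TestResult:
    """Joint Wald chi-square test of H0: effect = 0.

    statistic = n vec(effect)' V^dagger vec(effect); df = rank(V).
    """
    effect = np.atleast_2d(np.asarray(effect, dtype=float))
    v = effect.flatten(order="F")
    V = (V + V.T) / 2.0
    rank = int(np.linalg.matrix_rank(V, tol=PINV_RTOL * max(
        1.0, float(np.linalg.norm(V, 2)))))
    if rank == 0:
        stat, p = 0.0, 1.0
    else:
        stat = float(n * v @ np.linalg.pinv(V, rcond=PINV_RTOL) @ v)
        stat = max(stat, 0.0)
        p = float(stats.chi2.sf(stat, df=rank)) if stat > 0 else 1.0
    return TestResult(
        effect_name=effect_name, estimate=effect, statistic=stat,
        df=rank, p_value=p, method="wald",
    )


def fit_esplsm(
    data: MediationDataset,
    d: int,
    config: SparseConfig | None = None,
    seed: int = 0,
    tune_lambda: bool = True,
    sparse: bool = True,
    n_starts: int = 5,
    refine: int | str = "auto",
) -> ESPLSMFit:
    """Full low-dimensional pipeline: moments -> pilot -> (lambda) -> fit.

    ``refine`` controls iterative re-weighting: after a sparse fit, the
    envelope is refit unpenalized on the selected mediators only (a much
    better conditioned problem), the adaptive weights are rebuilt from that
    restricted pilot and the penalty is re-tuned.  'auto' runs two rounds
    when p is large relative to n (p > max(40, n/10)) and none otherwise.
    """
    from .envelope_core import EnvelopeBasis, complete_basis

    moments = compute_moments(data)
    if d and sparse:
        # pre-test: if the mediators show no outcome association at all
        # (Wilks LR below its null critical value), report no mediation;
        # fitting an envelope direction to pure noise would otherwise pick
        # the largest spurious association, whose coordinates can have
        # enormous leverage when S_{M|X,Z} is ill-conditioned
        stat, critical = mediation_evidence(moments)
        if stat < critical:
            p = data.p
            null_basis = EnvelopeBasis(np.empty((p, 0)), np.eye(p), 0)
            null_basis.objective = envelope_objective(null_basis, moments)
            cfg = config if config is not None else SparseConfig()
            cfg.null_preferred = True
            return estimate_parameters(
                moments, null_basis,
                SparsityPattern(np.empty(0, dtype=int), np.arange(p), p),
                cfg,
            )
    pilot = fit_envelope(moments, d, n_starts=n_starts, seed=seed)
    if d == 0 or not sparse:
        return estimate_parameters(moments, pilot, config=config)
    if refine == "auto":
        refine = 2 if data.p > max(40, data.n // 10) else 0

    def one_round(pilot, config, gamma=1.0):
        if config is None or config.weights is None:
            base = adaptive_weights(pilot)
            if config is not None:
                base.lam = config.lam
                base.lam_grid = config.lam_grid
            config = base
        if tune_lambda:
            config = select_lambda(moments, d, config, criterion="bic",
                                   seed=seed, pilot=pilot, data=data,
                                   ebic_gamma=gamma)
        basis, pattern = fit_sparse_envelope(moments, d, config, seed=seed,
                                             pilot=pilot)
        return basis, pattern, config

    # with refinement rounds ahead, the first pass stays deliberately
    # liberal (classical BIC) so weak rows survive to be re-weighted;
    # only the final pass applies the high-dimensional correction
    basis, pattern, config = one_round(
        pilot, config, gamma=0.0 if refine else 1.0
    )
    for r in range(int(refine)):
        prev_sel = pattern.selected
        if pattern.p_selected in (0, data.p):
            break
        # refit the envelope on the selected mediators only (a much better
        # conditioned problem) and rebuild the weights from that pilot
        sub = MediationDataset(
            data.Y, data.M[:, prev_sel], data.X, data.Z
        )
        mom_sub = compute_moments(sub)
        b_sub = fit_envelope(mom_sub, d, n_starts=n_starts, seed=seed)
        G = np.zeros((data.p, d))
        G[prev_sel] = b_sub.Gamma
        pilot = EnvelopeBasis(G, complete_basis(G), d)
        basis, pattern, config = one_round(
            pilot, None, gamma=1.0 if r == int(refine) - 1 else 0.0
        )
        if np.array_equal(pattern.selected, prev_sel):
            break
    return estimate_parameters(moments, basis, pattern, config)


def bootstrap_inference(
    data: MediationDataset,
    d: int,
    config: SparseConfig | None = None,
    B: int = 500,
    seed: int = 0,
    tune_lambda: bool = True,
    alpha: float = 0.05,
) -> tuple[TestResult, TestResult]:
    """Case-resampling bootstrap for the direct and indirect effects.

    Rows are resampled with replacement; each resample refits the pipeline
    (by default re-tuning lambda, so selection uncertainty is propagated).
    Percentile CIs per effect entry; two-sided p-value per entry is
    2 min(frac <= 0, frac >= 0) floored at 1/(B + 1).  For matrix effects the
    scalar p_value reports the smallest entry-wise p-value.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    fit0 = fit_esplsm(data, d, config, seed=seed, tune_lambda=tune_lambda)
    direct0 = fit0.beta_X
    indirect0 = fit0.indirect_effect
    k, r = direct0.shape

    rng = np.random.default_rng(seed)
    n = data.n
    directs, indirects = [], []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            boot = MediationDataset(
                data.Y[idx], data.M[idx], data.X[idx], data.Z[idx]
            )
            cfg_b = None
            if not tune_lambda and fit0.config is not None:
                cfg_b = SparseConfig(
                    lam=fit0.config.lam, weights=None,
                    weight_exponent=fit0.config.weight_exponent,
                )
            fit_b = fit_esplsm(boot, d, cfg_b, seed=sub_seed,
                               tune_lambda=tune_lambda)
            directs.append(fit_b.beta_X)
            indirects.append(fit_b.indirect_effect)
        except Exception:
            n_failed += 1
    if n_failed > 0.1 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap refits failed", RuntimeWarning
        )

    def summarize(draws, estimate, name):
        arr = np.stack(draws)  # (B_ok, k, r)
        lo = np.percentile(arr, 100 * alpha / 2, axis=0)
        hi = np.percentile(arr, 100 * (1 - alpha / 2), axis=0)
        frac_le = np.mean(arr <= 0, axis=0)
        frac_ge = np.mean(arr >= 0, axis=0)
        pvals = 2.0 * np.minimum(frac_le, frac_ge)
        pvals = np.clip(pvals, 1.0 / (B + 1), 1.0)
        return TestResult(
            effect_name=name, estimate=estimate, statistic=np.nan, df=0,
            p_value=float(pvals.min()), p_values=pvals,
            ci_lower=lo, ci_upper=hi, method="bootstrap", B=B, seed=seed,
            n_failed=n_failed,
        )

    return (
        summarize(directs, direct0, "direct"),
        summarize(indirects, indirect0, "indirect"),
    )
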