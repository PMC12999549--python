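"""Evaluation metrics and the OLS comparator.

Connects fitted models to the evaluation quantities used throughout the
simulation studies: Frobenius-norm RMSE over replications, mediator selection
rates (TPR / TNR / precision), empirical rejection rates, and an unstructured
multivariate least-squares baseline packaged in the same fit container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_moments import MediationDataset, SampleSizeError, compute_moments
from .envelope_core import EnvelopeBasis
from .estimators import ESPLSMFit, estimate_parameters
from .inference import TestResult
from .sparse_envelope import SparsityPattern


@dataclass
class SelectionTruth:
    """True sparsity-selected mediator indices (0-based)."""

    true_selected: np.ndarray
    p: int

    def __post_init__(self):
        self.true_selected = np.asarray(self.true_selected, dtype=int)
        if self.true_selected.size and (
            self.true_selected.min() < 0 or self.true_selected.max() >= self.p
        ):
            raise ValueError("true_selected indices out of range")


class UndefinedMetricError(ZeroDivisionError):
    """A selection-metric denominator is zero."""


def frobenius_rmse(
    estimates: list[np.ndarray], truth: np.ndarray
) -> tuple[float, float]:
    """sqrt(mean ||est - truth||_F^2) over replications, with MC SE.

    The SE is SD(per-replication Frobenius norms) / sqrt(reps).
    """
    if not estimates:
        raise ValueError("need at least one replication")
    truth = np.asarray(truth, dtype=float)
    norms = np.array(
        [np.linalg.norm(np.asarray(e, dtype=float) - truth)
         for e in estimates]
    )
    rmse = float(np.sqrt(np.mean(norms**2)))
    se = (
        float(np.std(norms, ddof=1) / np.sqrt(len(norms)))
        if len(norms) > 1 else np.nan
    )
    return rmse, se


def selection_metrics(
    pattern: SparsityPattern, truth: SelectionTruth
) -> tuple[float, float, float]:
    """(TPR, TNR, precision) of the selected set against the truth.

    TPR = |A ∩ T| / |T|; TNR = |I ∩ T^c| / |T^c|; precision = |A ∩ T| / |A|.
    A zero denominator raises unless both the selected set and the truth are
    empty, in which case the metric is 1 by convention.
    """
    if pattern.p != truth.p:
        raise ValueError("pattern and truth refer to different p")
    sel = set(pattern.selected.tolist())
    tru = set(truth.true_selected.tolist())
    comp = set(range(truth.p)) - tru
    exc = set(pattern.excluded.tolist())

    if tru:
        tpr = len(sel & tru) / len(tru)
    elif not sel:
        tpr = 1.0
    else:
        raise UndefinedMetricError("TPR undefined: no true positives exist")
    if comp:
        tnr = len(exc & comp) / len(comp)
    else:
        tnr = 1.0
    if sel:
        precision = len(sel & tru) / len(sel)
    elif not tru:
        precision = 1.0
    else:
        raise UndefinedMetricError("precision undefined: empty selection")
    return float(tpr), float(tnr), float(precision)


def empirical_power(
    test_results: list[TestResult] | list[float], alpha: float = 0.05
) -> tuple[float, float]:
    """Fraction of replications rejecting at level alpha, with binomial SE."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not test_results:
        raise ValueError("need at least one test result")
    pvals = np.array(
        [t.p_value if isinstance(t, TestResult) else float(t)
         for t in test_results]
    )
    power = float(np.mean(pvals < alpha))
    se = float(np.sqrt(power * (1.0 - power) / len(pvals)))
    return power, se


def ols_baseline(data: MediationDataset) -> ESPLSMFit:
    """Unstructured multivariate least squares in the shared fit container.

    Equivalent to the envelope fit with d = p (identity basis): beta_M is the
    OLS coefficient of Y on M given (X, Z), and beta_X, beta_Z the OLS
    exposure/confounder coefficients.
    """
    n, p, k, q = data.n, data.p, data.k, data.q
    if n <= p + k + q + 1:
        raise SampleSizeError(
            f"OLS baseline needs n > p+k+q+1 = {p + k + q + 1}, got n={n}"
        )
    moments = compute_moments(data)
    basis = EnvelopeBasis(np.eye(p), np.empty((p, 0)), p)
    fit = estimate_parameters(moments, basis)
    fit.diagnostics["method"] = "ols"
    return fit
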