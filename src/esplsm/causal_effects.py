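"""Identified causal effect functionals for an exposure contrast.

Under the linear mediation model without exposure-mediator interaction, and
under the standard identification assumptions (SUTVA, consistency, sequential
ignorability given Z, positivity), the average causal mediation effect
(ACME), the average natural direct effect (ANDE), and the total effect of
moving the exposure from x' to x are linear in the contrast:

    ACME  = beta_M' gamma_X' (x - x')
    ANDE  = beta_X' (x - x')
    total = ACME + ANDE = (beta_X + gamma_X beta_M)' (x - x').

The identification assumptions are untestable from the data; every estimate
carries a structured assumptions report rather than a silent claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import ESPLSMFit

ASSUMPTIONS = {
    "SUTVA": "no interference between units, no hidden treatment versions",
    "consistency": "observed outcome equals the potential outcome at the "
                   "received exposure level",
    "sequential_ignorability": "given Z: (i) exposure independent of "
                               "potential mediators/outcomes; (ii) potential "
                               "mediators independent of potential outcomes "
                               "given exposure and Z",
    "positivity": "every exposure/mediator level has positive probability "
                  "for all covariate values",
    "immaterial_part": "conditional on X, Z and the material mediator "
                       "component, the immaterial component carries no "
                       "additional outcome information",
}


@dataclass
class EffectEstimates:
    """ACME, ANDE and total effect for one exposure contrast."""

    contrast: tuple
    acme: np.ndarray  # (r,)
    ande: np.ndarray  # (r,)
    total: np.ndarray  # (r,)
    assumptions: dict = field(default_factory=lambda: dict(ASSUMPTIONS))


def causal_effects(
    fit: ESPLSMFit, x: np.ndarray, x_prime: np.ndarray
) -> EffectEstimates:
    """Estimated ACME, ANDE and total effect for the contrast x vs x'."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    x_prime = np.atleast_1d(np.asarray(x_prime, dtype=float))
    k = fit.beta_X.shape[0]
    if x.shape != (k,) or x_prime.shape != (k,):
        raise ValueError(
            f"contrast vectors must have length k={k}, got "
            f"{x.shape} and {x_prime.shape}"
        )
    delta = x - x_prime
    acme = fit.beta_M.T @ fit.gamma_X.T @ delta
    ande = fit.beta_X.T @ delta
    total = acme + ande  # additive decomposition holds exactly
    return EffectEstimates((x, x_prime), acme, ande, total)
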