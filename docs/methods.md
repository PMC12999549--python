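# Methods

## Model

The package fits a linear mediation system for outcomes `Y (n×r)`, mediators
`M (n×p)`, exposures `X (n×k)` and optional confounders `Z (n×q)`:

    Y = μ_Y + β_M'(M−μ_M) + β_X'(X−μ_X) + β_Z'(Z−μ_Z) + ε,  Var(ε) = Σ_{Y|M,X,Z}
    M = μ_M + γ_X'(X−μ_X) + γ_Z'(Z−μ_Z) + e,                Var(e) = Σ_{M|X,Z}

with a predictor-envelope constraint on the mediator side: an orthonormal
`Γ (p×d)` spans the smallest reducing subspace of `Σ_{M|X,Z}` containing
`span(β_M)`, so `β_M = Γη` and `Σ_{M|X,Z} = ΓΩΓ' + Γ₀Ω₀Γ₀'`.  Sparsity is
imposed row-wise on `Γ`: a mediator with a zero row has exactly zero
outcome-side coefficients and is "sparsity-excluded".

Assumptions: independent observations; errors independent of regressors (and
of each other across the two equations); Gaussian likelihood as the working
objective (consistency of the point estimators does not require normality,
but the plug-in Wald covariances do use the Gaussian forms); no
exposure–mediator interaction; causal readings of ACME/ANDE additionally
require SUTVA, consistency, sequential ignorability given `Z`, and
positivity — these are untestable from the data and are attached to every
effect estimate as an explicit assumptions report.

## Estimation pipeline

1. **Moments** (`data_moments`).  All covariances use the 1/n (maximum
   likelihood) convention, matching the closed-form estimator algebra.
   Residualization of `M` and `Y` on the centered `(X, Z)` design uses a QR
   decomposition, never normal equations.  `q = 0` and `k = 0` are empty
   blocks, not zero columns.

2. **Envelope subspace** (`envelope_core`).  For fixed `d` the objective

       f(Γ) = log|S_{Y|X,Z}| + log|Γ'S_{M|X,Z}⁻¹Γ| + log|Γ'S_{M|Y,X,Z}Γ|

   is minimized over the Grassmannian.  Because first-order descent stalls
   badly when `S_{M|X,Z}` is ill-conditioned, the default optimizer combines
   (a) a sequential one-direction-at-a-time construction in which each new
   direction exactly minimizes the objective increment (Schur-complement
   compression onto the orthocomplement), solved by an eigenvector
   fixed-point iteration, and (b) multi-start projected-gradient descent
   with QR retraction and Armijo backtracking from deterministic starts
   (ranked single-direction candidates, OLS span, leading eigenvectors) plus
   seeded random starts.  Convergence: relative objective change < 1e-8 or
   500 iterations.  The returned basis is canonicalized (rotated to the
   eigenvectors of `Γ'SΓ`, decreasing order, sign-fixed) so runs are
   reproducible.  `d = 0` is the no-mediation model; `d = p` reproduces OLS
   exactly.

3. **Sparse fit** (`sparse_envelope`).  The penalty `λ Σ w_i‖Γ_i‖₂` is
   applied in an anchored coordinate system: the `d` rows with the largest
   pilot norms are fixed to an identity block (unpenalized anchors, which
   also reconciles the `p − d` penalized terms with the `p` rows of `Γ`);
   the remaining rows are free coordinates `C` with adaptive weights
   `w_i = (‖pilot row i‖ + 1e-8)^{-2}` (exponent configurable, default 2).
   The solver is proximal gradient with row-wise group soft-thresholding and
   backtracking, warm-started along a decreasing 20-point log-spaced λ grid
   whose upper end is the smallest λ that zeroes every free row at the
   start.  Rows with final norm below 1e-6 are set exactly to zero and the
   basis is re-orthonormalized on its nonzero rows.

4. **Penalty tuning.**  Default criterion is an extended BIC,
   `−2·loglik + (log n + 2 log p)·n_par` with
   `n_par = d(p_A − d) + d·r`: the `2 log p` term is the standard
   high-dimensional correction, needed because the profile objective's gain
   per spurious row exceeds the classical `log n` penalty when `p/n` is not
   small.  Because the BIC is monotone in λ *within* a support class, the
   reported solution at the selected λ is the warm-started path solution
   (not a cold restart), which keeps the selected support and the fitted
   basis consistent.  Five-fold CV on held-out outcome prediction error is
   available (`criterion="cv"`); it tends to keep prediction-helpful but
   selection-spurious rows and is not the default.

5. **No-mediation pre-test.**  Before fitting any direction, the pipeline
   runs the classical Wilks likelihood-ratio test of `Y ⊥ M | (X, Z)`: the
   Bartlett-corrected statistic
   `(n − k − q − (p+r+3)/2)·log(|S_{Y|X,Z}| / |S_{Y|M,X,Z}|)` against a
   chi-square with `p·r` degrees of freedom at level 0.001.  Below the
   critical value the no-mediation model (`β_M = 0`, d = 0) is returned.
   This matters when the mediated effect is exactly zero: the envelope
   direction is then unidentified, and an unguarded fit reports the largest
   spurious association, whose coordinates can have enormous leverage when
   `Σ_{M|X,Z}` is ill-conditioned.  The Wilks statistic is invariant to
   linear transformations of the mediators — its null distribution does not
   depend on the mediator covariance at all — which makes the guard immune
   to exactly the conditioning pathology it protects against.  (A BIC-style
   comparison on the profile envelope objective was rejected: that objective
   also prices the covariance-structure fit and would turn away genuine
   mediation whenever the estimated sparse basis fits the noisy sample
   covariance imperfectly, which at p ≈ n/2 is always.)  The pre-test
   requires n > p + k + q + 1 and is skipped otherwise.

6. **Iterative refinement.**  When `p > max(40, n/10)` the pipeline runs two
   extra rounds: refit the unpenalized envelope on the selected mediators
   only (a much better conditioned problem), rebuild the weights from that
   restricted pilot, and re-tune λ.  This materially improves selection at
   `p ≈ n/2`; at small `p` it is a no-op by default.

7. **Closed forms** (`estimators`).  Given the basis, every parameter has an
   explicit expression (`γ̂_X = S_{X|Z}⁻¹S_{(X,M)|Z}`,
   `η̂ = (Γ'S_{M|X,Z}Γ)⁻¹Γ'S_{(M,Y)|X,Z}`, etc.); `β̂_M` equals the
   projection of the OLS coefficient onto `span(Γ̂)` in the `S_{M|X,Z}`
   metric.  All inverses go through factorizations.  For a sparse basis,
   `Ω̂₀` is computed on the orthocomplement of the re-orthonormalized `Γ̂`.

8. **High-dimensional path** (`highdim`).  When `p > n` (or forced), the
   singular `S_{M|X,Z}⁻¹` and `S_{M|Y,X,Z}` in the objective are replaced by
   penalized log-determinant (graphical-lasso-type) surrogates computed on
   the correlation scale and rescaled; the `Y`-adjusted block applies the
   same machinery to the residuals of `M` on `(Y, X, Z)` rather than
   differencing two estimates, which guarantees positive definiteness.  The
   default penalty follows the theoretical rate `0.5·√(log p / n)`
   (overridable); if the solver fails on a pathological input, a
   diagonal-shrinkage fallback keeps the PD guarantee and flags
   non-convergence.

## Inference

* **Wald.**  Plug-in covariances for `√n·vec(β̂_X)` and
  `√n·vec(γ̂_Xβ̂_M)` follow the Gaussian asymptotic forms implied by the
  envelope parameterization; the shared middle term inverts
  `ηΣ_{Y|M,X,Z}⁻¹η'⊗Ω₀ + Ω⊗Ω₀⁻¹ + Ω⁻¹⊗Ω₀ − 2I` by Moore–Penrose
  pseudo-inverse (rank tolerance 1e-8 of the largest singular value);
  statistics are `n·vec'V†vec` with chi-square reference on `rank(V)`
  degrees of freedom.  The direct-effect test is well calibrated in the
  simulations below.  The indirect-effect test would inherit post-selection
  optimism when the mediated signal is exactly zero (the envelope direction
  is then unidentified and the fitted direction chases the largest spurious
  association); the no-mediation pre-test absorbs this, making the indirect
  test conservative rather than anti-conservative near the null.  For
  calibrated indirect-effect p-values near the null the bootstrap remains
  the recommended route.
* **Bootstrap.**  Case resampling with full pipeline refits (λ re-tuned per
  resample by default; a fixed-λ fast path is available), percentile
  intervals, per-entry sign-based two-sided p-values floored at `1/(B+1)`.
  For matrix effects the scalar `p_value` is the smallest per-entry p-value;
  the full matrix is in `p_values`.

## Synthetic-data generator

`simulate.make_design` reproduces the benchmark designs exactly as printed:
main design `p=11, k=1, q=2, d=1, r=1`, `Σ_{Y|M,X,Z}=3I`, `(Γ,Γ₀)` from a QR
orthonormalization of a p×p standard-normal draw with the last seven rows of
`Γ` zeroed and the active block re-orthonormalized, `η ~ N(3, 0.25²)`,
`β_X = 1.5`, `β_Z = (−5, 2)'`, `γ_X = 1_p'`, `γ_Z = (−0.1·1_p, 2.5·1_p)'`,
`Ω = AA'` with `A ~ N(1,1)`, `Ω₀ = BB'` with `B ~ U(0.4, 0.7)` (plus a 1e-6
diagonal jitter for numerical safety); exposures Bernoulli(0.5), confounders
Bernoulli(0.1) and N(0, 0.1²).  Scenario switches: `γ_X = 0`, `η = 0`,
non-normal error families (t₃, χ²₄, U(0,1), each standardized to exact zero
mean and unit variance before coloring, so only the shape changes),
correlated Bernoulli exposures via a Gaussian copula, unobserved confounding
(`γ_U`, `β_U`), a `p=150 > n=100` design, and an application-matched design
`n=612, p=296, k=1, q=0, d=2, r=14` with the first 74 mediators active.
Signal scalings `c1` (direct) and `c2` (mediated) multiply `β_X` and `η`
post hoc.

Design parameters are drawn **once per `seed_design`** and reused across
replications.  A consequence worth stating plainly: `Ω₀ = BB'` with iid
uniform entries is nearly rank-one, so `Σ_{M|X,Z}` has a tiny smallest
eigenvalue whose magnitude varies by orders of magnitude across design
draws.  Quantities that depend on `Σ_{M|X,Z}⁻¹` — most notably the OLS
comparator's error, whose per-draw distribution is heavy-tailed with
effectively infinite mean — are therefore summarized by the **median across
design seeds** (errors pooled over replications within a seed) everywhere in
this package.  The envelope estimator itself is nearly insensitive to that
conditioning, which is precisely its advantage over OLS.

What the generator does not emulate: real omics data are non-Gaussian in
more structured ways (counts, batch effects), mediators may affect exposure
ascertainment, and true effects are not exactly row-sparse in any basis.
Passing tests therefore certify the estimator under its own model class, not
robustness to arbitrary real-data violations (the error-family and
confounding scenarios probe the first-order departures only).

## Problem sizes used in tests and the acceptance script

The published tables use 1000 replications per cell over a single design
draw.  This package's checks use, as its own choice of scale: 5 design
seeds × 40 replications per cell (201 seeds for the cheap OLS comparator) in
`scripts/acceptance.py`; 3 seeds × 15 replications per cell, 150-replication
type-I-error runs at n=400, 400-replication Monte-Carlo covariance checks at
n=2000, 300-draw bootstrap-vs-asymptotic comparisons, and 8 replications of the
application-matched design in the test suite.  Tolerances are three
Monte-Carlo standard errors of the reported summary (cross-seed for
design-draw-sensitive quantities, binomial for rates), one-sided where a
smaller error is unambiguously better.

## Known limitations

* The indirect-effect Wald test is anti-conservative under an exact null
  mediated effect (see above); use the bootstrap there.
* Selection at `p ≈ n/2` with a near-singular material covariance (tiny
  eigenvalues of `Ω`) recovers the support only partially; the refinement
  loop mitigates but does not eliminate this.
* `d` is selected by outcome-prediction CV; ties break toward smaller `d`,
  and a flat CV profile (no signal) is flagged with a warning rather than an
  error.
* No missing-data handling, weighting, or exposure-side sparsity.
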