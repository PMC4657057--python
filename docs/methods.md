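# Methods

## The problem

Bootstrap-type resampling solves B near-identical optimization problems:
for each resampled data set X_b, maximize the same log-likelihood
l(θ; X_b) that was already maximized on the original data X.  When one
fit is expensive, B = 2000 fits may be prohibitive.  `fpboot` exploits
the similarity of the problems: it learns, from resamples already
solved, the map from a cheap summary of a resampled data set — its
*fingerprint* — to that data set's own optimum, and uses the predicted
optimum either as a warm start for the optimizer or directly as the
estimate.

All costs are counted in objective-function evaluations, a
hardware-independent metric that covers both the optimizer iterations
and the finite differences spent on fingerprints.  The interpolator's
linear algebra is deliberately excluded: it does not evaluate the
objective and does not scale with the difficulty of the estimation
problem, which is the regime the method targets.

## Fingerprints

The fingerprint of a resample is the vector of partial derivatives of
its log-likelihood evaluated at the original optimum θ̂₀, truncated at
order g ∈ {1, 2}.  Near θ̂₀, gradient and curvature of the resample's
objective say where its optimum lies relative to θ̂₀ — the information a
Newton step would use.  For order 2 only the unique entries enter: the
gradient plus the upper triangle of the Hessian.

Derivatives are central finite differences with per-dimension step
h_k = 1e-4 · (1 + |θ̂₀_k|).  Costs are exact and charged to the budget:
2d evaluations for g = 1; 2d + 1 + 2d(d−1) for g = 2 (the gradient's ±
points are reused for the Hessian diagonal; each off-diagonal uses a
four-point cross stencil).  On the two toy models, where the analytic
derivatives are available, the stencil error is below 1e-5 relative.

If the objective is undefined at a stencil point (the GEV support
condition can fail at θ̂₀ for an unlucky resample), the fingerprint is
flagged invalid, the evaluations actually spent are charged, and the
driver routes that resample to a full optimization from the model's
naive start.

## Learning the fingerprint → optimum relation

The interpolator is a least-squares support-vector machine for
regression: an RBF-kernel ridge regression with an unpenalized bias,
solved as one bordered linear system.  One single-output model is
fitted per parameter dimension; fingerprint components are standardized
to zero mean and unit variance first.

Hyperparameters (ridge penalty λ ∈ {1e-8, …, 1e3} logarithmic; kernel
width ∈ {0.3, 1, 3} × the median pairwise distance of the standardized
inputs) are selected by exact leave-one-out cross-validation, using the
closed form r_i = α_i / (M⁻¹)_ii for the LOO residuals of the bordered
system.  The penalty grid reaches low enough that an exactly learnable
relation (the exponential toy's affine map) is interpolated to near the
finite-difference noise floor.  The per-dimension prediction error ε_k
is the RMS of the LOO residuals at the selected hyperparameters; it
doubles as the warm-start simplex scale.  Outputs are not standardized:
with one model per dimension and an unpenalized bias, output location
and scale are absorbed by the solution itself.

Constrained problems make the relation non-smooth where a constraint
activates, so couples whose optimum lies on a boundary (within 10·tol_x
of a finite bound) are excluded from that dimension's model, and any
prediction violating a constraint is clipped to the constraint value.

A nearest-neighbor predictor (squared Euclidean distance on
fingerprints, ties to the lowest resample index) is provided as the
baseline the kernel model improves upon.

## Optimizer

Nelder-Mead with the standard reflection/expansion/contraction/shrink
coefficients (1, 2, 0.5, 0.5), written from scratch so every objective
call is counted, including the initial vertices.  Convergence requires
both the infinity-norm spread of vertices around the best vertex and
the spread of their values to drop below tol_x and tol_f (both default
1e-6, configurable).  Box constraints are enforced by returning +inf
outside the feasible set — consistent with the GEV support handling —
so the simplex retreats rather than projects.  A safety valve of
2000·dim evaluations bounds pathological runs.

Two simplex initializations:

* default: vertex k+1 multiplies component k of the start by 1.05, or
  sets it to 0.00025 when zero (the classic `fminsearch` rule);
* predicted: vertex k+1 offsets component k additively by
  max(ε_k, tol_x).  The additive form is chosen because ε_k is an
  absolute error scale; the tol_x floor keeps the simplex nondegenerate
  when predictions are near-perfect.

## Scheduling a run

For the fingerprint variants, all B fingerprints are computed up front
(the extrapolation scan needs them) and charged up front on the cost
axis.  The initial phase then avoids extrapolation: the resamples
attaining the minimum or maximum in any fingerprint dimension (at most
2 per dimension, deduplicated) plus 20 randomly chosen ones are solved
first, starting from θ̂₀.  Remaining resamples are processed in index
order: warm-started from the prediction once the interpolator exists,
from θ̂₀ before that.

The interpolator is refitted when the pool has grown by
max(10, 10% of the last training size) couples, and refitting stops
once the pool exceeds 1000 couples (the last model is reused); both
cadence constants are configurable.  Only optimizer-based couples with
valid fingerprints enter the pool.

With bypass ratio p > 0, each optimized main-phase estimate is followed
by up to p predicted estimates taken as final (zero optimizer cost,
fingerprint already paid), never exceeding B total: with p = 3, 200
optimized estimates yield 800; at 1800 of 2000 only 200 more fit.
p = 0 reproduces the warm-start variant exactly.

Parallel execution is modeled by replay: with C cores, solved couples
enter the pool only at batch boundaries of size C, so resamples within
one batch cannot learn from each other.  C = 1 is the serial run,
bit-identical to the normal schedule; C ≥ B disables learning, leaving
fingerprints as pure overhead.

Determinism: one root seed spawns independent child streams for
resampling and for the initial-phase random picks, so all variants with
the same seed see identical resamples, and identical seeds give
byte-identical record files.

## Models

**Exponential** (dim 1, mean parametrization): l(θ) = −n ln θ − Σx/θ,
maximized at the sample mean.  The mean parametrization makes the
g = 1 fingerprint affinely equivalent to the optimum
(θ̂* = θ̂₀ + θ̂₀²F₁/n) — the cleanest possible learning problem.

**Regression** (dim 1, no intercept, error variance known and equal to
one): l(β) = −(n/2)ln 2π − ½Σ(y−βx)², maximized at Σxy/Σx².  The g = 1
fingerprint does not determine the optimum (equal gradients, different
curvatures), while g = 2 recovers it exactly via β̂* = β̂₀ − F₁/F₂ — the
minimal example of why fingerprint order matters.

**Linear mixed model** (dim 3): random intercept + slope per cluster,
Y_i ~ N(X_iβ, Z_i D Z_iᵀ + σ²I) with X_i = Z_i = [1, x_i].  Maximum
likelihood (not REML).  Writing D = σ²LLᵀ with L lower-triangular, β
and σ² have closed-form maximizers for fixed Γ = LLᵀ (GLS and the
generalized RSS over the total observation count N) and are profiled
out, leaving the three free Cholesky entries.  Per-cluster algebra is
reduced to 2×2 operations via the Woodbury identity and the matrix
determinant lemma, so one evaluation is O(#clusters).  The sign of each
Cholesky column is unidentified (D depends on LLᵀ only); optima are
canonicalized to a nonnegative diagonal so the fingerprint → optimum
relation is single-valued, and all comparisons and percentiles use the
recovered D entries, which are invariant.  Resampling is the case
bootstrap: whole clusters drawn with replacement, relabeled so repeated
clusters are distinct units.

**Nonstationary GEV** (dim 4): block maxima with location
μ_i = α + β·t_i, parameters (ξ, σ, α, β).  The density exists only
where 1 + ξ(x−μ)/σ > 0; violations return +inf.  Below |ξ| < 1e-8 the
Gumbel limit formulas are used (continuous to 1e-6 at the switch).  The
naive start combines least squares of x on t with Gumbel moment
matching on the residuals (σ₀ = s√6/π, location shifted by −σ₀γ with γ
Euler's constant) and ξ₀ = 0.1; σ₀ is doubled until the support
condition holds at the start.  Exactness is irrelevant here — it is
only a start.

## Synthetic data

The generators define the study conditions; their defaults are fixed
once:

* exponential: θ = 2, n = 100, B = 200 — the toy scale all warm-start
  and learning-curve results use;
* regression: β = 2, n = 100, x ~ U(0, 2), unit error variance;
* mixed: 30 clusters of size U{40, …, 100} (unbalanced longitudinal
  structure), β = (1.0, 0.5), D = [[0.5, 0.1], [0.1, 0.2]], σ² = 1,
  within-cluster predictor x ~ N(0, 1);
* GEV: ξ = 0.1, σ = 1, α = 10, β = 0.5 over t ∈ [0, 1] on an equally
  spaced covariate — a stylized record of block maxima with a linear
  trend, sampled by CDF inversion.

What they emulate — and what they do not: i.i.d. rows, clustered rows
with correlated random effects, and support-constrained maxima exercise
every code path of the pipeline (including invalid fingerprints via
short-tailed GEV shapes).  They do not reproduce missingness patterns,
serial dependence within clusters beyond the random effects, rounding
or measurement artifacts of real instruments.  Passing tests therefore
demonstrate the mechanics and the closed-form identities of the method,
not its speed-ups on any particular real data set.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen
as the smallest sizes at which each effect is visible and stable:
B ∈ {40, …, 200} resamples, 20-seed medians for stochastic properties,
n ≈ 5000 observations (72 clusters, or 5000 maxima) for parameter
recovery, and 6 pooled runs for reference percentiles.  The full-size
protocol (B = 2000, 99 pooled processes) is a straightforward scale-up
of the same plans.

## Numerical choices and edge cases

* Percentile bound: ascending order statistic at rank
  max(1, ⌊αB⌋).  The weighted form (used only to down-weight
  prioritized optima early in an accuracy curve) takes the smallest
  value whose cumulative weight reaches max(1, ⌊αW⌋), which reduces
  exactly to the unweighted rank under unit weights.  Prioritized
  records get weight min(1, b/index) after b estimates; the weighting
  has no effect once all estimates are used.
* High accuracy level: the baseline (original-optimum) curve's terminal
  error; medium is twice that.
* Boundary detection for pool exclusion: within 10·tol_x of a finite
  bound.
* Degenerate inputs signal errors early: empty data, missing columns,
  NaNs, zero design (Σx² = 0), zero residual variance, non-PSD D,
  non-positive σ².
* Ties in the nearest-neighbor predictor resolve to the lowest resample
  index; Nelder-Mead sorting is stable, so runs are reproducible across
  platforms with the same BLAS-free code path.

## Known limitations

* Single-mode objectives only: fingerprints assume all resamples
  converge to the same basin.
* The bypass error is not propagated into the confidence bound; the
  bound treats predicted estimates as exact.
* The LS-SVM refit is O(n³) in the pool size; the 1000-couple cap keeps
  this negligible relative to expensive objectives, but for very cheap
  objectives the interpolator overhead (excluded from the evaluation
  budget by design) is visible in wall-clock time.
* MARS-style interpolators and moment/ABC-style fingerprints are out of
  scope; the interpolator interface leaves room for them.
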