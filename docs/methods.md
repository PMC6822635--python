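# Methods

This note documents the models and numerical procedures implemented in
`matrixmi`, the choices made where the design was genuinely open, and what
the synthetic study conditions do and do not establish.

## Data model

A trial set is a collection of equal-shape real matrices `X_i ∈ R^{c×T}`
(channels × time samples) with class labels and a sampling rate `fs`. All
later stages either keep the matrix form (2D decompositions, the support
matrix machine) or produce per-trial *feature matrices* (channels ×
derivative order for TDP features, CSP components × 1 for log-variance
features), never bare vectors, so the row/column correlation structure stays
available to the classifier.

## Preprocessing

**Sample sizing.** The proportion-estimate sample size is
`n0 = Z²p(1−p)/e²`; with a finite population of `N` samples the correction
`n = n0 / (1 + (n0−1)/N)` applies. `p = 0.5` maximizes `n0` when the
proportion is unknown. The corrected size is rounded *up* (conservative; a
downward rounding could undershoot the requested confidence).

**Windowing.** A recording of `L` samples is cut into `k` contiguous
windows of `⌊L/k⌋` samples with the remainder appended to the *last*
window, so a 4097-sample signal in 4 windows gives 1024, 1024, 1024, 1025.
The stationarity assumption motivating the segmentation holds only within a
window.

**Budget allocation.** A sampling budget is split across windows
proportionally to `N_i · sqrt(Σ_j Var_{i,j}²)` (window size times the
root-sum-square of its per-channel variances) — a Neyman-style allocation
weight. The weight is a fraction, not a count; integer counts come from
largest-remainder rounding, which preserves the total exactly. An
all-zero-variance configuration has no defined weights and raises a
dedicated error.

**Filter bank.** Nine 4 Hz Butterworth bands spanning 4–40 Hz, order 4,
applied forward-backward (`sosfiltfilt`) for zero phase. Band edges must
lie strictly inside (0, fs/2).

**CSP.** Per-trial covariance `XXᵀ/tr(XXᵀ)` (trace normalization makes the
fit invariant to global amplitude), averaged per class, then the
generalized eigenproblem `S₁w = λ(S₁+S₂)w`. Eigenvalues lie in [0, 1] and
the class-2 view of component `i` is `1 − λ_i`; filters are sorted by `λ`
descending and jointly whiten the pooled covariance. A ridge of
`1e−8 × λ_max` is added only when the pooled covariance is numerically
singular. Log-variance features use the `m` top and `m` bottom filters with
the variance share of each component, guarded by `ε = 1e−12` for degenerate
trials.

**Channel selection.** Channels are scored by their weight in the two
extreme filters. Raw generalized-eigenvector coefficients are
scale-confounded (the `vᵀ(S₁+S₂)v = 1` normalization inflates weights on
low-variance channels), so each extreme filter is unit-normalized and
weighted by its discriminative strength `2|λ − ½|` before taking the
per-channel maximum; ties break to the lower index. Ranking uses the whole
trial, not per-window covariances — the simplest defensible reading of how
channel selection composes with windowing.

**TDP features.** `log(var(Δᵏx) + ε)` for derivative orders `k = 0..K`,
where `Δ` is the first difference scaled by `fs`. `K = 2` carries the same
information as the Hjorth activity/mobility/complexity triple.

**FBCSP selection.** Features are ranked by mutual information with the
label using an equal-width histogram estimator with `⌈√n⌉` bins (log₂, so
thresholds read in bits). This is a single-stage ranking; the original
FBCSP's iterative MI-based band selection is deliberately simplified to it.

## The sparse/robust PCA family

All vector variants share the regression reformulation of PCA: an
orthonormal basis `A` and loadings `B` (both `p×k`, `AᵀA = I`), data `X`
with *columns as samples*, reconstruction `ABᵀX`. All solvers initialize at
classical PCA (or 2D-PCA) of the possibly corrupted input and are
deterministic given their input. Every fit records an `objective_trace`
that is non-increasing by construction; a violation is a bug, and the test
suite asserts it on every fixture.

- **SPCA** (elastic net): the B-step is exact coordinate descent per
  component on the Gram matrix `C = XXᵀ` (components decouple given `A`);
  the A-step is the polar factor of `CB` (Procrustes). Stops when
  `max|ΔB| < 1e−6` or 200 iterations.
- **JSPCA**: the loss `‖X − ABᵀX‖₂,₁` sums *column* (sample) residual
  norms — a gross outlier sample contributes linearly, not quadratically —
  and the penalty `λ‖B‖₂,₁` sums *row* norms, zeroing features jointly
  across components. Solved by IRLS with clamped weights
  `1/(2·max(‖·‖, ε))`, `ε = 1e−6`: a ridge-type closed-form B-step
  (via least squares, covering the singular λ = 0 case) and weighted
  Procrustes A-step. The recorded objective is the ε-smoothed norm
  (`h(t) = t` for `t ≥ ε`, quadratic below) that the clamped weights
  *exactly majorize* — this is what makes the trace provably monotone;
  for `ε = 1e−6` it differs from the true ℓ₂,₁ objective by `O(ε)` per
  term. Convergence: relative objective change `< 1e−6` or 300 iterations.
- **JGSPCA**: squared loss plus `λ Σ_g η_g‖B^G‖_F` with `η_g = √|g|` over a
  partition of the features. The B-step is one proximal-gradient step with
  the exact Lipschitz constant `2λ_max(C)`, whose group soft threshold
  produces *exact* zero blocks; the A-step is Procrustes. With singleton
  groups and λ = 0 it coincides with unpenalized SPCA.
- **ORPCA / RJSPCA** (2D variants on trials `X_j ∈ R^{a×b}`): loadings `Q`
  and orthonormal basis `P` (both `b×k`), reconstruction `X_j Q Pᵀ`.
  Orthonormality of `P` is imposed (Procrustes step) because the
  reconstruction is otherwise scale-degenerate. The Q-step is the ridge
  closed form `(S + λ_a I)⁻¹ S P` with `S = Σ_j X_jᵀX_j`; RJSPCA adds
  `λ_b‖Q‖₂,₁` via the same clamped IRLS diagonal, and rows of `Q` with norm
  below `1e−6 ×` the largest are reported as discarded features. With
  λ_a = λ_b = 0 both reduce to classical 2D-PCA.
- **RPCA / principal component pursuit**: `min ‖L‖⋆ + λ‖S‖₁ s.t. X = L+S`
  by the inexact augmented Lagrangian method — singular value thresholding
  on `L`, elementwise soft threshold on `S`, dual update, `μ` grown by 1.5
  per iteration from `1.25/‖X‖₂`. Default `λ = 1/√max(m,n)` (the universal
  choice). Stops at feasibility `‖X−L−S‖_F/‖X‖_F < 1e−7` or 1000
  iterations. The sparse component is elementwise-ℓ₁ by default; a
  column-wise ℓ₂,₁ mode (`sparse_mode="l21cols"`) is available for
  whole-column corruptions but off by default.

Singular values below `1e−10 ×` the largest are treated as zero throughout
(rank reports, shrinkage tests). Full SVDs are used everywhere; the
matrices this package targets (tens of channels/features) never reach the
regime where truncated solvers pay off.

## The robust support matrix machine

Binary problem, labels ±1:

    min_{W,b}  γ‖W‖₂,₁ + τ‖W‖⋆ + C Σ_i max(0, 1 − y_i(tr(WᵀX_i) + b))

Consensus ADMM with three blocks sharing a consensus variable `Z`:

1. **Hinge block**: `min_W C Σ hinge + ρ/2‖W − V‖²` — a linear SVM with a
   proximity term, solved in vectorized space by dual coordinate descent
   (`α_i ∈ [0, C]`, warm-started across outer iterations) alternated with
   *exact* minimization over the unpenalized offset `b` (the 1-D hinge sum
   is piecewise linear; its minimum sits at a breakpoint). Inner tolerance
   `1e−8` on the subproblem objective, capped at 25 rounds per outer
   iteration — the ADMM tolerates inexact subproblem solves.
2. **Nuclear block**: singular value thresholding with `τ/ρ`.
3. **Row-sparsity block**: row-wise group soft threshold with `γ/ρ`.

`ρ` starts at 1 with residual balancing (×2 / ÷2 when the primal/dual
residual ratio exceeds 10, rescaling the scaled duals accordingly);
termination when the scaled residuals drop below `1e−4`, cap 500
iterations.

Two deliberate choices:

- **Centering.** Trials are centered by their mean matrix inside the
  solver and the mean is absorbed into `b` on exit. This makes the decision
  function *exactly* invariant to adding a constant matrix to every trial
  (the invariance holds analytically for the exact minimizer but is hard to
  verify through a finitely-converged splitting method on shifted,
  ill-conditioned data) and conditions the hinge subproblem.
- **Incumbent iterate.** Splitting iterates are mildly nonmonotone in the
  objective. The solver evaluates, at every iteration, the *structured*
  candidate from the proximal blocks — the nuclear block when τ > 0
  (exactly low rank), else the row-sparse block when γ > 0 (exact zero
  rows), else the hinge block — and returns the incumbent with the lowest
  objective. The recorded trace is the incumbent objective, monotone by
  construction, and the returned `(W, b)` attains its final value exactly.

Multiclass is one-vs-rest with a shared `(γ, τ, C)`: the per-class margin
constraints decouple given per-class slacks, and prediction is
`argmax_j tr(W_jᵀX) + b_j` with ties to the lowest class identifier. A
Crammer–Singer joint formulation was rejected as needless coupling.
Defaults `γ = τ = 0.1, C = 1`; a cross-validated grid-search helper over
`10⁻³..10²` is provided but nothing in the pipeline depends on it. The
vectorized baseline (`svm_baseline_fit`) is the exact soft-margin SVM
(libsvm with an unpenalized intercept, tolerance `1e−8`), which the matrix
machine reduces to at γ = τ = 0 because `tr(WᵀX) = vec(W)ᵀvec(X)`.

## Evaluation

Cohen's kappa uses the balanced-class chance level `p_o = 1/k`, i.e.
`κ = (acc − 1/k)/(1 − 1/k)` — appropriate for the balanced designs this
package targets and *not* the general marginal-product form.
Precision/recall/F1 are per class from the pooled confusion matrix (rows
true, columns predicted); zero denominators yield 0 with an explicit flag;
macro averages are unweighted. Cross-validation is stratified k-fold
(shuffled, seed-deterministic; stratification stabilizes small classes),
with the feature extractor refit on each training split only — validation
labels are never visible to any fitting step, and a pure-noise fixture in
the test suite checks that accuracy stays at chance. Multiclass problems
can also be decomposed into all `C(k,2)` pairwise binary tasks in
lexicographic order.

## Synthetic study conditions

`gen_trials` emulates the statistics the methods assume: per trial
`X = Σ_c^{1/2}E` (iid normal `E`, class-dependent SPD spatial covariance),
plus an optional class-band sinusoidal rhythm with a fixed per-class
spatial pattern, a rank-r common background, Bernoulli artifact spikes,
and whole-trial amplitude scaling for outliers. Defaults — fixed once as
the study conditions — are 10 channels, 250 Hz, 500-sample trials, 60
trials/class, two classes with swapped high-variance channel blocks
(contrast 4), rhythm bands 10–12 Hz and 20–24 Hz, background rank 2,
artifact density 0.005 at amplitude 8, and a 0.1 outlier fraction at scale
10. Generators are pure functions of spec + seed, with per-trial
sub-streams keyed by `(seed, trial index)` so enlarging a set never
perturbs earlier trials.

What the generators do **not** emulate: physiological forward modeling,
realistic EOG/EMG waveforms, non-stationarity across a session,
inter-subject variability. Passing tests therefore establish that the
algorithms behave as their theory predicts on data satisfying their
assumptions — not performance on real recordings.

The support-recovery conditions are 20 features with 2 informative rows
carrying a shared factor at SNR 9, 100 samples, 10% gross outlier columns
(sd 10), 20 seeded replicates; penalties (`λ = 12` for the ℓ₂,₁ variants,
`λ₂ = 12` for SPCA on `X/√n`; `λ_b = 1200` for RJSPCA against its
unnormalized trial scatter) are set to the scale of the respective Gram
matrices. The classifier robustness conditions are rank-1 discriminative
trials (unit pattern, noise sd 0.6), 60 training trials with 10%
amplitude-×10 outliers, clean test sets, 20 replicates.

## Known limitations

- The ℓ₂,₁ loss caps outlier influence linearly, not boundedly; sufficiently
  extreme corruption still biases JSPCA/RJSPCA.
- ADMM residual tolerances (`1e−4`) mean decision values of the RSMM are
  reproducible but not exact minimizers; the incumbent rule guarantees the
  reported objective, not global optimality.
- `cross_validate` exposes only the feature methods and classifiers of this
  package; it is an evaluation harness, not a general pipeline engine.
- The archive format stores one text matrix per trial; it is meant for
  small sessions and fixtures, not hour-long recordings.
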