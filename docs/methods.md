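# Methods

## Problem setting

The inverse ECG problem treated here is the reconstruction of ventricular
transmembrane potentials (TMPs) `φ_m(t)` at `n_nodes` source nodes from
body-surface potentials (BSPs) `φ_B(t)` at `n_leads` torso leads, linked by
a linear equivalent-double-layer forward operator `φ_B = A·φ_m`. Because
`A`'s singular values span ~12 orders of magnitude, the problem is treated
as a statistical regression from BSP instants to TMP instants instead of a
per-instant linear inversion: a training set of paired instants fits the
regression, and unseen instants are reconstructed by prediction.

## Maximum margin clustering

Each training instant is one sample; its feature vector is the BSP lead
vector min-max scaled to [0, 1] *within that instant* (each instant uses
its own extrema, for train and test alike — the wide dynamic range across
the beat makes a global scaling useless). MMC looks for the binary labeling
of these samples that maximizes the SVM margin subject to the class-balance
bound `|Σ yᵢ| ≤ ℓ`, and is solved by alternating minimization:

- **SVR step** — with labels fixed, fit a Gaussian-kernel SVR with
  Laplacian loss (ε-insensitive loss at ε = 0) to the ±1 labels. This
  minimizes `½‖ω‖² + C Σ(ξᵢ+ξᵢ*)` in its dual form.
- **Label step** — with `ω` fixed, minimize `Σᵢ |ω·φ(xᵢ) + b − yᵢ|` exactly
  over `(b, y)`. The optimal labeling is monotone in the decision score
  (for fixed `b` the flip cost is monotone in the score, so a
  balance-constrained optimum flips points nearest the threshold), so the
  implementation scans all n+1 threshold labelings in sorted-score order,
  assigns each feasible labeling its closed-form optimal bias
  `b = median(yᵢ − scoreᵢ)`, and keeps the least objective. This scan is
  verified against exhaustive enumeration over all feasible labelings in
  the test suite.

The alternation stops when the label vector repeats any previously seen
labeling (fixed points and cycles both stop it; only a fixed point counts
as converged) or after `max_iter = 50` iterations. Two objective traces are
recorded per split: the label-step objective `Σ|score + b − y|` and the
full regularized objective `‖ω‖² + 2C Σ|f(xᵢ) − yᵢ|`. Alternating
minimization guarantees monotone descent of the *full* objective (each
half-step minimizes it over its block); the label-step value alone carries
no such guarantee, so monotonicity is asserted on the full trace, with a
relative tolerance of 1e−6 because the SMO solver is an inexact minimizer.

Choices left open by the formulation, fixed here:

- **k > 2 clusters** by recursive bisection of depth log₂k (the margin
  formulation is inherently binary). Leaves are numbered in tree order; a
  branch with fewer than 2 samples stops early and is recorded.
- **Initialization**: sign of the first principal component's centered
  scores, rebalanced to `|Σy| ≤ ℓ` by flipping majority points nearest the
  hyperplane; a seeded random balanced initializer is available.
- **Balance bound** default `ℓ = ⌈0.2 n⌉` (at most a 40/60 split).
- **MMC kernel parameters** are not tuned: σ defaults to the median
  pairwise distance, C = 1. Clustering has no supervised objective to tune
  against; only the regression SVRs are searched.
- **Ties**: a decision value of exactly 0 routes to the positive side.

## Support vector regression

The ε-SVR dual is solved by libsvm's SMO (via scikit-learn) with a
precomputed Gaussian Gram matrix shared across all output nodes of a
cluster; the fitted model is held in dual form (support inputs, dual
coefficients `βᵢ = αᵢ − αᵢ* ∈ [−C, C]` with `Σβᵢ = 0`, bias). One
single-output SVR per TMP node shares (C, σ, ε) within a cluster — a
per-node search would multiply the tuning cost by the node count for
little benefit. TMP targets are used unscaled (millivolts); only BSP
inputs are scaled. Degenerate inputs (constant BSP vectors, which the
per-instant scaling cannot map) raise a dedicated error.

Correctness is checked against an independent generic-QP solve of the
dual (SLSQP on the 2n-dimensional box with the equality constraint) at
1e−4 relative on the dual objective, plus KKT tube conditions on
non-support points. Fits whose SMO iteration count exceeds a cap raise a
solver error; during hyperparameter search such points simply receive
worst fitness, which steers the search away from untrainable corners
(e.g. very large C with ε = 0).

## Hyperparameter search

A real-coded GA (tournament size 2, BLX-0.5 crossover at rate 0.8,
Gaussian mutation with σ = 10 % of each axis range at rate 0.3, elitism 1)
searches (log₁₀C, log₁₀σ, ε) over C ∈ [1e−2, 1e4], σ ∈ [1e−2, 1e2],
ε ∈ [0, 0.5]; Nelder–Mead then refines the GA's best point, clamped to the
box, never returning a worse point. The fitness is k-fold cross-validated
MSE of the multi-output SVR, averaged over folds and output nodes; a
seeded subset of output nodes can be probed instead of all of them, and an
optional total-evaluation cap degrades the search to best-so-far. The
sphere-function recovery rate and a dense-grid comparison on a learnable
toy regression are tested.

## Linear baselines

Zero-order Tikhonov, `min ‖Ax − b‖² + λ²‖x‖²`, is solved in SVD
filter-factor form; the SVD of `A` is computed once and reused across all
instants and λ values. λ is selected per instant as the L-curve corner:
the curvature of `(log‖Ax−b‖, log‖x‖)` is evaluated *analytically* from
the filter factors (no finite differences) on a 40-point log grid spanning
the singular-value range, extended three decades below the smallest
singular value. If no grid point has curvature above 0.1 the curve has no
convex corner — characteristic of noise-free consistent data — and the
smallest λ is chosen. LSQR (scipy's Golub–Kahan implementation) is
regularized by early stopping, with the iteration count chosen by the same
corner logic over ~25 log-spaced iteration counts; its iterates are
checked against an independently written textbook recursion. Both
monotonicity properties (solution norm down, residual up in λ) and the
semi-convergence of LSQR under noise are asserted.

## Synthetic forward protocol

The generator emulates a normal ventricular excitation:

- **Action potentials**: piecewise-smooth templates (cubic smoothstep
  upstroke of ~2 ms, plateau with optional linear sag, smoothstep
  repolarization), exactly at rest before activation and after full
  repolarization. Four template classes with APDs 270/230/200/160 ms are
  assigned to contiguous node blocks, giving the distinct temporal regimes
  the clustering is supposed to discover.
- **Activation**: nodes on a spheroidal point cloud activate at
  distance-to-nearest-breakthrough over conduction velocity (3 breakthrough
  sites by default), rescaled so depolarization spans roughly the first
  third of the record; t = 0 is the first breakthrough.
- **Transfer matrix**: random orthogonal factors around a geometric
  singular spectrum give exact condition-number control (412 × 478 at
  5.6×10¹² by default; realized condition verified within 1 %). A
  quasi-physical 1/r² lead field is not used because it cannot be
  condition-controlled.
- **Noise**: white Gaussian at a *global* 30 dB SNR (power ratio over the
  whole BSP matrix — the per-lead/per-instant alternative is a
  convention choice; the global one is recorded in metadata).
- **Record**: 358 instants (0–357 ms at 1 ms); test instants at
  3, 9, …, 357 ms (60), training on the remaining 298.

What the generator does *not* emulate: realistic torso/heart geometry and
boundary-element lead fields, pathological excitation, correlated
electrode noise, baseline wander, or beat-to-beat variability. Passing
tests therefore demonstrate the method's behavior under the idealized
statistical structure of the protocol, not clinical performance.

## Experiment sizes and determinism

The default simulation is full scale (412 × 478). The comparison
experiments and the acceptance script use a reduced protocol —
60 leads × 80 nodes, all 358 instants, GA budget pop 6 × 4 generations,
3-fold CV probing 10 output nodes, 15 simplex steps — which preserves the
qualitative comparison (MMC-SVR ≤ single SVR < Tikhonov/LSQR in mean RE)
at about half a minute per seed. Every stochastic component (simulation,
initialization, GA, CV folds, output subsampling) derives from a single
integer seed; cluster c of a reconstructor uses `random_state + c`, so the
one-cluster reconstructor is bit-identical to the single-SVR model with
the same seed. Two runs of `run_experiment` with equal configs produce
byte-identical report files.

## Known limitations

- Recursive bisection fixes the cluster count to a power of two and can
  split a natural cluster across subtrees; no cluster-number selection is
  attempted.
- The L-curve corner can misplace λ by several grid steps on problems with
  very steep (super-exponential) spectra; it is reliable on
  Picard-regular spectra like the geometric ones generated here.
- LSQR's per-instant mean RE is occasionally inflated by instants whose
  L-curve corner overshoots the semi-convergence point.
- Per-instant input scaling maps near-resting instants (whose BSP columns
  are almost proportional) to nearly identical feature vectors with
  different targets, bounding achievable accuracy at the very start of the
  record regardless of hyperparameters.
- With ε = 0 and large C the SMO solver may exceed its iteration cap;
  such corners are reported (or penalized during search) rather than
  silently accepted.
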