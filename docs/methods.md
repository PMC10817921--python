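# Methods

## The projection filter

The package removes a user-specified signal from a cells × features matrix
`X` by subtracting the expectation of expression under a cell–cell similarity
distribution. The similarity kernel `K` is row-stochastic, so the projection
`P = K·X` is a convex combination of (target-) cell expression and stays on
the scale of `X`; the filtered matrix `X̃ = X − P` is each cell's deviation
from what cells carrying the same signal state express. The model is entirely
linear: filtering is idempotent for projection kernels built from one-hot
labels (within-class centering), linear in `X` for fixed `K`, and kernel rows
are independent, which is what makes row-wise batching exactly equivalent to
the unbatched product.

The method assumes the signal to remove is *expressed* in the feature space —
it subtracts the conditional mean given the mapping, nothing more. Variance
components uncorrelated with the mapping survive untouched; nonlinear
interactions between the filtered signal and hidden signals are not removed.

Input is expected to be log-normalized expression. Raw counts are
mathematically acceptable but the interpretation of the subtraction (and the
pseudocount) is then unclear; the package documents rather than enforces
this. After filtering, values are no longer properly log-transformed — this
is inherent to the subtraction and deliberately not "fixed".

## Kernels

**Mapping kernel.** `K = A·Bᵀ`, where `A` is the source rows of `T`
normalized across mapping columns (`p(label | cell)`) and `B` the target rows
normalized within each column (`p(cell | label)`). Row-stochasticity is
structural: each row of `K` sums to `Σ_μ p(μ|i)·Σ_j p(j|μ) = 1`. Mapping
columns with zero mass over the target set carry no filterable signal and are
dropped with a warning; source rows are re-normalized over the remaining
columns (the only way to keep `K` stochastic after the drop), and a source
cell left with no mass raises an error naming it. Continuous scalars are
discretized by `binned_mapping` into `M` equal-width bins, half-open
`[min, max)` with the maximum closed: `bin = floor((v − min)/width)` clipped
to `M − 1`; the midpoint of a 2-bin range therefore lands in the upper bin.

**knn kernel.** Exact nearest-neighbor search (full pairwise distances,
lexicographic tie-break on the target index so duplicated points are handled
deterministically), `k = 15` by default following the common single-cell
neighborhood default. Edge weights: `umap` (default) computes fuzzy
connectivity weights `exp(−max(d − ρ, 0)/σ)` with `ρ, σ` from the standard
smoothed-knn calibration; `binary` and `inverse_distance` (`1/(d+1e−12)`)
modes exist for exact testability. No fuzzy-union symmetrization is applied:
symmetrizing would add edges outside a row's k-neighbor set, and we keep the
guarantee that each row's support is exactly its k nearest targets. The self
edge is excluded by default (knn-graph convention); `include_self=True`
overrides. The kernel is stored sparse.

**Distance kernel.** `K_ij = exp(−γ·d_ij)/Z_i` with `Z_i` the row sum. The
formula uses the distance `d`, not `d²`, also for the euclidean metric (an
RBF-style similarity on `d`; the Laplacian kernel for manhattan). `γ` (units:
1/distance) controls the effective radius of influence; `γ = 0` is an
explicit uniform-kernel mode, and the default `γ = 1/median(d)` over a
subsample of source–target distances adapts to the scale of the mapping and
is always recorded in the kernel's parameter record. Exponentiation is
stabilized by shifting each row by its minimum distance
(`exp(−γ(d − min d))`, exponents ≤ 0) before normalization.

**Precomputed kernels** are validated (non-negative, no zero rows, rows
summing to 1 within 1e−8) and optionally row-renormalized.

## Pseudocount

`α = min(X̃)` globally, `X̃⁺ = X̃ − α`. Per-feature means shift by `−α`,
variances and all pairwise feature differences are exactly preserved, so any
statistic built from differences of means plus variances (t test, rank tests)
is invariant. The shift is applied even when `min(X̃) > 0`, matching the
definition; the correction is off by default.

## Case–control filtering

With `source = cases` and `target = controls`, `K` is `n_case × n_control`
and `X̃` measures each case cell's deviation from its most similar healthy
cells; control rows pass through bit-identical. To call responder cells we
cluster the filtered case cells (KMeans, seeded, `n_clusters = 4` at the
default problem size — chosen for determinism over graph clustering) and
apply the cluster-purity score: a cluster of size `n` whose dominant label
covers `m` cells is *informative* when `m/n > τ`, default `τ = 0.55`, strict
inequality, ties on the dominant label broken lexicographically. Cells in
informative clusters dominated by the responder label are predicted
responders. The purity score is the package's implementation of the
homogeneity measure; the classification rule built on top of it is our own
construction.

## Synthetic data

All generators simulate log-scale expression with additive Gaussian noise
and are bit-reproducible under a seed; a negative-binomial count mode exists
behind a flag. Defaults are fixed once: effect sizes 1.0 log-units, noise sd
0.5 (two-signal) / 0.3 (others) — strong enough that direction-of-change
assertions are stable, weak enough that nothing is trivially separable from
noise alone.

- *two_signal*: 600 cells × 200 genes, 3 color × 3 shape classes assigned
  independently and uniformly; disjoint blocks of 20% of genes per signal
  (rest background), each class a fixed Gaussian archetype over its block.
- *subclone*: a 279-cell cycling base (angle on the unit circle, 3 discrete
  phases, 30% cycle genes following `cos(θ + offset)`); the clone doubles a
  random gene subset on the linear scale (`log1p(2·expm1(x))`), mixing cycle
  and non-cycle genes.
- *spatial*: a `20×20` lattice with a Gaussian-bump mixture field (length
  scale 4 lattice units) on half the genes plus a 40-cell global
  subpopulation program on the other half.
- *case_control*: 300 + 300 cells sharing a rank-5 latent manifold; 25% of
  cases add a response program (effect 1.0) on the last quarter of genes.

What passing these tests shows: the filter removes exactly the mapped signal
and exposes an orthogonal one under additive Gaussian structure. What it does
not show: robustness to dropout, batch effects, library-size artifacts or
nonlinear signal mixing — the generators do not model them.

Regression fixtures (hidden-label accuracy after filtering, responder
recall) were computed once from these generators at their defaults with seed
0 and frozen in the test suite; they pin the exact behavior of the
implementation rather than an external reference.

## Numerical choices

- Projection accumulates in float64 regardless of input dtype (the final
  subtraction cancels leading digits).
- Kernel row-sum tolerance 1e−8; validation rejects anything worse.
- knn ties: lowest target index wins; binning: maximum closed into the last
  bin; purity ties: lexicographically smallest label.
- Auto-batching sizes row blocks from a 256 MiB budget and logs the choice;
  batched and unbatched paths are required identical within 1e−8 (tested at
  1, 7 and N rows).

## Problem sizes

Tests and the acceptance script run at N ≤ 600 cells and G ≤ 200 genes —
sizes chosen so the whole suite exercises every kernel family, both mask
layouts and all three synthetic studies in well under a minute while keeping
brute-force oracle comparisons (triple-loop kernels, exhaustive knn)
tractable.

## Known limitations

- Exact neighbor search only; no approximate index, so kernel construction
  is quadratic in cells. The batching contract bounds memory, not time.
- The UMAP weighting exposes no tuning of the fuzzy-calibration parameters;
  use `binary`/`inverse_distance` when exact weights matter.
- The HVG overlap metric ranks by plain per-feature variance of the corrected
  matrix; equivalence with dispersion-based highly-variable-gene selections
  used elsewhere is not claimed.
- Latent-space inputs (features that are not genes) are accepted, but the
  pseudocount correction has no clear interpretation there.
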