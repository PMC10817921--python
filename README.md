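# cellsift

Kernel-projection filtering of biological signals in single-cell expression
data.

Single-cell datasets superimpose many biological signals at once — spatial
zonation, cell-cycle phase, a healthy reference trajectory — and a dominant
signal can mask the structure an analyst actually cares about (a circadian
program, a tumor subclone, a disease response). `cellsift` removes a *known*
signal at the gene-expression level so that hidden structure resurfaces, and
works for any signal the user can describe by a per-cell mapping: a
categorical label, a pseudotime, an embedding, a marker-gene panel, or a
ready-made kernel.

## Method

Given an expression matrix `X ∈ ℝ^{N×G}` (cells × features, ideally
log-normalized) and a per-cell mapping `T ∈ ℝ^{N×M}` describing the signal to
remove, the procedure is:

1. **Kernel** — build a row-stochastic cell–cell similarity kernel
   `K ∈ [0,1]^{N×N}`: each row is a probability distribution expressing how
   similar cell *i* is to every other cell *with respect to the mapped
   signal*. Three constructions are provided:
   - *mapping kernel*: `K = A·Bᵀ` where `A` normalizes `T` across labels
     (`p(label | cell)`) and `B` normalizes `T` across cells
     (`p(cell | label)`); one-hot labels give uniform within-class averaging;
   - *knn kernel*: row-normalized weighted adjacency of the k-nearest-neighbor
     graph in mapping space (UMAP fuzzy-connectivity, binary, or
     inverse-distance edge weights);
   - *distance kernel*: `K_ij = exp(−γ·d(T_i,T_j)) / Z_i` — a per-row softmax
     of negative scaled distances (RBF-style for euclidean `d`, Laplacian for
     manhattan).
2. **Project** — `P = K·X`: row *i* of `P` is the expected expression under
   cell *i*'s similarity distribution.
3. **Filter** — `X̃ = X − P`: each cell's deviation from the expression
   expected of its signal-neighbors. `X̃` can be negative; an optional
   pseudocount `α = min(X̃)`, `X̃⁺ = X̃ − α` restores non-negativity while
   preserving per-gene variances and all pairwise gene differences (so t /
   Wilcoxon tests are unaffected).

Source and target cell sets may differ: filtering disease cells against a
healthy reference (`K` of shape `n_disease × n_healthy`) leaves the reference
untouched and turns `X̃` into a per-cell disease signature.

## Worked example

```python
import cellsift as cs
from cellsift import synthdata as sd
from cellsift.evaluate import label_separability

# 600 cells x 200 genes; every cell has a "color" label (to filter) and an
# independent "shape" label (hidden underneath)
X, truth = sd.two_signal_dataset(n_cells=600, n_genes=200, seed=0)

model = cs.SiftModel(
    X, mapping=cs.CellMapping.from_labels(truth.filtered_signal_label),
    kernel="mapping")
res = model.fit()
print(res.summary())

for name, M in [("raw", X.values), ("sifted", res.filtered)]:
    print(name,
          "color:", label_separability(M, truth.filtered_signal_label, seed=0),
          "shape:", label_separability(M, truth.hidden_signal_label, seed=0))
```

prints

```
Projection filter results
=========================================
kernel kind:            mapping
source x target:        600 x 600
max |row sum - 1|:      1.110e-16
filtered range:         [-3.3631, 3.5466]
variance removed (R^2): 0.2749
  bins: None
  mapping_kind: labels
raw color: 1.0 shape: 1.0
sifted color: 0.26666666666666666 shape: 1.0
```

Before filtering, a knn classifier separates both labels perfectly. After
filtering the color signal, color separability collapses to chance (1/3 for
three classes) while the hidden shape signal remains fully separable — the
filter removed exactly the targeted signal.

The same flow is available from the shell:

```bash
sift simulate --scenario two_signal --seed 0 --output sim.h5ad
sift filter --input sim.h5ad --kernel mapping --mapping-obs filtered_signal \
     --output sifted.h5ad
sift evaluate purity --input sifted.h5ad --cluster-obs cluster --type-obs cell_type
```

`sift filter` writes the filtered matrix to `layers/sift` (the original `X`
is never overwritten) and records every resolved parameter (kernel kind, k,
γ, seed, version) in `uns['sift']`.

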