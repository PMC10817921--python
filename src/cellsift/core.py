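"""Shared domain types: expression matrix, cell mapping, similarity kernel,
filter result, and input validation.

Conventions used throughout the package: cells are rows, features are columns,
indices are 0-based, and the mapping T shares the cell order of X (no implicit
reordering by id — misaligned inputs must fail loudly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.sparse as sp

ROW_SUM_TOL = 1e-8

MappingKind = Literal[
    "labels", "continuous_scalar", "embedding", "marker_genes", "precomputed_kernel"
]
KernelKind = Literal["mapping", "knn", "distance", "precomputed"]


def _as_2d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dups))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A cells (N) x features (G) numeric matrix with identifiers.

    Values are expected to be pre-processed (log-normalized) expression, but
    any finite per-cell representation (e.g. a latent space) is accepted.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = _as_2d_float(self.values, "values")
        n, g = self.values.shape
        if n < 1 or g < 1:
            raise ValueError(f"matrix must be at least 1x1, got {n}x{g}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN or Inf entries")
        self.cell_ids = _check_unique(self.cell_ids, "cell ids")
        self.feature_ids = _check_unique(self.feature_ids, "feature ids")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.feature_ids) != g:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {g} columns")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        """Build from a pandas DataFrame (cells as rows, features as columns)."""
        return cls(
            values=df.to_numpy(dtype=np.float64),
            cell_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
        )


@dataclass
class CellMapping:
    """Per-cell representation T (N x M) of the signal to filter.

    ``kind`` records how T was obtained; for ``labels`` every row must be a
    probability row (non-negative, summing to one) — one-hot rows are the
    common deterministic case.
    """

    T: np.ndarray
    kind: MappingKind = "embedding"
    bins: Optional[int] = None
    label_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.T = _as_2d_float(self.T, "T")
        if not np.all(np.isfinite(self.T)):
            raise ValueError("mapping T contains NaN or Inf entries")
        if self.T.shape[1] < 1:
            raise ValueError("mapping must have at least one dimension")
        if self.kind == "labels":
            if np.any(self.T < 0):
                raise ValueError("label mapping must be non-negative")
            rs = self.T.sum(axis=1)
            bad = np.where(np.abs(rs - 1.0) > 1e-6)[0]
            if bad.size:
                if np.all(rs[bad] > 0):
                    self.T = self.T / rs[:, None]
                else:
                    raise ValueError(
                        f"label mapping rows {bad[:5].tolist()} have zero mass"
                    )
        if self.label_names is not None and len(self.label_names) != self.T.shape[1]:
            raise ValueError("label_names length must equal mapping width M")

    @property
    def n_cells(self) -> int:
        return self.T.shape[0]

    @property
    def n_dims(self) -> int:
        return self.T.shape[1]

    @classmethod
    def from_labels(cls, labels: Sequence) -> "CellMapping":
        """One-hot encode a categorical per-cell annotation."""
        labels = np.asarray(labels)
        names = sorted({str(x) for x in labels})
        idx = {v: j for j, v in enumerate(names)}
        T = np.zeros((len(labels), len(names)))
        for i, lab in enumerate(labels):
            T[i, idx[str(lab)]] = 1.0
        return cls(T=T, kind="labels", label_names=names)


@dataclass
class DistanceSpec:
    """Distance configuration for knn and distance kernels.

    gamma is the smoothing parameter of the distance kernel: it sets the
    effective radius beyond which cells stop contributing similarity mass.
    gamma=0 is permitted as an explicit uniform-kernel mode; None requests
    the scale-adaptive default 1/median(distance).
    """

    metric: Literal["euclidean", "manhattan", "precomputed"] = "euclidean"
    gamma: Optional[float] = None
    k: int = 15

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")


@dataclass
class SimilarityKernel:
    """Row-stochastic N_source x N_target similarity matrix.

    Row i is a probability distribution over target cells expressing the
    similarity of source cell i with respect to the mapped signal.
    """

    K: "np.ndarray | sp.spmatrix"
    source_index: np.ndarray
    target_index: np.ndarray
    kernel_kind: KernelKind = "precomputed"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.source_index = np.asarray(self.source_index, dtype=np.intp)
        self.target_index = np.asarray(self.target_index, dtype=np.intp)
        ns, nt = self.shape
        if ns != len(self.source_index) or nt != len(self.target_index):
            raise ValueError(
                f"kernel shape {self.shape} does not match index lists "
                f"({len(self.source_index)}, {len(self.target_index)})"
            )
        data = self.K.data if sp.issparse(self.K) else self.K
        if not np.all(np.isfinite(data)):
            raise ValueError("kernel contains NaN or Inf entries")
        if np.any(np.asarray(data) < 0):
            raise ValueError("kernel contains negative entries")
        dev = self.max_row_sum_deviation()
        if dev > ROW_SUM_TOL:
            raise ValueError(
                f"kernel is not row-stochastic: max |row sum - 1| = {dev:.3g}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.K.shape

    def row_sums(self) -> np.ndarray:
        if sp.issparse(self.K):
            return np.asarray(self.K.sum(axis=1)).ravel()
        return self.K.sum(axis=1)

    def max_row_sum_deviation(self) -> float:
        return float(np.max(np.abs(self.row_sums() - 1.0)))

    def toarray(self) -> np.ndarray:
        return self.K.toarray() if sp.issparse(self.K) else np.asarray(self.K)


@dataclass
class FilterResult:
    """Output of the projection filter.

    filtered = source rows of X minus the projection; it may contain negative
    values (features below the expected expression in similar cells). The
    optional pseudocount alpha = min(filtered) shifts the matrix so its
    minimum is zero, preserving per-feature variances and all pairwise
    feature differences.
    """

    projection: np.ndarray
    filtered: np.ndarray
    pseudocount: Optional[float] = None
    filtered_corrected: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.projection.shape != self.filtered.shape:
            raise ValueError("projection and filtered must have the same shape")


def _resolve_mask(mask, n: int, what: str) -> np.ndarray:
    if mask is None:
        return np.arange(n, dtype=np.intp)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != (n,):
            raise ValueError(f"{what} mask must have length {n}, got {mask.shape}")
        idx = np.flatnonzero(mask)
    else:
        idx = mask.astype(np.intp)
        if idx.size and (idx.min() < 0 or idx.max() >= n):
            raise ValueError(f"{what} indices out of range [0, {n})")
    if idx.size == 0:
        raise ValueError(f"empty {what} set")
    return np.asarray(idx, dtype=np.intp)


def validate_inputs(
    X: ExpressionMatrix,
    T: CellMapping,
    source_mask=None,
    target_mask=None,
) -> tuple[ExpressionMatrix, CellMapping, np.ndarray, np.ndarray]:
    """Check X/T alignment and resolve source/target masks to index lists.

    The mapping must share X's cell order. Masks may be boolean N-vectors or
    integer index arrays; the default for both is all cells. Unequal
    source/target sets implement case-control reference filtering (e.g.
    source = disease cells, target = healthy reference).
    """
    if T.n_cells != X.n_cells:
        raise ValueError(
            f"mapping has {T.n_cells} rows but expression matrix has "
            f"{X.n_cells} cells; T must share X's cell order"
        )
    source_index = _resolve_mask(source_mask, X.n_cells, "source")
    target_index = _resolve_mask(target_mask, X.n_cells, "target")
    return X, T, source_index, target_index


def as_expression_matrix(X, cell_ids=None, feature_ids=None) -> ExpressionMatrix:
    """Coerce a raw array / DataFrame / ExpressionMatrix to ExpressionMatrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if hasattr(X, "to_numpy") and hasattr(X, "index"):  # DataFrame
        return ExpressionMatrix.from_dataframe(X)
    arr = np.asarray(X, dtype=np.float64)
    n, g = arr.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(n)]
    if feature_ids is None:
        feature_ids = [f"gene_{j}" for j in range(g)]
    return ExpressionMatrix(arr, list(cell_ids), list(feature_ids))
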