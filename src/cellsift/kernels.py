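"""Construction of the row-stochastic cell-cell similarity kernels.

Three families are provided, differing in the prior knowledge they require
of the mapping T:

* ``mapping_kernel`` — T assigns cells to a low-dimensional domain (discrete
  classes or a binned continuum); the kernel is the double normalization of T,
  summing out the domain dimension. One-hot assignments reduce to uniform
  within-class averaging.
* ``knn_kernel`` — T is any representation with a distance metric; the kernel
  is the row-normalized weighted adjacency of the k-nearest-neighbor graph in
  mapping space.
* ``distance_kernel`` — a per-row softmax of negative scaled distances,
  exp(-gamma * d(T_i, T_j)) / Z_i: the RBF-style kernel for the euclidean
  metric, the Laplacian kernel for manhattan.

All constructors accept source/target index lists so that similarity can be
evaluated against a reference subset (case-control filtering).
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import pairwise_distances

from .core import CellMapping, DistanceSpec, SimilarityKernel

logger = logging.getLogger(__name__)

_METRICS = {"euclidean", "manhattan", "precomputed"}


def _indices(idx, n) -> np.ndarray:
    if idx is None:
        return np.arange(n, dtype=np.intp)
    return np.asarray(idx, dtype=np.intp)


def mapping_kernel(
    T: CellMapping,
    source_index=None,
    target_index=None,
) -> SimilarityKernel:
    """Kernel from a cell-to-domain assignment matrix by double normalization.

    With A the source rows of T normalized across domain columns (probability
    of a domain label given the cell) and B the target rows of T normalized
    across cells within each column (probability of a cell given the label),
    the kernel is K = A @ B.T — the expectation over labels of the
    cell-given-label distribution, which is row-stochastic by construction.

    Domain columns with zero mass over the target cells carry no filterable
    signal; they are dropped with a warning and the source rows re-normalized
    over the remaining columns. A source cell whose entire mass sat in dropped
    columns (it maps nowhere in the reference) raises an error naming it.
    """
    M = np.asarray(T.T, dtype=np.float64)
    if np.any(M < 0):
        raise ValueError("mapping kernel requires a non-negative mapping T")
    n = M.shape[0]
    src = _indices(source_index, n)
    tgt = _indices(target_index, n)

    col_mass = M[tgt].sum(axis=0)
    keep = col_mass > 0
    if not np.all(keep):
        dropped = np.flatnonzero(~keep)
        names = (
            [T.label_names[j] for j in dropped]
            if T.label_names is not None
            else dropped.tolist()
        )
        warnings.warn(
            f"dropping {dropped.size} mapping column(s) with zero mass over "
            f"target cells: {names[:10]}",
            UserWarning,
            stacklevel=2,
        )
        logger.warning("mapping kernel dropped zero-target-mass columns: %s", names)
        M = M[:, keep]
        col_mass = col_mass[keep]

    row_mass = M[src].sum(axis=1)
    dead = np.flatnonzero(row_mass == 0)
    if dead.size:
        raise ValueError(
            f"source cell(s) at positions {src[dead][:5].tolist()} have zero "
            "mapping mass (map to no label present in the target set)"
        )

    A = M[src] / row_mass[:, None]          # p(label | source cell)
    B = M[tgt] / col_mass[None, :]          # p(target cell | label)
    K = A @ B.T
    return SimilarityKernel(
        K=K,
        source_index=src,
        target_index=tgt,
        kernel_kind="mapping",
        params={"bins": T.bins, "mapping_kind": T.kind},
    )


def binned_mapping(values: Sequence[float], M: int) -> CellMapping:
    """Discretize a continuous per-cell scalar into M equal-width one-hot bins.

    Bins are half-open [min, max) with the maximum closed into the last bin,
    i.e. bin = floor((v - min) / width) clipped to M - 1.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError("binned mapping requires finite values")
    if M < 2:
        raise ValueError(f"number of bins M must be >= 2, got {M}")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("cannot bin a constant variable (zero range)")
    width = (hi - lo) / M
    bins = np.minimum((v - lo) // width, M - 1).astype(np.intp)
    T = np.zeros((v.size, M))
    T[np.arange(v.size), bins] = 1.0
    return CellMapping(
        T=T, kind="labels", bins=M, label_names=[f"bin_{b}" for b in range(M)]
    )


def _pairwise(
    T_src: np.ndarray, T_tgt: np.ndarray, metric: str
) -> np.ndarray:
    if metric not in _METRICS:
        raise ValueError(f"unsupported metric {metric!r}; use one of {_METRICS}")
    if metric == "precomputed":
        D = np.asarray(T_src, dtype=np.float64)
        if D.shape != (T_src.shape[0], T_tgt.shape[0]):
            raise ValueError(
                "precomputed metric expects T to hold the source x target "
                f"distance matrix; got {D.shape}"
            )
        return D
    D = pairwise_distances(T_src, T_tgt, metric=metric)
    return np.asarray(D, dtype=np.float64)


def default_gamma(
    D: np.ndarray, rng: Optional[np.random.Generator] = None, max_pairs: int = 100_000
) -> float:
    """Scale-adaptive default smoothing: 1 / median(positive distances)."""
    d = D.ravel()
    if d.size > max_pairs:
        rng = rng or np.random.default_rng(0)
        d = rng.choice(d, size=max_pairs, replace=False)
    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("all distances are zero; cannot set a default gamma")
    return float(1.0 / np.median(pos))


def distance_kernel(
    T: CellMapping,
    spec: DistanceSpec | None = None,
    source_index=None,
    target_index=None,
) -> SimilarityKernel:
    """Softmax-of-negative-distance kernel K_ij = exp(-gamma d_ij) / Z_i.

    Z_i is the row sum, so each row is a probability distribution over target
    cells. The exponent is shifted by the row minimum distance before
    exponentiation for numerical stability. gamma=0 gives the explicit uniform
    kernel (every target weighted 1/N_target); gamma=None picks the
    scale-adaptive default 1/median(d), which is recorded in params.

    When source and target sets overlap, the self term is included with weight
    exp(0) as the formula implies; pass the distances through a precomputed
    metric to override.
    """
    spec = spec or DistanceSpec()
    M = np.asarray(T.T, dtype=np.float64)
    n = M.shape[0]
    src = _indices(source_index, n)
    tgt = _indices(target_index, n)
    D = _pairwise(M[src], M[tgt], spec.metric)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances in distance kernel")

    gamma = spec.gamma
    if gamma is None:
        gamma = default_gamma(D)
        logger.info("distance kernel: auto gamma = %.6g", gamma)
    if gamma == 0:
        K = np.full(D.shape, 1.0 / D.shape[1])
    else:
        E = -gamma * D
        E -= E.max(axis=1, keepdims=True)  # softmax stability shift
        K = np.exp(E)
        K /= K.sum(axis=1, keepdims=True)
    return SimilarityKernel(
        K=K,
        source_index=src,
        target_index=tgt,
        kernel_kind="distance",
        params={"gamma": float(gamma), "metric": spec.metric},
    )


def _umap_weights(knn_dists: np.ndarray, k: int) -> np.ndarray:
    """Fuzzy-connectivity edge weights exp(-max(d - rho, 0) / sigma) per row."""
    from umap.umap_ import smooth_knn_dist

    order = np.argsort(knn_dists, axis=1, kind="stable")
    sorted_d = np.take_along_axis(knn_dists, order, axis=1).astype(np.float32)
    sigmas, rhos = smooth_knn_dist(sorted_d, float(k))
    sigmas = np.maximum(sigmas.astype(np.float64), 1e-12)
    w = np.exp(-np.maximum(knn_dists - rhos[:, None], 0.0) / sigmas[:, None])
    return w


def knn_kernel(
    T: CellMapping,
    spec: DistanceSpec | None = None,
    source_index=None,
    target_index=None,
    weighting: str = "umap",
    include_self: bool = False,
) -> SimilarityKernel:
    """Row-normalized weighted k-nearest-neighbor graph in mapping space.

    For each source cell the k nearest target cells under spec.metric are
    found by exact search; ties at the k-th distance keep the lowest target
    index. Edge weights: ``umap`` (default) — fuzzy connectivities as in the
    UMAP graph construction; ``binary`` — 1 for every neighbor;
    ``inverse_distance`` — 1/(d + 1e-12). Rows of the resulting sparse
    adjacency are normalized to sum to one.

    The self edge is excluded by default (standard knn-graph convention) when
    a source cell also appears in the target set.
    """
    spec = spec or DistanceSpec()
    if weighting not in ("umap", "binary", "inverse_distance"):
        raise ValueError(f"unknown weighting {weighting!r}")
    M = np.asarray(T.T, dtype=np.float64)
    n = M.shape[0]
    src = _indices(source_index, n)
    tgt = _indices(target_index, n)
    k = spec.k
    n_tgt = tgt.size

    D = _pairwise(M[src], M[tgt], spec.metric)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances in knn kernel")

    if k >= n_tgt:
        raise ValueError(f"k={k} must be smaller than the target set size {n_tgt}")
    # mask self edges where the same global cell is both source and target;
    # k < n_tgt guarantees enough finite neighbors remain in every row
    if not include_self:
        self_cols = {c: j for j, c in enumerate(tgt)}
        for i, c in enumerate(src):
            j = self_cols.get(c)
            if j is not None:
                D[i, j] = np.inf

    # deterministic ties: sort by (distance, target position)
    cols = np.arange(n_tgt)[None, :].repeat(D.shape[0], axis=0)
    order = np.lexsort((cols, D), axis=1)[:, :k]
    knn_idx = order
    knn_d = np.take_along_axis(D, order, axis=1)

    if weighting == "binary":
        W = np.ones_like(knn_d)
    elif weighting == "inverse_distance":
        W = 1.0 / (knn_d + 1e-12)
    else:
        W = _umap_weights(knn_d, k)

    rows = np.repeat(np.arange(D.shape[0]), k)
    K = sp.csr_matrix(
        (W.ravel(), (rows, knn_idx.ravel())), shape=(D.shape[0], n_tgt)
    )
    K = K.multiply(1.0 / np.asarray(K.sum(axis=1)).ravel()[:, None]).tocsr()
    return SimilarityKernel(
        K=K,
        source_index=src,
        target_index=tgt,
        kernel_kind="knn",
        params={"k": k, "metric": spec.metric, "weighting": weighting,
                "include_self": include_self},
    )


def precomputed_kernel(
    K_raw,
    source_index=None,
    target_index=None,
    renormalize: bool = False,
) -> SimilarityKernel:
    """Validate (optionally row-normalize) a user-supplied kernel matrix."""
    dense = not sp.issparse(K_raw)
    K = np.asarray(K_raw, dtype=np.float64) if dense else K_raw.astype(np.float64)
    data = K if dense else K.data
    if np.any(np.asarray(data) < 0):
        raise ValueError("precomputed kernel contains negative entries")
    rs = np.asarray(K.sum(axis=1)).ravel()
    if np.any(rs == 0):
        raise ValueError(
            f"precomputed kernel has zero rows at {np.flatnonzero(rs == 0)[:5].tolist()}"
        )
    if renormalize:
        K = K / rs[:, None] if dense else K.multiply(1.0 / rs[:, None]).tocsr()
    src = _indices(source_index, K.shape[0])
    tgt = _indices(target_index, K.shape[1])
    return SimilarityKernel(
        K=K,
        source_index=src,
        target_index=tgt,
        kernel_kind="precomputed",
        params={"renormalize": renormalize},
    )
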