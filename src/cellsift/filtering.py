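"""The projection filter: P = K @ X_target, X_tilde = X_source - P.

Row i of the projection is the expectation of expression under the similarity
distribution of cell i, so the filtered value is each cell's deviation from
the expected expression in its (signal-) neighboring cells. Filtered values
may be negative; the optional pseudocount shift restores non-negativity while
preserving per-feature variances and all pairwise feature differences.

Projection is accumulated in float64 regardless of input precision: the final
subtraction of near-equal quantities would otherwise lose precision. Batching
over source rows is exactly equivalent to the unbatched product because kernel
rows are independent.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .core import ExpressionMatrix, FilterResult, SimilarityKernel, as_expression_matrix

logger = logging.getLogger(__name__)

#: default memory budget (bytes) used to auto-size row batches
DEFAULT_BATCH_BUDGET = 256 * 1024 * 1024


def _auto_batch_rows(n_source: int, n_features: int, budget: int) -> int:
    rows = max(1, budget // max(8 * n_features, 1))
    return min(n_source, rows)


def project(
    K: SimilarityKernel,
    X,
    batch_rows: Optional[int] = None,
) -> np.ndarray:
    """Project expression onto the mapped signal: P = K @ X[target rows].

    Every entry of P is a convex combination of target expression, so each
    column of P lies within the range of that column over target cells.
    """
    X = as_expression_matrix(X)
    n_src, n_tgt = K.shape
    if K.target_index.max() >= X.n_cells or K.source_index.max() >= X.n_cells:
        raise ValueError("kernel indices exceed the expression matrix")
    Xt = np.asarray(X.values[K.target_index], dtype=np.float64)
    if Xt.shape[0] != n_tgt:
        raise ValueError(
            f"kernel has {n_tgt} target columns but {Xt.shape[0]} target rows resolved"
        )
    if batch_rows is None or batch_rows >= n_src:
        return _matmul(K.K, Xt)
    if batch_rows < 1:
        raise ValueError(f"batch_rows must be positive, got {batch_rows}")
    P = np.empty((n_src, Xt.shape[1]), dtype=np.float64)
    for start in range(0, n_src, batch_rows):
        stop = min(start + batch_rows, n_src)
        P[start:stop] = _matmul(K.K[start:stop], Xt)
    return P


def _matmul(K, Xt: np.ndarray) -> np.ndarray:
    if sp.issparse(K):
        return np.asarray(K @ Xt, dtype=np.float64)
    return np.asarray(K, dtype=np.float64) @ Xt


def sift(
    X,
    K: SimilarityKernel,
    pseudocount: bool = False,
    batch_rows: Optional[int | str] = None,
    batch_budget: int = DEFAULT_BATCH_BUDGET,
) -> FilterResult:
    """Subtract the kernel projection from the source rows of X.

    Only source rows are filtered; target-only cells are untouched (the
    caller keeps them as they were). ``batch_rows`` may be an integer, None
    (no batching) or ``"auto"`` (sized from ``batch_budget`` bytes).
    """
    X = as_expression_matrix(X)
    if batch_rows == "auto":
        batch_rows = _auto_batch_rows(K.shape[0], X.n_features, batch_budget)
        logger.info("auto batch_rows = %d", batch_rows)
    P = project(K, X, batch_rows=batch_rows)
    Xs = np.asarray(X.values[K.source_index], dtype=np.float64)
    filtered = Xs - P
    result = FilterResult(projection=P, filtered=filtered)
    if pseudocount:
        alpha, corrected = apply_pseudocount(filtered)
        result.pseudocount = alpha
        result.filtered_corrected = corrected
    return result


def apply_pseudocount(filtered: np.ndarray) -> tuple[float, np.ndarray]:
    """Shift by the global minimum so the corrected matrix has minimum zero.

    alpha = min(filtered) and corrected = filtered - alpha: per-feature means
    shift by -alpha, variances are unchanged, and every pairwise feature
    difference is unchanged — so mean-difference tests (t, Wilcoxon) give
    identical results before and after. The shift is applied even when the
    minimum is positive, matching the definition.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    if not np.all(np.isfinite(filtered)):
        raise ValueError("filtered matrix contains non-finite entries")
    alpha = float(filtered.min())
    return alpha, filtered - alpha
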