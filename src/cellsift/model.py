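"""Model/Results objects wrapping kernel construction and projection filtering.

``SiftModel`` is built from an expression matrix plus a mapping of the cells
(a categorical annotation, a continuous scalar, an embedding, a marker-gene
restriction, or a precomputed kernel); ``fit()`` constructs the requested
similarity kernel and returns a ``SiftResults`` carrying the projection, the
filtered matrix, the optional pseudocount correction and kernel diagnostics.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CellMapping,
    DistanceSpec,
    ExpressionMatrix,
    FilterResult,
    SimilarityKernel,
    as_expression_matrix,
    validate_inputs,
)
from .filtering import apply_pseudocount, project, sift
from .kernels import (
    binned_mapping,
    distance_kernel,
    knn_kernel,
    mapping_kernel,
    precomputed_kernel,
)


class SiftModel:
    """Projection-filter model for a cells x features expression matrix.

    Parameters
    ----------
    X
        Expression matrix (``ExpressionMatrix``, DataFrame, or array). The
        method assumes (but does not enforce) log-normalized values.
    mapping
        Per-cell signal representation: a ``CellMapping``, a 1-D sequence of
        labels (one-hot encoded), a 1-D numeric array (binned when ``bins`` is
        given, otherwise used as a 1-column embedding), or a 2-D array used as
        an embedding. Ignored when ``kernel="precomputed"``.
    kernel
        One of ``mapping``, ``knn``, ``distance``, ``precomputed``.
    source_mask, target_mask
        Optional cell subsets: the cells whose expression is filtered and the
        cells similarity is evaluated against. Unequal sets give case-control
        reference filtering.
    precomputed
        Row-stochastic kernel matrix when ``kernel="precomputed"``.

    Examples
    --------
    >>> model = SiftModel(X, mapping=adata_obs_labels, kernel="mapping")
    >>> res = model.fit()
    >>> filtered = res.filtered
    """

    def __init__(
        self,
        X,
        mapping=None,
        kernel: str = "distance",
        *,
        source_mask=None,
        target_mask=None,
        bins: Optional[int] = None,
        k: int = 15,
        gamma: Optional[float] = None,
        metric: str = "euclidean",
        weighting: str = "umap",
        include_self: Optional[bool] = None,
        precomputed=None,
        renormalize: bool = False,
    ) -> None:
        if kernel not in ("mapping", "knn", "distance", "precomputed"):
            raise ValueError(f"unknown kernel kind {kernel!r}")
        self.X = as_expression_matrix(X)
        self.kernel_kind = kernel
        self.precomputed = precomputed
        self.renormalize = renormalize
        self.spec = DistanceSpec(metric=metric, gamma=gamma, k=k)
        self.weighting = weighting
        self.include_self = include_self

        if kernel == "precomputed":
            if precomputed is None:
                raise ValueError("kernel='precomputed' requires a kernel matrix")
            self.mapping = None
            n = self.X.n_cells
            from .core import _resolve_mask

            self.source_index = _resolve_mask(source_mask, n, "source")
            self.target_index = _resolve_mask(target_mask, n, "target")
        else:
            if mapping is None:
                raise ValueError(f"kernel={kernel!r} requires a mapping of the cells")
            self.mapping = _coerce_mapping(mapping, bins)
            _, _, self.source_index, self.target_index = validate_inputs(
                self.X, self.mapping, source_mask, target_mask
            )

    @classmethod
    def from_anndata(
        cls,
        adata,
        mapping_obs: Optional[str] = None,
        mapping_obsm: Optional[str] = None,
        layer: Optional[str] = None,
        **kwargs,
    ) -> "SiftModel":
        """Build from an AnnData object, taking the mapping from obs/obsm."""
        from .io import expression_from_anndata

        X = expression_from_anndata(adata, layer=layer)
        mapping = None
        if mapping_obs is not None and mapping_obsm is not None:
            raise ValueError("give only one of mapping_obs / mapping_obsm")
        if mapping_obs is not None:
            col = adata.obs[mapping_obs]
            if pd.api.types.is_numeric_dtype(col):
                mapping = np.asarray(col, dtype=float)
            else:
                mapping = CellMapping.from_labels(col.astype(str))
        elif mapping_obsm is not None:
            mapping = CellMapping(np.asarray(adata.obsm[mapping_obsm], dtype=float),
                                  kind="embedding")
        return cls(X, mapping=mapping, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mapping=None, **kwargs) -> "SiftModel":
        return cls(ExpressionMatrix.from_dataframe(df), mapping=mapping, **kwargs)

    def build_kernel(self) -> SimilarityKernel:
        """Construct the similarity kernel without filtering."""
        if self.kernel_kind == "precomputed":
            return precomputed_kernel(
                self.precomputed,
                self.source_index,
                self.target_index,
                renormalize=self.renormalize,
            )
        if self.kernel_kind == "mapping":
            return mapping_kernel(self.mapping, self.source_index, self.target_index)
        if self.kernel_kind == "knn":
            kw = {}
            if self.include_self is not None:
                kw["include_self"] = self.include_self
            return knn_kernel(
                self.mapping,
                self.spec,
                self.source_index,
                self.target_index,
                weighting=self.weighting,
                **kw,
            )
        return distance_kernel(
            self.mapping, self.spec, self.source_index, self.target_index
        )

    def fit(
        self,
        pseudocount: bool = False,
        batch_rows: Optional[int | str] = None,
    ) -> "SiftResults":
        """Build the kernel, project, subtract, and wrap up diagnostics."""
        K = self.build_kernel()
        res = sift(self.X, K, pseudocount=pseudocount, batch_rows=batch_rows)
        return SiftResults(self, K, res)


class SiftResults:
    """Results of a projection filter fit.

    Attributes
    ----------
    kernel : SimilarityKernel
        The row-stochastic similarity kernel used.
    projection : ndarray
        P = K @ X over target rows — expected expression under the similarity
        distribution of each source cell.
    filtered : ndarray
        Source expression minus the projection (may be negative).
    pseudocount, filtered_corrected
        Global-minimum shift and shifted matrix when requested.
    """

    def __init__(self, model: SiftModel, kernel: SimilarityKernel,
                 result: FilterResult) -> None:
        self.model = model
        self.kernel = kernel
        self._result = result

    @property
    def projection(self) -> np.ndarray:
        return self._result.projection

    @property
    def filtered(self) -> np.ndarray:
        return self._result.filtered

    @property
    def pseudocount(self) -> Optional[float]:
        return self._result.pseudocount

    @property
    def filtered_corrected(self) -> Optional[np.ndarray]:
        return self._result.filtered_corrected

    @property
    def source_index(self) -> np.ndarray:
        return self.kernel.source_index

    def filtered_frame(self) -> pd.DataFrame:
        """Filtered matrix as a DataFrame indexed by source cell ids."""
        X = self.model.X
        return pd.DataFrame(
            self.filtered,
            index=[X.cell_ids[i] for i in self.kernel.source_index],
            columns=X.feature_ids,
        )

    def full_matrix(self, layer: str = "filtered") -> np.ndarray:
        """Original matrix with source rows replaced by filtered values.

        Target-only cells are returned untouched.
        """
        out = np.asarray(self.model.X.values, dtype=np.float64).copy()
        vals = self.filtered_corrected if (
            layer == "corrected" and self.filtered_corrected is not None
        ) else self.filtered
        out[self.kernel.source_index] = vals
        return out

    def diagnostics(self) -> dict:
        K = self.kernel
        return {
            "kernel_kind": K.kernel_kind,
            "n_source": int(K.shape[0]),
            "n_target": int(K.shape[1]),
            "max_row_sum_deviation": K.max_row_sum_deviation(),
            "params": dict(K.params),
            "pseudocount": self.pseudocount,
            "filtered_min": float(self.filtered.min()),
            "filtered_max": float(self.filtered.max()),
            "projection_fraction_of_variance": self._projection_r2(),
        }

    def _projection_r2(self) -> float:
        Xs = self.model.X.values[self.kernel.source_index]
        total = float(((Xs - Xs.mean(axis=0)) ** 2).sum())
        if total == 0:
            return float("nan")
        resid = float(((self.filtered - self.filtered.mean(axis=0)) ** 2).sum())
        return 1.0 - resid / total

    def summary(self) -> str:
        """Human-readable fit summary."""
        d = self.diagnostics()
        lines = [
            "Projection filter results",
            "=" * 41,
            f"kernel kind:            {d['kernel_kind']}",
            f"source x target:        {d['n_source']} x {d['n_target']}",
            f"max |row sum - 1|:      {d['max_row_sum_deviation']:.3e}",
            f"filtered range:         [{d['filtered_min']:.4f}, {d['filtered_max']:.4f}]",
            f"variance removed (R^2): {d['projection_fraction_of_variance']:.4f}",
        ]
        for key, val in d["params"].items():
            lines.append(f"  {key}: {val}")
        if d["pseudocount"] is not None:
            lines.append(f"pseudocount alpha:      {d['pseudocount']:.6f}")
        return "\n".join(lines)


def _coerce_mapping(mapping, bins: Optional[int]) -> CellMapping:
    if isinstance(mapping, CellMapping):
        return mapping
    arr = np.asarray(mapping)
    if arr.ndim == 1 and not np.issubdtype(arr.dtype, np.number):
        return CellMapping.from_labels(arr)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 1:
        if bins is not None:
            return binned_mapping(arr, bins)
        return CellMapping(arr[:, None], kind="continuous_scalar")
    return CellMapping(arr, kind="embedding")
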