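"""Readers and writers for standard single-cell containers.

Supported formats: AnnData h5ad, Matrix Market directory (matrix.mtx +
cells.tsv + genes.tsv), and dense CSV (header row = feature ids, first column
= cell ids). Marker-gene lists are plain text, one symbol per line, '#'
comments allowed. Kernels serialize to a single .npz holding the sparse/dense
matrix, the source/target id lists and a JSON parameter record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CellMapping, ExpressionMatrix, SimilarityKernel

MTX_MATRIX = "matrix.mtx"
MTX_CELLS = "cells.tsv"
MTX_GENES = "genes.tsv"


def expression_from_anndata(adata, layer: Optional[str] = None) -> ExpressionMatrix:
    X = adata.layers[layer] if layer else adata.X
    if sp.issparse(X):
        X = X.toarray()
    return ExpressionMatrix(
        np.asarray(X, dtype=np.float64),
        [str(i) for i in adata.obs_names],
        [str(v) for v in adata.var_names],
    )


def to_anndata(X: ExpressionMatrix, truth=None):
    import anndata as ad

    adata = ad.AnnData(
        X=np.asarray(X.values, dtype=np.float64),
        obs=pd.DataFrame(index=pd.Index(X.cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(X.feature_ids, name="gene_id")),
    )
    if truth is not None:
        adata.obs["filtered_signal"] = pd.Categorical(
            [str(v) for v in truth.filtered_signal_label]
        )
        adata.obs["hidden_signal"] = pd.Categorical(
            [str(v) for v in truth.hidden_signal_label]
        )
        if truth.responder_flag is not None:
            adata.obs["responder"] = np.asarray(truth.responder_flag, dtype=bool)
        if truth.spatial_coords is not None:
            adata.obsm["spatial"] = np.asarray(truth.spatial_coords, dtype=float)
    return adata


def read_expression(
    path, format: str, layer: Optional[str] = None, transposed: bool = False
) -> ExpressionMatrix:
    """Read a cells x features matrix; ``transposed`` flips explicitly
    (orientation is never guessed)."""
    path = Path(path)
    if format == "h5ad":
        import anndata as ad

        X = expression_from_anndata(ad.read_h5ad(path), layer=layer)
    elif format == "mtx_dir":
        X = _read_mtx_dir(path)
    elif format == "csv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        dup = sorted({h for h in header if header.count(h) > 1})
        if dup:
            raise ValueError(f"duplicate feature column(s) in CSV: {dup[:5]}")
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        X = ExpressionMatrix.from_dataframe(df)
    else:
        raise ValueError(f"unknown format {format!r}; use h5ad, mtx_dir or csv")
    if transposed:
        X = ExpressionMatrix(X.values.T, X.feature_ids, X.cell_ids)
    return X


def _read_mtx_dir(path: Path) -> ExpressionMatrix:
    from scipy.io import mmread

    mtx, cells_f, genes_f = path / MTX_MATRIX, path / MTX_CELLS, path / MTX_GENES
    for f in (mtx, cells_f, genes_f):
        if not f.exists():
            raise FileNotFoundError(f"missing {f.name} in MTX directory {path}")
    M = mmread(mtx)
    if sp.issparse(M):
        M = M.toarray()
    cells = [ln.strip() for ln in cells_f.read_text().splitlines() if ln.strip()]
    genes = [ln.strip() for ln in genes_f.read_text().splitlines() if ln.strip()]
    if M.shape != (len(cells), len(genes)):
        raise ValueError(
            f"MTX shape {M.shape} does not match {len(cells)} cells x {len(genes)} genes"
        )
    return ExpressionMatrix(np.asarray(M, dtype=np.float64), cells, genes)


def write_expression(X: ExpressionMatrix, path, format: str, truth=None) -> None:
    path = Path(path)
    if format == "h5ad":
        to_anndata(X, truth).write_h5ad(path)
    elif format == "mtx_dir":
        from scipy.io import mmwrite

        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / MTX_MATRIX), sp.coo_matrix(X.values))
        (path / MTX_CELLS).write_text("\n".join(X.cell_ids) + "\n")
        (path / MTX_GENES).write_text("\n".join(X.feature_ids) + "\n")
    elif format == "csv":
        # %.17g keeps float64 round-trips bit-exact
        pd.DataFrame(X.values, index=X.cell_ids, columns=X.feature_ids).to_csv(
            path, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_marker_list(path) -> list[str]:
    """Plain-text marker list: one symbol per line, '#' starts a comment."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if ln:
            out.append(ln)
    return out


def mapping_from_markers(
    X: ExpressionMatrix, markers: Sequence[str], skip_missing: bool = False
) -> CellMapping:
    """Mapping T = X restricted to a marker-gene set (file order preserved)."""
    index = {g: j for j, g in enumerate(X.feature_ids)}
    missing = [g for g in markers if g not in index]
    if missing and not skip_missing:
        raise ValueError(f"marker genes absent from features: {missing}")
    if missing:
        import warnings

        warnings.warn(f"skipping absent marker genes: {missing}", UserWarning,
                      stacklevel=2)
    cols = [index[g] for g in markers if g in index]
    if not cols:
        raise ValueError("no marker genes present in the feature set")
    return CellMapping(X.values[:, cols], kind="marker_genes",
                       label_names=[X.feature_ids[j] for j in cols])


def save_kernel(K: SimilarityKernel, path, cell_ids: Optional[Sequence[str]] = None) -> None:
    """Serialize a kernel (sparse or dense) with indices and parameters."""
    path = Path(path)
    meta = json.dumps(
        {"kernel_kind": K.kernel_kind,
         "params": {k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
                    for k, v in K.params.items()}}
    )
    payload = {
        "source_index": K.source_index,
        "target_index": K.target_index,
        "meta": np.array(meta),
        "shape": np.array(K.shape),
    }
    if sp.issparse(K.K):
        csr = K.K.tocsr()
        payload.update(
            sparse=np.array(True), data=csr.data, indices=csr.indices, indptr=csr.indptr
        )
    else:
        payload.update(sparse=np.array(False), dense=np.asarray(K.K))
    np.savez_compressed(path, **payload)


def load_kernel(path) -> SimilarityKernel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        shape = tuple(z["shape"])
        if bool(z["sparse"]):
            K = sp.csr_matrix((z["data"], z["indices"], z["indptr"]), shape=shape)
        else:
            K = z["dense"]
        return SimilarityKernel(
            K=K,
            source_index=z["source_index"],
            target_index=z["target_index"],
            kernel_kind=meta["kernel_kind"],
            params=meta["params"],
        )


def write_filtered_h5ad(
    adata, results, path, layer_out: str = "sift",
    save_projection: bool = False, params: Optional[dict] = None,
) -> None:
    """Write filter output into a copy of the AnnData: filtered matrix to
    layers[layer_out] (original X untouched), projection optionally to
    layers['sift_projection'], parameter record to uns['sift'], and the kernel
    to obsp when square over all cells."""
    out = adata.copy()
    out.layers[layer_out] = results.full_matrix()
    if save_projection:
        proj = np.zeros_like(np.asarray(out.X, dtype=np.float64))
        proj[results.kernel.source_index] = results.projection
        out.layers["sift_projection"] = proj
    K = results.kernel
    if K.shape == (adata.n_obs, adata.n_obs):
        out.obsp["sift_kernel"] = sp.csr_matrix(K.K)
    record = {"kernel_kind": K.kernel_kind, **{
        k: v for k, v in K.params.items()
        if isinstance(v, (int, float, str, bool)) or v is None}}
    if params:
        record.update(params)
    if results.pseudocount is not None:
        record["pseudocount"] = results.pseudocount
    from . import __version__

    record["version"] = __version__
    out.uns["sift"] = {k: ("" if v is None else v) for k, v in record.items()}
    out.write_h5ad(path)
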