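"""Evaluation utilities: the cluster-purity score and small separability
metrics used to quantify signal removal and recovery.

The cluster-purity score says a cluster is informative for a labelling when
its dominant label occupies more than a threshold fraction tau of the cluster
(default tau = 0.55). ``classify_by_purity`` turns this into a simple
classifier: cells in informative clusters whose dominant label is the positive
class are predicted positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

DEFAULT_TAU = 0.55


@dataclass
class ClusterPurity:
    cluster: str
    size: int
    purity: float
    dominant_type: str
    informative: bool


def cluster_purity(
    cluster_labels: Sequence,
    type_labels: Sequence,
    tau: float = DEFAULT_TAU,
) -> list[ClusterPurity]:
    """Per-cluster purity m/n with the dominant-type tie broken
    lexicographically; informative iff purity strictly exceeds tau."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    clusters = np.asarray([str(c) for c in cluster_labels])
    types = np.asarray([str(t) for t in type_labels])
    if clusters.shape != types.shape:
        raise ValueError("cluster and type labels must be aligned")
    out = []
    for c in sorted(set(clusters)):
        mask = clusters == c
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"empty cluster {c!r}")
        vals, counts = np.unique(types[mask], return_counts=True)
        m = counts.max()
        dominant = min(vals[counts == m])  # lexicographic tie-break
        purity = m / n
        out.append(ClusterPurity(c, n, float(purity), str(dominant), purity > tau))
    return out


def purity_table(records: list[ClusterPurity]) -> pd.DataFrame:
    """Tabular (TSV-ready) report of per-cluster purity."""
    return pd.DataFrame([r.__dict__ for r in records]).set_index("cluster")


def classify_by_purity(
    cluster_labels: Sequence,
    type_labels: Sequence,
    positive_label: str,
    tau: float = DEFAULT_TAU,
) -> np.ndarray:
    """Predict positive for cells in informative clusters dominated by the
    positive label; returns a boolean per-cell prediction."""
    records = cluster_purity(cluster_labels, type_labels, tau=tau)
    positive_clusters = {
        r.cluster for r in records
        if r.informative and r.dominant_type == str(positive_label)
    }
    clusters = np.asarray([str(c) for c in cluster_labels])
    return np.isin(clusters, sorted(positive_clusters))


def kmeans_clusters(
    X: np.ndarray, n_clusters: int = 4, seed: int = 0
) -> np.ndarray:
    """Deterministic KMeans clustering used by the purity classifier."""
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    return km.fit_predict(np.asarray(X, dtype=np.float64)).astype(str)


def label_separability(
    X: np.ndarray,
    labels: Sequence,
    k: int = 15,
    seed: int = 0,
    test_size: float = 0.3,
) -> float:
    """knn-classification accuracy of a labelling on a stratified split.

    A crude but fast separability measure: chance level for uninformative
    data, 1.0 for perfectly separated classes. Used for direction-of-change
    assertions (does filtering remove the nuisance label and keep or improve
    the hidden one).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray([str(v) for v in labels])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, random_state=seed, stratify=y
    )
    clf = KNeighborsClassifier(n_neighbors=min(k, len(y_tr)))
    clf.fit(X_tr, y_tr)
    return float(clf.score(X_te, y_te))


def hvg_overlap(
    filtered: np.ndarray,
    feature_ids: Sequence[str],
    gene_set: Sequence[str],
    n_top: int = 50,
) -> float:
    """Fraction of a gene set found among the n_top most variable features.

    Variance ranking uses plain per-feature variance of the (corrected)
    filtered matrix; ties broken by feature order.
    """
    feature_ids = [str(f) for f in feature_ids]
    missing = [g for g in gene_set if g not in set(feature_ids)]
    if missing:
        raise ValueError(f"gene set members absent from features: {missing[:5]}")
    if not gene_set:
        raise ValueError("empty gene set")
    var = np.asarray(filtered, dtype=np.float64).var(axis=0)
    top = np.argsort(-var, kind="stable")[:n_top]
    top_names = {feature_ids[j] for j in top}
    return sum(g in top_names for g in gene_set) / len(gene_set)
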