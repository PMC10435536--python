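"""Outcome-blind sample clustering and Ward partitions for bi-cluster seeding.

Cluster discovery is deliberately blind to outcomes: these functions never
see a clinical table.  Prognosis labels (FP = favorable, PP = poor) are
attached post hoc by comparing Kaplan-Meier medians between the two
clusters, without altering the partition.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .survival import km_estimate
from .types import ClinicalTable, ClusteringResult, warn

log = logging.getLogger(__name__)

__all__ = ["kmeans_select_k", "assign_prognosis_labels", "ward_clusters", "zscore_rows"]


def zscore_rows(X: np.ndarray) -> np.ndarray:
    """Standardize each row to mean 0, SD 1 (rows with zero spread left at 0)."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by descending size (ties by first appearance)."""
    counts = pd.Series(raw).value_counts(sort=False)
    first_seen = {lab: int(np.argmax(raw == lab)) for lab in counts.index}
    ordered = sorted(counts.index, key=lambda lab: (-counts[lab], first_seen[lab]))
    remap = {lab: i for i, lab in enumerate(ordered)}
    return np.array([remap[lab] for lab in raw])


def kmeans_select_k(
    X: np.ndarray,
    sample_ids: Sequence[str],
    k_range: Sequence[int] = range(2, 7),
    n_init: int = 50,
    seed: Optional[int] = None,
    feature_space: str = "features",
) -> ClusteringResult:
    """K-means over k in ``k_range`` with mean-silhouette model selection.

    For each k the best-inertia partition of ``n_init`` restarts is scored
    by mean Euclidean silhouette; the k with the maximum silhouette wins
    (ties to the smaller k).  Labels are relabeled canonically by
    descending cluster size.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be samples x features")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.allclose(X, X[0:1, :]):
        raise ValueError("constant feature matrix: silhouette undefined")
    k_range = sorted(k_range)
    if X.shape[0] < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range) + 1} samples for k_max={max(k_range)}")

    sil = {}
    parts = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        raw = km.fit_predict(X)
        if len(set(raw)) < k:  # degenerate split; silhouette undefined for it
            continue
        sil[k] = float(silhouette_score(X, raw, metric="euclidean"))
        parts[k] = raw
    if not sil:
        raise ValueError("no k in range produced a valid partition")
    best_k = min(sil, key=lambda k: (-sil[k], k))
    labels = _canonical_labels(parts[best_k])
    return ClusteringResult(
        labels=pd.Series(labels, index=[str(s) for s in sample_ids], name="cluster"),
        k_selected=best_k,
        silhouette_by_k=sil,
        feature_space=feature_space,
    )


def assign_prognosis_labels(clust: ClusteringResult, surv: ClinicalTable,
                            endpoint: Optional[str] = None) -> ClusteringResult:
    """Label the two clusters FP/PP by Kaplan-Meier median survival.

    The cluster with the longer median survival is FP; a cluster whose
    median is never reached counts as longest.  Labeling is post hoc and
    never alters the partition.  Requires survival for >= 80% of samples.
    """
    if clust.k_selected != 2:
        raise ValueError(
            f"prognosis labels are defined for k=2 (got k={clust.k_selected}); "
            "use pairwise analyses for k>2"
        )
    endpoint = endpoint or surv.endpoints()[0]
    table = surv.for_endpoint(endpoint)
    covered = clust.labels.index.isin(table.index)
    if covered.mean() < 0.8:
        raise ValueError(
            f"survival available for only {covered.mean():.0%} of samples (need >= 80%)"
        )

    medians = {}
    for c in (0, 1):
        ids = [s for s in clust.cluster_samples(c) if s in table.index]
        sub = table.loc[ids]
        curve = km_estimate(sub["time_days"].to_numpy(), sub["event"].to_numpy())
        medians[c] = np.inf if curve.median is None else curve.median
    if medians[0] == medians[1]:
        warn("identical median survival in both clusters; labeling cluster 0 as FP")
        fp = 0
    else:
        fp = max(medians, key=medians.get)
    mapping = {fp: "FP", 1 - fp: "PP"}
    return ClusteringResult(
        labels=clust.labels.copy(),
        k_selected=clust.k_selected,
        silhouette_by_k=dict(clust.silhouette_by_k),
        feature_space=clust.feature_space,
        prognosis_labels=mapping,
    )


def ward_clusters(
    X: np.ndarray, n_gene_clusters: int = 10, n_sample_clusters: int = 7
) -> Tuple[np.ndarray, np.ndarray]:
    """Ward hierarchical partitions of rows (genes) and columns (samples).

    Classic Ward on squared Euclidean distances, rows and columns cut
    independently to the requested counts.  Returns 0-based partition
    labels for genes and samples.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix must be finite")
    if n_gene_clusters > X.shape[0] or n_sample_clusters > X.shape[1]:
        raise ValueError("requested more clusters than items")
    gene_part = fcluster(linkage(X, method="ward"), n_gene_clusters, criterion="maxclust") - 1
    sample_part = fcluster(linkage(X.T, method="ward"), n_sample_clusters, criterion="maxclust") - 1
    return gene_part, sample_part
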