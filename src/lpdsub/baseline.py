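"""Hard-clustering comparison arm: Ward hierarchical and k-means clustering.

These are the traditional subtyping baselines the mixed-membership model is
compared against: agglomerative clustering with the Ward D2 criterion on
Euclidean distances, k-means with multiple restarts, silhouette-based choice
of k, and log-rank evaluation of the resulting clusters' survival
separation.  Samples are points; features are the same top-variance
log-expression genes fed to the decomposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from lpdsub.clinical import logrank_test
from lpdsub.data_io import ClinicalTable, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    method: str
    k: int
    labels: np.ndarray     # values in 1..k
    mean_silhouette: float | None = None
    seed: int | None = None


def _sample_points(expr: ExpressionMatrix) -> np.ndarray:
    return expr.values.T  # samples x genes


def hclust_ward(expr: ExpressionMatrix, k: int) -> ClusteringResult:
    """Agglomerative clustering with Ward's D2 linkage, cut at k clusters."""
    x = _sample_points(expr)
    n = x.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    z = linkage(x, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusteringResult(method="hierarchical_ward_d2", k=k, labels=labels)


def kmeans_cluster(
    expr: ExpressionMatrix, k: int, restarts: int = 50, seed: int = 0
) -> ClusteringResult:
    """Best-of-restarts k-means (Lloyd iterations) by within-cluster SS."""
    x = _sample_points(expr)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(x) + 1
    return ClusteringResult(method="kmeans", k=k, labels=labels, seed=seed)


def silhouette_mean(expr: ExpressionMatrix, labels: np.ndarray) -> float:
    """Mean silhouette with Euclidean distance; singletons score 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    return float(silhouette_score(_sample_points(expr), labels, metric="euclidean"))


def silhouette_scan(
    expr: ExpressionMatrix,
    k_range: list[int],
    methods: tuple[str, ...] = ("hierarchical_ward_d2", "kmeans"),
    restarts: int = 50,
    seed: int = 0,
) -> dict:
    """Per method, the k in ``k_range`` maximizing the mean silhouette
    (ties to the smaller k) plus the full score table."""
    scores: dict[str, dict[int, float]] = {m: {} for m in methods}
    for k in sorted(k_range):
        for m in methods:
            if m == "hierarchical_ward_d2":
                res = hclust_ward(expr, k)
            elif m == "kmeans":
                res = kmeans_cluster(expr, k, restarts=restarts, seed=seed)
            else:
                raise ValueError(f"unknown method {m!r}")
            scores[m][k] = silhouette_mean(expr, res.labels)
    best = {
        m: max(sorted(ks), key=lambda k: (ks[k], -k))
        for m, ks in scores.items()
    }
    return {"best_k": best, "scores": scores}


def survival_by_cluster(
    labels: np.ndarray, sample_ids: list[str], clinical: ClinicalTable
) -> float:
    """Overall log-rank p across cluster groups (delegates to the survival
    module)."""
    surv = clinical.survival(sample_ids)
    lab_map = dict(zip(sample_ids, np.asarray(labels)))
    groups = {}
    for _, row in surv.iterrows():
        groups.setdefault(lab_map[row["sample_id"]], []).append(
            (row["time"], row["event"])
        )
    group_arrays = [
        (np.array([t for t, _ in rows]), np.array([e for _, e in rows]))
        for rows in groups.values()
    ]
    return logrank_test(group_arrays).p
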