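"""Two-stage trajectory clustering with Calinski-Harabasz model choice.

Subjects are grouped on their four standardized spline parameters:
Ward's minimum-variance hierarchical clustering supplies an initial
partition, which Lloyd's K-means then consolidates at the same k.  The
Calinski-Harabasz pseudo-F — between-cluster over within-cluster
dispersion, each normalised by its degrees of freedom — selects the
number of clusters when k is left free.

The whole stage is deterministic: Ward's agglomeration is
deterministic, and K-means starts from the Ward centroids rather than a
random initialisation, so the same parameter matrix always yields the
same labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

K_MIN_DEFAULT = 2
K_MAX_DEFAULT = 8


@dataclass
class ClusterSolution:
    """A partition of subjects into k trajectory clusters.

    ``labels`` are 1-based cluster indices; ``centroids`` holds the
    per-cluster mean of the (standardized) spline parameters, row i for
    cluster i+1.
    """

    labels: np.ndarray
    k: int
    ch_score: float
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=self.k + 1)[1:]
        if self.labels.min() < 1 or self.labels.max() > self.k or (sizes == 0).any():
            raise ValueError("labels must cover 1..k with no empty cluster")


def ward_cluster(matrix: np.ndarray, k: int) -> np.ndarray:
    """Ward's-linkage hierarchical clustering cut at k clusters."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if not np.isfinite(matrix).all():
        raise ValueError("matrix must be finite")
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n={n}")
    Z = linkage(matrix, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _relabel_by_first_occurrence(raw)


def kmeans_consolidate(matrix: np.ndarray, init_labels: np.ndarray) -> np.ndarray:
    """Lloyd's K-means seeded at the init partition's cluster means.

    Iterates assignment/update until labels are stable or the centroid
    shift drops below 1e-8.  k never changes: if a cluster empties, its
    centroid is re-seeded at the point farthest from its own centroid
    and the event is logged.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(init_labels, dtype=int)
    ks = np.unique(labels)
    k = len(ks)
    if labels.min() < 1 or set(ks) != set(range(1, k + 1)):
        raise ValueError("init_labels must be a 1..k partition with no gaps")
    centroids = np.stack([matrix[labels == j].mean(axis=0) for j in range(1, k + 1)])

    for _ in range(300):
        d = cdist(matrix, centroids, metric="sqeuclidean")
        new_labels = d.argmin(axis=1) + 1
        for j in range(1, k + 1):
            if not np.any(new_labels == j):
                # Re-seed an emptied cluster at the worst-fitting point.
                worst = int(np.argmax(d[np.arange(len(matrix)), new_labels - 1]))
                new_labels[worst] = j
                logger.warning("k-means cluster %d emptied; re-seeded at point %d", j, worst)
        new_centroids = np.stack(
            [matrix[new_labels == j].mean(axis=0) for j in range(1, k + 1)]
        )
        shift = float(np.abs(new_centroids - centroids).max())
        moved = bool(np.any(new_labels != labels))
        labels, centroids = new_labels, new_centroids
        if not moved or shift < 1e-8:
            break
    return _relabel_by_first_occurrence(labels)


def calinski_harabasz(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz pseudo-F statistic.

    score = [SS_between / (k - 1)] / [SS_within / (n - k)] with sums of
    squared Euclidean distances about cluster centroids and the grand
    mean.
    """
    matrix = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = matrix.shape[0]
    ks = np.unique(labels)
    k = len(ks)
    if k < 2 or k >= n:
        raise ValueError(f"Calinski-Harabasz undefined for k={k} with n={n}")
    grand = matrix.mean(axis=0)
    ss_b = 0.0
    ss_w = 0.0
    for j in ks:
        pts = matrix[labels == j]
        c = pts.mean(axis=0)
        ss_b += len(pts) * float(((c - grand) ** 2).sum())
        ss_w += float(((pts - c) ** 2).sum())
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def cluster_at_k(matrix: np.ndarray, k: int) -> ClusterSolution:
    """Ward seeding + K-means consolidation + CH score at fixed k."""
    labels = kmeans_consolidate(matrix, ward_cluster(matrix, k))
    centroids = np.stack(
        [np.asarray(matrix)[labels == j].mean(axis=0) for j in range(1, k + 1)]
    )
    score = calinski_harabasz(matrix, labels) if k < len(labels) else float("nan")
    return ClusterSolution(labels=labels, k=k, ch_score=score, centroids=centroids)


def optimal_k(
    matrix: np.ndarray, k_min: int = K_MIN_DEFAULT, k_max: int = K_MAX_DEFAULT
) -> tuple[ClusterSolution, dict[int, float]]:
    """Free search for the number of clusters.

    Runs the two-stage clustering for each k in [k_min, k_max] and
    returns the solution maximising the Calinski-Harabasz score plus
    the full score profile, so near-ties between neighbouring k remain
    inspectable.
    """
    n = np.asarray(matrix).shape[0]
    if not 2 <= k_min <= k_max < n:
        raise ValueError("need 2 <= k_min <= k_max < n")
    profile: dict[int, float] = {}
    best: ClusterSolution | None = None
    for k in range(k_min, k_max + 1):
        sol = cluster_at_k(matrix, k)
        profile[k] = sol.ch_score
        if best is None or sol.ch_score > best.ch_score:
            best = sol
    assert best is not None
    return best, profile


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Deterministic 1..k relabelling in order of first appearance."""
    labels = np.asarray(labels, dtype=int)
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out
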