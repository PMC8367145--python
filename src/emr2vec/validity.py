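"""Cluster validity: Hopkins statistic, Silhouette index, Davies-Bouldin index,
and the supervised cluster-to-diagnosis mapping with precision/recall/F1.

Conventions: silhouette of a singleton-cluster point is 0, as is the 0/0
case (a = b = 0); the Davies-Bouldin index is reported unbounded above (it
is not clamped to [0, 1]); Hopkins uses m = min(n//10, 100) probe points by
default, uniform pseudo-points in the per-dimension bounding box, and the
exponent-free form sum(u) / (sum(u) + sum(w)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .clustering import ClusterSolution, ClusteringError
from .distances import DistanceSpec, pairwise, pairwise_cross

logger = logging.getLogger(__name__)


def hopkins_statistic(
    X: np.ndarray,
    distance: DistanceSpec = DistanceSpec("euclidean"),
    m: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Clustering tendency in (0, 1): ~0.5 for spatially uniform data, near 1
    for strongly clustered data.

    Compares nearest-real-neighbor distances of m uniform pseudo-points
    (sampled in the data's per-dimension bounding box) against those of m
    real points sampled without replacement.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ClusteringError("hopkins statistic needs at least 2 points")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.allclose(lo, hi):
        raise ClusteringError("degenerate data: all points identical")
    if m is None:
        m = min(max(n // 10, 1), 100)
    if not (1 <= m <= n // 2):
        raise ClusteringError(f"m={m} outside [1, n/2={n // 2}]")
    rng = np.random.default_rng(seed)
    pseudo = rng.uniform(lo, hi, size=(m, X.shape[1]))
    sample_idx = rng.choice(n, size=m, replace=False)
    u = pairwise_cross(distance, pseudo, X).min(axis=1)
    Dsr = pairwise_cross(distance, X[sample_idx], X)
    Dsr[np.arange(m), sample_idx] = np.inf  # exclude self-distance
    w = Dsr.min(axis=1)
    total = u.sum() + w.sum()
    if total == 0:
        raise ClusteringError("degenerate data: zero nearest-neighbor distances")
    return float(u.sum() / total)


def silhouette_index(D: np.ndarray, assignments: np.ndarray) -> float:
    """Mean silhouette over all points from a precomputed distance matrix."""
    D = np.asarray(D, dtype=np.float64)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ClusteringError("silhouette requires at least 2 clusters")
    n = D.shape[0]
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        ci = labels[i]
        if sizes[ci] == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = D[i, masks[ci]].sum() / (sizes[ci] - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != ci)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def silhouette_for(
    X: np.ndarray, assignments: np.ndarray, distance: DistanceSpec
) -> float:
    return silhouette_index(pairwise(distance, X), assignments)


def davies_bouldin_index(
    X: np.ndarray,
    solution: ClusterSolution,
    distance: Optional[DistanceSpec] = None,
    D: Optional[np.ndarray] = None,
) -> float:
    """DBI = (1/k) sum_i max_{j != i} (sigma_i + sigma_j) / d(center_i, center_j).

    Centers are the solution's centroids for spherical k-means and its
    medoids for k-medoids clusterings, keeping the index internal to the
    distance space. Scatter sigma is the mean member-to-center distance.
    """
    distance = distance or solution.distance
    labels = solution.assignments
    k = solution.k
    if k < 2:
        raise ClusteringError("DBI requires at least 2 clusters")
    X = np.asarray(X, dtype=np.float64)
    if solution.medoid_indices is not None:
        if D is None:
            D = pairwise(distance, X)
        med = solution.medoid_indices
        sigma = np.array([D[labels == c, med[c]].mean() for c in range(k)])
        center_dist = D[np.ix_(med, med)]
    else:
        centers = solution.centers
        to_centers = pairwise_cross(distance, X, centers)
        sigma = np.array([to_centers[labels == c, c].mean() for c in range(k)])
        center_dist = pairwise_cross(distance, centers, centers)
    off = ~np.eye(k, dtype=bool)
    if np.any(center_dist[off] == 0):
        raise ClusteringError("degenerate solution: coincident cluster centers")
    ratios = (sigma[:, None] + sigma[None, :]) / np.where(center_dist == 0, np.inf, center_dist)
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


@dataclass
class ValidityReport:
    hopkins: Optional[float] = None
    silhouette: Optional[float] = None
    dbi: Optional[float] = None
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    cluster_label_map: dict[int, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "hopkins": self.hopkins,
                "silhouette": self.silhouette,
                "dbi": self.dbi,
                "per_class": self.per_class,
                "cluster_label_map": {str(k): v for k, v in self.cluster_label_map.items()},
            },
            indent=1,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def map_and_score(
    assignments: Sequence[int] | np.ndarray,
    true_labels: Sequence[str],
) -> ValidityReport:
    """Label each cluster by its majority true class and score per class.

    precision(label) = correctly-labeled members / size of the cluster(s)
    mapped to that label; recall(label) = correctly-labeled members / label
    prevalence in the cohort; F1 their harmonic mean. A label that no
    cluster maps to gets recall 0 and (undefined) precision reported as 0
    with a warning.
    """
    assignments = np.asarray(list(assignments))
    true_labels = np.asarray([str(t) for t in true_labels])
    if assignments.shape[0] != true_labels.shape[0]:
        raise ValueError("assignments and labels must align")
    clusters = np.unique(assignments)
    labels = np.unique(true_labels)
    cluster_label_map: dict[int, str] = {}
    for c in clusters:
        members = true_labels[assignments == c]
        lab, counts = np.unique(members, return_counts=True)
        # majority label; ties broken lexicographically for reproducibility
        order = np.lexsort((lab, -counts))
        cluster_label_map[int(c)] = str(lab[order[0]])
    per_class: dict[str, dict[str, float]] = {}
    for lab in labels:
        mapped_clusters = [c for c, l in cluster_label_map.items() if l == lab]
        prevalence = int((true_labels == lab).sum())
        if not mapped_clusters:
            logger.warning("label %r mapped to no cluster; precision reported as 0", lab)
            per_class[str(lab)] = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
            continue
        in_mapped = np.isin(assignments, mapped_clusters)
        tp = int((in_mapped & (true_labels == lab)).sum())
        precision = tp / int(in_mapped.sum())
        recall = tp / prevalence
        f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
        per_class[str(lab)] = {"precision": precision, "recall": recall, "f1": f1}
    return ValidityReport(per_class=per_class, cluster_label_map=cluster_label_map)


def score_from_counts(cluster_counts: Mapping[int, Mapping[str, int]]) -> ValidityReport:
    """Majority mapping and P/R/F1 from a table of per-cluster label counts.

    ``cluster_counts[c][label]`` is the number of patients with ``label``
    assigned to cluster ``c`` — the confusion-table form in which published
    clustering results are typically reported.
    """
    assignments: list[int] = []
    labels: list[str] = []
    for c, table in cluster_counts.items():
        for lab, count in table.items():
            assignments.extend([int(c)] * int(count))
            labels.extend([str(lab)] * int(count))
    return map_and_score(assignments, labels)
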