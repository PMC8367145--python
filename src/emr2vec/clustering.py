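"""Patient clustering under non-Euclidean distances.

K-means on cosine distance is realized as spherical k-means (rows are
unit-normalized, centroids are renormalized means, assignment maximizes
cosine). Jaccard and mixed distances have no meaningful coordinate mean, so
those representations are clustered by k-medoids (alternating medoid-update
iterations on a precomputed distance matrix, best of ``n_init`` restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distances import DistanceSpec, pairwise, pairwise_cross


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray          # cluster index per point
    distance: DistanceSpec
    seed: int
    centers: Optional[np.ndarray] = None      # centroid matrix (spherical k-means)
    medoid_indices: Optional[np.ndarray] = None  # medoid row ids (k-medoids)
    objective: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    provenance: dict = field(default_factory=dict)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def _reseed_empty(assign: np.ndarray, point_dist: np.ndarray, k: int) -> np.ndarray:
    """Repair empty clusters by reseeding them from the farthest point."""
    for c in range(k):
        if not (assign == c).any():
            far = int(np.argmax(point_dist))
            assign[far] = c
            point_dist[far] = -np.inf
    return assign


def _spherical_kmeans_once(
    Xn: np.ndarray, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    n = Xn.shape[0]
    centers = Xn[rng.choice(n, size=k, replace=False)].copy()
    prev_obj = np.inf
    converged = False
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        sims = Xn @ centers.T
        assign = np.argmax(sims, axis=1)
        point_dist = 1.0 - sims[np.arange(n), assign]
        assign = _reseed_empty(assign, point_dist.copy(), k)
        obj = float(np.sum(1.0 - (Xn @ centers.T)[np.arange(n), assign]))
        trace.append(obj)
        for c in range(k):
            members = Xn[assign == c]
            m = members.mean(axis=0)
            norm = np.linalg.norm(m)
            centers[c] = m / norm if norm > 0 else Xn[rng.integers(n)]
        if prev_obj - obj <= tol * max(abs(prev_obj), 1e-12):
            converged = True
            break
        prev_obj = obj
    sims = Xn @ centers.T
    assign = np.argmax(sims, axis=1)
    obj = float(np.sum(1.0 - sims[np.arange(n), assign]))
    trace.append(obj)
    return assign, centers, obj, it, converged, trace


def spherical_kmeans(
    X: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
    max_iter: int = 300, tol: float = 1e-4,
) -> ClusterSolution:
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ClusteringError(f"k={k} outside [1, n={n}]")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ClusteringError("zero rows cannot be placed on the unit sphere")
    Xn = X / norms[:, None]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        assign, centers, obj, n_iter, conv, trace = _spherical_kmeans_once(
            Xn, k, rng, max_iter, tol
        )
        if best is None or obj < best[2]:
            best = (assign, centers, obj, n_iter, conv, trace)
    assign, centers, obj, n_iter, conv, trace = best
    return ClusterSolution(
        k=k, assignments=assign, distance=DistanceSpec("cosine"), seed=seed,
        centers=centers, objective=obj, n_iter=n_iter, converged=conv,
        provenance={"objective_trace": trace},
    )


def _kmedoids_once(
    D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    converged = False
    for it in range(1, max_iter + 1):
        assign = np.argmin(D[:, medoids], axis=1)
        point_dist = D[np.arange(n), medoids[assign]]
        assign = _reseed_empty(assign, point_dist.copy(), k)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            within = D[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            converged = True
            break
        medoids = new_medoids
    assign = np.argmin(D[:, medoids], axis=1)
    obj = float(D[np.arange(n), medoids[assign]].sum())
    return assign, medoids, obj, it, converged


def kmedoids(
    D: np.ndarray, k: int, seed: int = 0, n_init: int = 10, max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """K-medoids on a precomputed square distance matrix; best of n_init."""
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ClusteringError(f"k={k} outside [1, n={n}]")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        result = _kmedoids_once(D, k, rng, max_iter)
        if best is None or result[2] < best[2]:
            best = result
    return best


def cluster(
    X: np.ndarray,
    k: int,
    distance: DistanceSpec,
    seed: int = 0,
    n_init: int = 10,
    D: Optional[np.ndarray] = None,
) -> ClusterSolution:
    """Cluster points under the distance the representation calls for.

    Cosine (and euclidean) route to spherical (resp. standard Lloyd via
    spherical on raw coords is not meaningful, so euclidean uses k-medoids);
    jaccard/mixed route to k-medoids on the precomputed matrix ``D``
    (computed here if not supplied).
    """
    if distance.kind == "cosine":
        return spherical_kmeans(X, k, seed=seed, n_init=n_init)
    if D is None:
        D = pairwise(distance, X)
    assign, medoids, obj, n_iter, conv = kmedoids(D, k, seed=seed, n_init=n_init)
    return ClusterSolution(
        k=k, assignments=assign, distance=distance, seed=seed,
        medoid_indices=medoids, objective=obj, n_iter=n_iter, converged=conv,
    )


def select_k(
    X: np.ndarray,
    distance: DistanceSpec,
    k_range: range = range(2, 16),
    seed: int = 0,
    n_init: int = 10,
    D: Optional[np.ndarray] = None,
) -> tuple[int, dict[int, float], dict[int, ClusterSolution]]:
    """Sweep k, score each solution by Silhouette, return the argmax.

    Ties go to the smaller k. Returns (k*, {k: SI}, {k: solution}).
    """
    from .validity import silhouette_index

    X = np.asarray(X, dtype=np.float64)
    if max(k_range) > X.shape[0]:
        raise ClusteringError("k_range exceeds the number of points")
    if D is None:
        D = pairwise(distance, X)
    si_by_k: dict[int, float] = {}
    solutions: dict[int, ClusterSolution] = {}
    for k in k_range:
        sol = cluster(X, k, distance, seed=seed, n_init=n_init, D=D)
        si_by_k[k] = silhouette_index(D, sol.assignments)
        solutions[k] = sol
    k_star = max(sorted(si_by_k), key=lambda k: (si_by_k[k], -k))
    return k_star, si_by_k, solutions
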