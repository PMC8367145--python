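"""Distances over patient representations: cosine, Jaccard, and the mixed form.

Each representation scheme carries its natural distance: cosine for the
real-valued embedding vectors, Jaccard for the binary multi-hot vectors, and
for the mixture representation the sum of a Jaccard term on the discrete
block and a cosine term on the continuous block.

Jaccard is implemented in its Ruzicka (weighted) form
``1 - sum(min(a,b)) / sum(max(a,b))``, which coincides with the set Jaccard
distance on binary vectors and extends it to nonnegative real vectors; this
lets the same distance score the uniform pseudo-points used by the Hopkins
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceSpec:
    """Distance kind plus parameters.

    ``split`` is the number of leading columns forming the discrete block of
    a mixed representation (required for ``kind="mixed"``, where data rows
    are the concatenation [discrete bits | continuous values]).
    """

    kind: str = "cosine"
    mixed_weights: tuple[float, float] = (1.0, 1.0)
    split: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("cosine", "jaccard", "mixed", "euclidean"):
            raise DistanceError(f"unknown distance kind: {self.kind!r}")
        if self.kind == "mixed" and self.split is None:
            raise DistanceError("mixed distance requires the discrete-block split")


def cosine_distance(u: np.ndarray, w: np.ndarray) -> float:
    from .similarity import cosine_similarity

    return 1.0 - cosine_similarity(u, w)


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Ruzicka/Jaccard distance; set Jaccard when inputs are binary."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DistanceError("vectors must share a dimension")
    if (a < 0).any() or (b < 0).any():
        raise DistanceError("jaccard distance requires nonnegative vectors")
    union = np.maximum(a, b).sum()
    if union == 0:
        raise DistanceError("jaccard distance undefined for two all-zero vectors")
    return float(1.0 - np.minimum(a, b).sum() / union)


def mixed_distance(
    discrete_a: np.ndarray,
    continuous_a: np.ndarray,
    discrete_b: np.ndarray,
    continuous_b: np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Weighted sum: Jaccard on discrete blocks + cosine distance on continuous."""
    w_d, w_c = weights
    return w_d * jaccard_distance(discrete_a, discrete_b) + w_c * cosine_distance(
        continuous_a, continuous_b
    )


def _cosine_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    nx = np.linalg.norm(X, axis=1)
    ny = np.linalg.norm(Y, axis=1)
    if (nx == 0).any() or (ny == 0).any():
        raise DistanceError("cosine distance undefined for zero rows")
    D = 1.0 - (X @ Y.T) / np.outer(nx, ny)
    return np.clip(D, 0.0, 2.0)


def _jaccard_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if (X < 0).any() or (Y < 0).any():
        raise DistanceError("jaccard distance requires nonnegative vectors")
    binary = set(np.unique(X)).issubset({0.0, 1.0}) and set(np.unique(Y)).issubset(
        {0.0, 1.0}
    )
    if binary:
        inter = X @ Y.T
        union = X.sum(1)[:, None] + Y.sum(1)[None, :] - inter
    else:
        n, m = X.shape[0], Y.shape[0]
        inter = np.empty((n, m))
        union = np.empty((n, m))
        for i in range(n):
            inter[i] = np.minimum(X[i], Y).sum(1)
            union[i] = np.maximum(X[i], Y).sum(1)
    if (union == 0).any():
        raise DistanceError("jaccard distance undefined for two all-zero vectors")
    return 1.0 - inter / union


def pairwise_cross(spec: DistanceSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """|X| x |Y| distance matrix under the given distance kind."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if spec.kind == "euclidean":
        return cdist(X, Y)
    if spec.kind == "cosine":
        return _cosine_cross(X, Y)
    if spec.kind == "jaccard":
        return _jaccard_cross(X, Y)
    s = spec.split
    w_d, w_c = spec.mixed_weights
    return w_d * _jaccard_cross(X[:, :s], Y[:, :s]) + w_c * _cosine_cross(
        X[:, s:], Y[:, s:]
    )


def pairwise(spec: DistanceSpec, X: np.ndarray) -> np.ndarray:
    """Square distance matrix with an exactly-zero diagonal."""
    D = pairwise_cross(spec, X, X)
    np.fill_diagonal(D, 0.0)
    return D
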