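"""Validity indices against brute-force oracles, plus the supervised mapping."""

import numpy as np
import pytest

from emr2vec import (
    ClusterSolution,
    DistanceSpec,
    cluster,
    davies_bouldin_index,
    hopkins_statistic,
    map_and_score,
    pairwise,
    score_from_counts,
    silhouette_index,
)
from emr2vec.clustering import ClusteringError


# ---------------------------------------------------------------- oracles
def silhouette_oracle(D, labels):
    """Naive per-point silhouette straight from the definition."""
    n = len(labels)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = sum(D[i, j] for j in same) / len(same)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == c)
            / sum(1 for j in range(n) if labels[j] == c)
            for c in set(labels) if c != labels[i]
        )
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


def dbi_oracle(D_to_center, center_D, labels, k):
    sigma = [np.mean([D_to_center[i] for i in range(len(labels)) if labels[i] == c])
             for c in range(k)]
    worst = []
    for i in range(k):
        worst.append(max((sigma[i] + sigma[j]) / center_D[i][j]
                         for j in range(k) if j != i))
    return float(np.mean(worst))


def random_instance(rng, kind):
    n = int(rng.integers(6, 13))
    if kind == "cosine":
        X = rng.normal(size=(n, 4)) + 3
    elif kind == "jaccard":
        X = (rng.random((n, 8)) < 0.5).astype(float)
        X[X.sum(1) == 0, 0] = 1
    else:  # mixed
        disc = (rng.random((n, 6)) < 0.5).astype(float)
        disc[disc.sum(1) == 0, 0] = 1
        X = np.hstack([disc, rng.normal(size=(n, 3)) + 2])
    spec = DistanceSpec(kind, split=6 if kind == "mixed" else None)
    k = int(rng.integers(2, 4))
    while True:
        labels = rng.integers(0, k, size=n)
        if len(set(labels)) == k:
            return X, spec, labels, k


# ---------------------------------------------------------------- silhouette
class TestSilhouette:
    def test_worked_one_dimensional_example(self):
        """{0, 0.1} vs {10, 10.1}: a = 0.1 for every point; b = 10.05 for the
        outer points and 9.95 for the inner ones, so SI = 0.9900 (~0.99005)."""
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        D = pairwise(DistanceSpec("euclidean"), X)
        si = silhouette_index(D, np.array([0, 0, 1, 1]))
        exact = (9.95 / 10.05 + 9.85 / 9.95) / 2  # brute force by hand
        assert si == pytest.approx(exact, abs=1e-12)
        assert si == pytest.approx(0.99005, abs=1e-4)

    def test_identical_points_convention_zero(self):
        X = np.zeros((6, 3))
        D = pairwise(DistanceSpec("euclidean"), X)
        assert silhouette_index(D, np.array([0, 0, 0, 1, 1, 1])) == 0.0

    def test_singleton_cluster_scores_zero(self):
        X = np.array([[0.0], [0.1], [5.0]])
        D = pairwise(DistanceSpec("euclidean"), X)
        si = silhouette_index(D, np.array([0, 0, 1]))
        oracle = silhouette_oracle(D, [0, 0, 1])
        assert si == pytest.approx(oracle)

    def test_fewer_than_two_clusters_rejected(self):
        D = pairwise(DistanceSpec("euclidean"), np.eye(3))
        with pytest.raises(ClusteringError):
            silhouette_index(D, np.zeros(3, dtype=int))

    @pytest.mark.parametrize("kind", ["cosine", "jaccard", "mixed"])
    def test_matches_oracle_on_random_instances(self, kind):
        rng = np.random.default_rng(hash(kind) % 2**31)
        for _ in range(60):
            X, spec, labels, _ = random_instance(rng, kind)
            D = pairwise(spec, X)
            assert silhouette_index(D, labels) == pytest.approx(
                silhouette_oracle(D, list(labels)), abs=1e-9
            )

    def test_matches_sklearn_on_euclidean(self, rng):
        from sklearn.metrics import silhouette_score

        X = rng.normal(size=(30, 4))
        labels = rng.integers(0, 3, size=30)
        D = pairwise(DistanceSpec("euclidean"), X)
        assert silhouette_index(D, labels) == pytest.approx(
            silhouette_score(X, labels), abs=1e-9
        )


# ---------------------------------------------------------------- DBI
class TestDaviesBouldin:
    def test_zero_scatter_gives_zero(self):
        X = np.array([[1, 0, 0]] * 3 + [[0, 1, 0]] * 3, dtype=float)
        sol = cluster(X, 2, DistanceSpec("jaccard"), seed=0)
        D = pairwise(DistanceSpec("jaccard"), X)
        assert davies_bouldin_index(X, sol, D=D) == pytest.approx(0.0)

    @pytest.mark.parametrize("kind", ["cosine", "jaccard", "mixed"])
    def test_matches_oracle_on_random_instances(self, kind):
        rng = np.random.default_rng(hash("dbi" + kind) % 2**31)
        for _ in range(40):
            X, spec, _, k = random_instance(rng, kind)
            sol = cluster(X, k, spec, seed=1, n_init=3)
            D = pairwise(spec, X)
            labels = sol.assignments
            if sol.medoid_indices is not None:
                med = sol.medoid_indices
                d_to_center = D[np.arange(len(labels)), med[labels]]
                center_D = D[np.ix_(med, med)]
            else:
                from emr2vec.distances import pairwise_cross

                to_c = pairwise_cross(spec, X, sol.centers)
                d_to_center = to_c[np.arange(len(labels)), labels]
                center_D = pairwise_cross(spec, sol.centers, sol.centers)
            if np.any(center_D[~np.eye(k, dtype=bool)] == 0):
                continue  # degenerate draw; the index itself rejects these
            assert davies_bouldin_index(X, sol, D=D) == pytest.approx(
                dbi_oracle(d_to_center, center_D, labels, k), abs=1e-9
            )

    def test_overlapping_clusters_score_worse(self, rng):
        """Merging well-separated groups into overlapping ones raises DBI."""
        tight_a = rng.normal(0, 0.5, size=(20, 3)) + [0, 0, 20]
        tight_b = rng.normal(0, 0.5, size=(20, 3)) + [20, 0, 0]
        X_sep = np.vstack([tight_a, tight_b])
        sol_sep = cluster(X_sep, 2, DistanceSpec("cosine"), seed=0)
        mixed_a = rng.normal(0, 4.0, size=(20, 3)) + [5, 5, 8]
        mixed_b = rng.normal(0, 4.0, size=(20, 3)) + [8, 5, 5]
        X_mix = np.vstack([np.abs(mixed_a), np.abs(mixed_b)])
        sol_mix = cluster(X_mix, 2, DistanceSpec("cosine"), seed=0)
        dbi_sep = davies_bouldin_index(X_sep, sol_sep)
        dbi_mix = davies_bouldin_index(X_mix, sol_mix)
        assert dbi_mix > dbi_sep

    def test_coincident_centers_rejected(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        sol = ClusterSolution(
            k=2, assignments=np.array([0, 0, 1, 1]),
            distance=DistanceSpec("cosine"), seed=0,
            centers=np.array([[1.0, 0.0], [1.0, 0.0]]),
        )
        with pytest.raises(ClusteringError, match="degenerate"):
            davies_bouldin_index(X, sol)


# ---------------------------------------------------------------- Hopkins
class TestHopkins:
    def test_uniform_data_near_half(self):
        """Null behavior: uniformly distributed data has no cluster structure,
        so H ~ 0.5. (A regular lattice scores well below 0.5: it is *more*
        even than the uniform-random null the statistic compares against.)"""
        X = np.random.default_rng(0).uniform(0, 1, size=(225, 2))
        vals = [hopkins_statistic(X, DistanceSpec("euclidean"), seed=s)
                for s in range(20)]
        assert abs(np.mean(vals) - 0.5) <= 0.1

    def test_two_tight_blobs_clustered(self, rng):
        X = np.vstack([
            rng.normal(0, 0.05, size=(100, 2)),
            rng.normal(5, 0.05, size=(100, 2)),
        ])
        assert hopkins_statistic(X, DistanceSpec("euclidean"), seed=0) >= 0.75

    def test_boundary_m_half_n(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        h = hopkins_statistic(X, DistanceSpec("euclidean"), m=2, seed=0)
        assert 0.0 < h < 1.0

    def test_identical_points_rejected(self):
        with pytest.raises(ClusteringError):
            hopkins_statistic(np.ones((10, 2)), DistanceSpec("euclidean"))

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 3))
        spec = DistanceSpec("euclidean")
        assert hopkins_statistic(X, spec, seed=9) == hopkins_statistic(X, spec, seed=9)

    def test_m_out_of_range_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ClusteringError):
            hopkins_statistic(X, DistanceSpec("euclidean"), m=9)


# ---------------------------------------------------------------- supervised
class TestMapAndScore:
    def _printed_counts(self):
        return {1: {"IS": 6495, "HS": 427}, 2: {"IS": 340, "HS": 970}}

    def test_published_confusion_counts(self):
        """The printed two-cluster stroke confusion table: F1 0.944 / 0.717."""
        report = score_from_counts(self._printed_counts())
        assert report.cluster_label_map == {1: "IS", 2: "HS"}
        assert report.per_class["IS"]["f1"] == pytest.approx(0.944, abs=5e-4)
        assert report.per_class["HS"]["f1"] == pytest.approx(0.717, abs=5e-4)

    def test_recall_from_printed_counts(self):
        report = score_from_counts(self._printed_counts())
        assert report.per_class["IS"]["recall"] == pytest.approx(6495 / 6835)
        assert 100 * report.per_class["IS"]["recall"] == pytest.approx(95.0, abs=0.05)

    def test_perfect_assignment(self):
        report = map_and_score([0, 0, 1, 1], ["a", "a", "b", "b"])
        for lab in ("a", "b"):
            assert report.per_class[lab] == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_unmapped_label_scored_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            report = map_and_score([0, 0, 0], ["a", "a", "b"])
        assert report.per_class["b"] == {"precision": 0.0, "recall": 0.0, "f1": 0.0}
        assert any("b" in m for m in caplog.messages)

    def test_f1_is_harmonic_mean(self):
        report = score_from_counts(self._printed_counts())
        for scores in report.per_class.values():
            p, r = scores["precision"], scores["recall"]
            assert scores["f1"] == pytest.approx(2 * p * r / (p + r))
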