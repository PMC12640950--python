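"""kNN-Jaccard graph construction, Louvain partitions, t-SNE, median profiles."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from immunohub.clustering import (
    ClusterAssignment,
    build_knn_jaccard_graph,
    cluster_median_profile,
    louvain_cluster,
    tsne_embed,
)
from immunohub.errors import ConfigError
from immunohub.graph import WeightedGraph
from immunohub.oracles import max_modularity_bruteforce, modularity

from conftest import make_event_table


def _two_blobs(n_per=60, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, 3))
    b = rng.normal(sep, 1.0, size=(n_per, 3))
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


class TestKnnJaccardGraph:
    def test_collinear_hand_enumeration(self):
        """Points at 0,1,2,10 with k=2: Jaccard(p0,p1) over kNN sets {1,2}
        and {0,2} is 1/3."""
        g = build_knn_jaccard_graph(np.array([[0.0], [1.0], [2.0], [10.0]]), k=2)
        weights = {tuple(e): w for e, w in zip(map(tuple, g.edges), g.weights)}
        assert weights[(0, 1)] == pytest.approx(1 / 3)

    def test_separated_groups_never_connect(self):
        """Well-separated point pairs share no cross-group edges at k=1."""
        X = np.array([[0.0, 0.0], [0.1, 0.0], [100.0, 0.0], [100.1, 0.0]])
        g = build_knn_jaccard_graph(X, k=1)
        groups = np.array([0, 0, 1, 1])
        for i, j in g.edges:
            assert groups[i] == groups[j]

    def test_k_equal_n_rejected(self):
        with pytest.raises(ConfigError):
            build_knn_jaccard_graph(np.zeros((4, 2)), k=4)

    def test_weights_in_unit_interval(self):
        X, _ = _two_blobs(40)
        g = build_knn_jaccard_graph(X, k=10)
        assert (g.weights > 0).all() and (g.weights <= 1).all()


class TestLouvain:
    def test_two_disjoint_triangles(self):
        """Exhaustive enumeration over all partitions of 6 nodes gives
        modularity 0.5 for the two-triangle split."""
        edges = np.array([[0, 1], [0, 2], [1, 2], [3, 4], [3, 5], [4, 5]])
        g = WeightedGraph(tuple(range(6)), edges, np.ones(6))
        part = louvain_cluster(g, seed=1)
        assert part.n_clusters == 2
        assert part.modularity == pytest.approx(0.5)
        assert part.modularity == pytest.approx(max_modularity_bruteforce(g)[0])

    def test_single_edge_is_one_cluster(self):
        g = WeightedGraph((0, 1), np.array([[0, 1]]), np.ones(1))
        part = louvain_cluster(g, seed=0)
        assert part.n_clusters == 1

    def test_edgeless_graph_gives_singletons(self):
        g = WeightedGraph(tuple(range(5)), np.empty((0, 2), np.int64), np.empty(0))
        part = louvain_cluster(g, seed=0)
        assert part.n_clusters == 5

    def test_labels_ordered_by_descending_size(self):
        X, _ = _two_blobs(n_per=40, seed=3)
        X = np.vstack([X, X[:20] + [0, 0, 40.0]])  # add a smaller third blob
        g = build_knn_jaccard_graph(X, k=10)
        part = louvain_cluster(g, seed=2)
        sizes = part.sizes
        assert (np.diff(sizes) <= 0).all()

    def test_same_seed_reproduces_partition(self):
        X, _ = _two_blobs(50, seed=1)
        g = build_knn_jaccard_graph(X, k=8)
        p1 = louvain_cluster(g, seed=9)
        p2 = louvain_cluster(g, seed=9)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_permutation_stability_on_separated_blobs(self):
        """Shuffling cell order then unshuffling labels yields the same
        partition on unambiguous data."""
        X, truth = _two_blobs(40, seed=2)
        g = build_knn_jaccard_graph(X, k=20)
        base = louvain_cluster(g, seed=4).labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        g2 = build_knn_jaccard_graph(X[perm], k=20)
        shuffled = louvain_cluster(g2, seed=4).labels
        unshuffled = np.empty_like(shuffled)
        unshuffled[perm] = shuffled
        # compare as partitions (label names may differ)
        for lab in np.unique(base):
            members = np.flatnonzero(base == lab)
            assert len(np.unique(unshuffled[members])) == 1


class TestTsne:
    def test_output_shape_and_determinism(self):
        X, _ = _two_blobs(30, seed=5)
        e1 = tsne_embed(X, seed=3, perplexity=10)
        e2 = tsne_embed(X, seed=3, perplexity=10)
        assert e1.shape == (60, 2)
        np.testing.assert_array_equal(e1, e2)

    def test_separated_blobs_have_positive_silhouette(self):
        X, labels = _two_blobs(30, sep=10.0, seed=6)
        emb = tsne_embed(X, seed=0, perplexity=10)
        assert silhouette_score(emb, labels) > 0

    def test_too_large_perplexity_rejected(self):
        with pytest.raises(ConfigError):
            tsne_embed(np.zeros((10, 2)), seed=0, perplexity=5)


class TestMedianProfile:
    def test_singleton_cluster_equals_cell_values(self):
        table = make_event_table({"a": [1.0, 5.0], "b": [2.0, 6.0]})
        prof = cluster_median_profile(table, ClusterAssignment(np.array([0, 1])))
        assert prof.values.loc[1, "a"] == 5.0
        assert prof.values.loc[1, "b"] == 6.0

    def test_median_is_robust_to_outlier(self):
        table = make_event_table({"a": [1.0, 2.0, 100.0], "b": [0.0] * 3})
        prof = cluster_median_profile(table, ClusterAssignment(np.zeros(3, dtype=int)))
        assert prof.values.loc[0, "a"] == 2.0

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=30)
        labels = rng.integers(0, 3, size=30)
        t1 = make_event_table({"a": values, "b": -values})
        perm = rng.permutation(30)
        t2 = make_event_table({"a": values[perm], "b": -values[perm]})
        p1 = cluster_median_profile(t1, ClusterAssignment(labels))
        p2 = cluster_median_profile(t2, ClusterAssignment(labels[perm]))
        assert p1.values.equals(p2.values)
        assert p1.row_order == p2.row_order
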