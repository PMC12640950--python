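"""Hub-gene discovery: DE, DEG filter, MCC, MCODE, random forest, intersection."""

import numpy as np
import pandas as pd
import pytest

from immunohub.errors import ConfigError
from immunohub.graph import WeightedGraph
from immunohub.netrank import (
    filter_degs,
    hub_intersection,
    mcc_rank,
    mcode_modules,
    rf_importance_rank,
    simple_paired_de,
)
from immunohub.oracles import mcc_bruteforce
from immunohub.simulate import SimExprConfig, expression_sample_info, simulate_expression


def _graph(n, pairs):
    pairs = sorted((min(a, b), max(a, b)) for a, b in pairs)
    edges = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    return WeightedGraph(tuple(range(n)), edges, np.ones(len(edges)))


def _sample_info(n_donors=3, arms=("A", "B")):
    rows = [
        {"sample": f"D{d}_{arm}", "donor": f"D{d}", "arm": arm}
        for d in range(n_donors)
        for arm in arms
    ]
    return pd.DataFrame(rows).set_index("sample")


class TestSimplePairedDE:
    def _counts(self, matrix, info):
        return pd.DataFrame(matrix, index=[f"G{i}" for i in range(len(matrix))], columns=info.index)

    def test_identical_arms_zero_lfc(self):
        info = _sample_info()
        block = np.tile([[100], [50], [10]], (1, 3))
        counts = self._counts(np.column_stack([block, block])[:, [0, 3, 1, 4, 2, 5]], info)
        # identical per-donor columns across arms
        counts = self._counts(np.column_stack([c for d in range(3) for c in ([100, 50, 10], [100, 50, 10])]), info)
        de = simple_paired_de(counts, info)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-12)

    def test_doubled_gene_has_lfc_near_one(self):
        """Doubling one gene's counts in arm B (large libraries) gives
        log2FC within 0.05 of 1."""
        info = _sample_info()
        base = np.full(200, 5000.0)
        cols = []
        for _ in range(3):
            a = base.copy()
            b = base.copy()
            b[0] *= 2
            cols.extend([a, b])
        de = simple_paired_de(self._counts(np.column_stack(cols).astype(int), info), info)
        assert de.iloc[0]["log2fc"] == pytest.approx(1.0, abs=0.05)

    def test_all_zero_gene_flagged_not_error(self):
        info = _sample_info()
        mat = np.ones((3, 6), dtype=int) * 50
        mat[1] = 0
        de = simple_paired_de(self._counts(mat, info), info)
        assert de.iloc[1]["log2fc"] == 0.0
        assert de.iloc[1]["q"] == 1.0
        assert bool(de.iloc[1]["all_zero"])


class TestFilterDegs:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "q"], index=[f"G{i}" for i in range(len(rows))])

    def test_inclusive_boundaries(self):
        de = self._de([(1.0, 0.05), (-1.2, 0.01), (0.9, 0.001), (0.999, 0.05), (1.0, 0.0501)])
        out = filter_degs(de)
        assert list(out.index) == ["G0", "G1"]
        assert out.loc["G1", "direction"] == "down"

    def test_monotone_in_thresholds(self):
        """Relaxing either threshold never removes a gene."""
        rng = np.random.default_rng(3)
        de = self._de(list(zip(rng.normal(0, 1.5, 200), rng.uniform(0, 0.2, 200))))
        strict = set(filter_degs(de, lfc_min=1.2, q_max=0.03).index)
        relaxed_lfc = set(filter_degs(de, lfc_min=0.8, q_max=0.03).index)
        relaxed_q = set(filter_degs(de, lfc_min=1.2, q_max=0.10).index)
        assert strict <= relaxed_lfc
        assert strict <= relaxed_q


class TestMCC:
    def test_triangle_member_scores_two(self):
        g = _graph(3, [(0, 1), (0, 2), (1, 2)])
        out = mcc_rank(g)
        assert (out["mcc"] == 2).all()  # (3-1)! = 2

    def test_isolated_edge_endpoint_scores_one(self):
        g = _graph(2, [(0, 1)])
        assert (mcc_rank(g)["mcc"] == 1).all()

    def test_isolated_node_scores_zero(self):
        g = _graph(3, [(0, 1)])
        out = mcc_rank(g)
        assert out.loc[2, "mcc"] == 0

    def test_oversized_top_n_warns_and_returns_all(self):
        g = _graph(3, [(0, 1)])
        with pytest.warns(UserWarning):
            out = mcc_rank(g, top_n=10)
        assert len(out) == 3

    def test_matches_bruteforce_on_random_graphs(self):
        """Exact agreement with exhaustive clique enumeration on a random
        suite of small graphs."""
        import networkx as nx

        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            gnx = nx.gnp_random_graph(n, rng.uniform(0.2, 0.8), seed=int(rng.integers(2**31 - 1)))
            g = _graph(n, gnx.edges())
            expected = mcc_bruteforce(g)
            got = mcc_rank(g)
            assert {v: int(got.loc[v, "mcc"]) for v in g.node_names} == expected


class TestMCODE:
    def test_clique_with_pendant_hand_trace(self):
        """Isolated 4-clique plus a pendant: one module of the 4 clique
        members, pendant removed by haircut, score 1.0 * 4 = 4."""
        g = _graph(5, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (0, 4)])
        modules = mcode_modules(g)
        assert len(modules) == 1
        assert modules[0].members == (0, 1, 2, 3)
        assert modules[0].score == pytest.approx(4.0)

    def test_edgeless_graph_has_no_modules(self):
        g = _graph(4, [])
        assert mcode_modules(g) == []

    def test_module_members_survive_two_core(self):
        import networkx as nx

        rng = np.random.default_rng(2)
        gnx = nx.gnp_random_graph(40, 0.15, seed=9)
        g = WeightedGraph.from_networkx(gnx)
        for module in mcode_modules(g):
            sub = gnx.subgraph(module.members)
            assert nx.k_core(sub, 2).number_of_nodes() > 0

    def test_scores_non_increasing(self):
        import networkx as nx

        gnx = nx.gnp_random_graph(60, 0.12, seed=4)
        modules = mcode_modules(WeightedGraph.from_networkx(gnx))
        scores = [m.score for m in modules]
        assert scores == sorted(scores, reverse=True)

    def test_fluff_not_supported(self):
        with pytest.raises(NotImplementedError):
            mcode_modules(_graph(3, [(0, 1)]), fluff=True)


class TestRFImportance:
    def test_constant_feature_has_zero_importances(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 12))
        X[0] = 7.0  # gene 0 identical across samples
        labels = np.array(["A", "B"])[np.arange(12) % 2]
        X[1, labels == "B"] += 3.0  # informative gene for signal
        expr = pd.DataFrame(X, index=[f"G{i}" for i in range(20)])
        out = rf_importance_rank(expr, labels, n_trees=200, seed=0)
        assert out.loc["G0", "mda"] == 0.0
        assert out.loc["G0", "mdg"] == 0.0

    def test_same_seed_same_ranking(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(30, 10)), index=[f"G{i}" for i in range(30)])
        labels = np.array(["A", "B"])[np.arange(10) % 2]
        r1 = rf_importance_rank(expr, labels, n_trees=100, seed=5)
        r2 = rf_importance_rank(expr, labels, n_trees=100, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_sample_arm_rejected(self):
        expr = pd.DataFrame(np.zeros((5, 3)), index=[f"G{i}" for i in range(5)])
        with pytest.raises(ConfigError):
            rf_importance_rank(expr, ["A", "A", "B"], n_trees=10, seed=0)


class TestHubIntersection:
    def _de(self, genes):
        return pd.DataFrame(
            {"log2fc": np.linspace(-2, 2, len(genes)), "q": 0.01}, index=list(genes)
        )

    def test_exact_three_way_intersection(self):
        de = self._de("ABCDE")
        report = hub_intersection({"A", "B", "C"}, {"B", "C", "D"}, {"C", "E"}, de)
        assert list(report.final.index) == ["C"]
        assert report.venn_counts["all_three"] == 1

    def test_empty_input_empty_intersection(self):
        de = self._de("ABC")
        report = hub_intersection({"A"}, set(), {"A"}, de)
        assert len(report.final) == 0

    def test_argument_order_invariance(self):
        de = self._de("ABCDEF")
        sets = [{"A", "B"}, {"B", "C"}, {"B", "D"}]
        r1 = hub_intersection(*sets, de)
        r2 = hub_intersection(sets[2], sets[0], sets[1], de)
        assert list(r1.final.index) == list(r2.final.index)

    def test_gene_missing_from_de_rejected(self):
        with pytest.raises(ConfigError):
            hub_intersection({"Z"}, {"Z"}, {"Z"}, self._de("ABC"))
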