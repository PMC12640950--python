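"""PCA-based population selection: frequencies, retention, contributions,
intersection, count filter, merging, robustness."""

import numpy as np
import pandas as pd
import pytest

from immunohub.clustering import ClusterAssignment
from immunohub.errors import ConfigError
from immunohub.selection import (
    PCAResult,
    apply_count_filter,
    frequency_matrix,
    intersect_timepoints,
    merge_populations,
    pca_fit,
    retain_pcs,
    run_selection,
    select_populations,
    selection_robustness,
    variable_contributions,
)

from conftest import make_event_table


def _freq(data, columns=None):
    df = pd.DataFrame(data, columns=columns)
    df.index = pd.MultiIndex.from_tuples(
        [(f"D{i}", "CAR", "day11") for i in range(len(df))], names=["donor", "arm", "timepoint"]
    )
    return df


class TestFrequencyMatrix:
    def test_even_split_gives_fifty_fifty(self):
        table = make_event_table({"a": [0.0] * 4, "b": [0.0] * 4})
        freq = frequency_matrix(table, ClusterAssignment(np.array([0, 0, 1, 1])))
        assert list(freq.iloc[0]) == [50.0, 50.0]

    def test_one_three_split(self):
        table = make_event_table({"a": [0.0] * 4, "b": [0.0] * 4})
        freq = frequency_matrix(table, ClusterAssignment(np.array([0, 1, 1, 1])))
        assert list(freq.iloc[0]) == [25.0, 75.0]

    def test_rows_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        table = make_event_table({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        freq = frequency_matrix(table, ClusterAssignment(rng.integers(0, 4, 60)))
        np.testing.assert_allclose(freq.sum(axis=1), 100.0, atol=1e-9)

    def test_missing_expected_sample_is_error(self):
        table = make_event_table({"a": [0.0], "b": [0.0]})
        with pytest.raises(ConfigError, match="D9"):
            frequency_matrix(
                table,
                np.array([0]),
                expected_samples=[("D1", "CAR", "day11"), ("D9", "CAR", "day11")],
            )


class TestPCA:
    def test_perfectly_correlated_pair_is_rank_one(self):
        x = np.arange(10.0)
        freq = _freq({"v1": x, "v2": 2 * x + 3})
        pca = pca_fit(freq)
        assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        freq = _freq(rng.normal(size=(8, 5)))
        pca = pca_fit(freq)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_leading_fraction_near_uniform(self):
        """On isotropic data the leading variance fraction approaches 1/p
        (averaged over seeds, generous simulation tolerance)."""
        p, fractions = 4, []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            freq = _freq(rng.normal(size=(200, p)))
            fractions.append(pca_fit(freq).variance_fractions[0])
        assert np.mean(fractions) == pytest.approx(1 / p, abs=0.05)

    def test_constant_columns_dropped_with_warning(self):
        freq = _freq({"v1": np.arange(5.0), "v2": np.ones(5), "v3": np.arange(5.0)[::-1]})
        with pytest.warns(UserWarning, match="zero-variance"):
            pca = pca_fit(freq)
        assert list(pca.loadings.index) == ["v1", "v3"]

    def test_fewer_than_two_informative_columns_rejected(self):
        freq = _freq({"v1": np.arange(4.0), "v2": np.ones(4)})
        with pytest.raises(ConfigError):
            pca_fit(freq)


class TestRetainPcs:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ((0.75, 0.25), [0]),
            ((0.5, 0.5), [0, 1]),
            ((0.60, 0.20, 0.20), [0, 1]),
            ((0.70, 0.30), [0]),  # boundary: exactly 70% retains PC1 alone
        ],
    )
    def test_smallest_prefix_reaching_threshold(self, fractions, expected):
        fr = np.asarray(fractions, dtype=float)
        pca = PCAResult(
            eigenvalues=fr.copy(),
            variance_fractions=fr,
            loadings=pd.DataFrame(np.eye(len(fr))),
            scores=pd.DataFrame(np.zeros((2, len(fr)))),
            center=pd.Series(dtype=float),
            scale=pd.Series(dtype=float),
        )
        assert retain_pcs(pca, 0.70) == expected


class TestContributionsAndSelection:
    def test_correlated_pair_contributes_fifty_fifty(self):
        x = np.arange(12.0)
        pca = pca_fit(_freq({"v1": x, "v2": 3 * x}))
        contribs = variable_contributions(pca, [0])
        assert contribs.aggregate["v1"] == pytest.approx(50.0, abs=1e-9)
        assert contribs.aggregate["v2"] == pytest.approx(50.0, abs=1e-9)

    def test_per_pc_contributions_sum_to_hundred(self):
        rng = np.random.default_rng(4)
        pca = pca_fit(_freq(rng.normal(size=(10, 5))))
        contribs = variable_contributions(pca, retain_pcs(pca))
        np.testing.assert_allclose(contribs.per_pc.sum(axis=0), 100.0, atol=1e-9)

    def test_single_retained_pc_aggregate_equals_its_column(self):
        rng = np.random.default_rng(5)
        pca = pca_fit(_freq(rng.normal(size=(10, 4))))
        contribs = variable_contributions(pca, [0])
        np.testing.assert_allclose(contribs.aggregate, contribs.per_pc.iloc[:, 0])

    def test_selection_strictly_above_uniform(self):
        contribs = pd.Series({"v1": 60.0, "v2": 30.0, "v3": 10.0})
        assert select_populations(contribs) == {"v1"}

    def test_exactly_uniform_selects_nothing(self):
        contribs = pd.Series({"a": 100 / 3, "b": 100 / 3, "c": 100 / 3})
        with pytest.warns(UserWarning):
            assert select_populations(contribs) == set()


class TestIntersectionAndFilters:
    def test_exact_intersection(self):
        assert intersect_timepoints([{"A", "B", "C"}, {"B", "C", "D"}]) == {"B", "C"}

    def test_disjoint_sets_warn_and_empty(self):
        with pytest.warns(UserWarning):
            assert intersect_timepoints([{"A"}, {"B"}]) == set()

    def test_order_invariance(self):
        sets = [{"A", "B"}, {"B", "C"}, {"B"}]
        assert intersect_timepoints(sets) == intersect_timepoints(sets[::-1])

    def test_count_filter_boundary(self):
        """'less than 300 excluded': 299 goes, 300 stays."""
        sizes = {"p299": 299, "p300": 300, "p5000": 5000}
        kept = apply_count_filter({"p299", "p300", "p5000"}, sizes, min_total=300)
        assert kept == {"p300", "p5000"}

    def test_count_filter_empty_input(self):
        assert apply_count_filter(set(), {}, 300) == set()

    def test_count_filter_unknown_population(self):
        with pytest.raises(ConfigError):
            apply_count_filter({"x"}, {"y": 10}, 300)

    def test_merge_eleven_into_four(self):
        pops = {f"c{i}" for i in range(11)}
        merge_map = {
            "apoptotic": [f"c{i}" for i in range(4)],
            "resting": [f"c{i}" for i in range(4, 7)],
            "primed": [f"c{i}" for i in range(7, 9)],
            "other": [f"c{i}" for i in range(9, 11)],
        }
        merged, counts = merge_populations(pops, merge_map, {p: 10 for p in pops})
        assert merged == {"apoptotic", "resting", "primed", "other"}
        assert counts["apoptotic"] == 40

    def test_merge_identity_map_passthrough(self):
        merged, _ = merge_populations({"a", "b"}, {})
        assert merged == {"a", "b"}

    def test_merge_conserves_counts(self):
        merged, counts = merge_populations({"a", "b", "c"}, {"ab": ["a", "b"]}, {"a": 1, "b": 2, "c": 5})
        assert sum(counts.values()) == 8

    def test_double_assignment_rejected(self):
        with pytest.raises(ConfigError):
            merge_populations({"a"}, {"x": ["a"], "y": ["a"]})


class TestRunSelection:
    def test_nesting_invariant_and_determinism(self, immuno_fixture):
        from immunohub.events import arcsinh_transform, concat_event_tables

        tables, cfg, _ = immuno_fixture
        pooled = arcsinh_transform(concat_event_tables(list(tables.values())), cfg.cofactor)
        r1, a1 = run_selection(pooled, seed=3, k=15, n_restarts=1)
        r2, a2 = run_selection(pooled, seed=3, k=15, n_restarts=1)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        for tp, entry in r1.per_timepoint.items():
            assert r1.intersection <= entry["selected"]
        assert r1.after_count_filter <= r1.intersection
        assert r1.after_count_filter == r2.after_count_filter


class TestRobustness:
    def test_planted_shift_is_stable_and_seeded(self):
        """The planted shifted population survives cell bootstrap in most
        resamples; the stability vector is reproducible."""
        from immunohub.events import arcsinh_transform, concat_event_tables
        from immunohub.simulate import default_cyto_config, simulate_cytometry, cluster_truth_map

        cfg = default_cyto_config(21, cells_per_sample=700, n_donors=4, rare_total=0)
        tables, truth = simulate_cytometry(cfg)
        pooled = arcsinh_transform(concat_event_tables(list(tables.values())), cfg.cofactor)
        report, assignment = run_selection(pooled, seed=21, k=15, n_restarts=1)
        stability = selection_robustness(
            pooled, report, assignment, n_boot=10, seed=22, k=15, n_restarts=1
        )
        stability2 = selection_robustness(
            pooled, report, assignment, n_boot=10, seed=22, k=15, n_restarts=1
        )
        pd.testing.assert_series_equal(stability, stability2)
        tmap = cluster_truth_map(pooled, assignment.labels)
        planted_clusters = [
            c for c in report.after_count_filter
            if tmap.loc[c, "population"] == "CD4_apoptotic" and tmap.loc[c, "purity"] >= 0.5
        ]
        if planted_clusters:  # planted population reached the final set
            assert max(stability[c] for c in planted_clusters) >= 0.8
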