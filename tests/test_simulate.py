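"""Synthetic-data generators: determinism, conservation, planted structure."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from immunohub.errors import ConfigError
from immunohub.simulate import (
    PopulationSpec,
    SimCytoConfig,
    SimExprConfig,
    SimNetConfig,
    default_cyto_config,
    expression_sample_info,
    simulate_cytometry,
    simulate_expression,
    simulate_gene_sets,
    simulate_ppi,
)


def _two_pop_config(**kwargs):
    pops = (
        PopulationSpec("hi", (3.0, 3.0), (0.3, 0.3), 0.5),
        PopulationSpec("lo", (0.5, 0.5), (0.3, 0.3), 0.5),
    )
    defaults = dict(
        markers=("m1", "m2"),
        populations=pops,
        n_donors=1,
        timepoints=("day11",),
        cells_per_sample=10_000,
        donor_concentration=None,
        seed=5,
    )
    defaults.update(kwargs)
    return SimCytoConfig(**defaults)


class TestSimulateCytometry:
    def test_same_seed_same_tables(self):
        cfg = default_cyto_config(3, cells_per_sample=500, n_donors=2)
        t1, _ = simulate_cytometry(cfg)
        t2, _ = simulate_cytometry(cfg)
        for key in t1:
            pd.testing.assert_frame_equal(t1[key].data, t2[key].data)

    def test_balanced_multinomial_frequencies_within_binomial_se(self):
        """Two 50/50 populations, no donor noise: observed frequency within
        3 * sqrt(0.25/n) of 0.5 (binomial standard error)."""
        cfg = _two_pop_config()
        _, truth = simulate_cytometry(cfg)
        se3 = 3 * np.sqrt(0.25 / cfg.cells_per_sample)
        assert (np.abs(truth.frequencies["frequency"] - 0.5) < se3).all()

    def test_rare_population_flagged_sub_threshold(self):
        cfg = default_cyto_config(1, cells_per_sample=1000, rare_total=250)
        _, truth = simulate_cytometry(cfg)
        assert truth.flags["rare_artifact"] == "sub_threshold"
        pooled = truth.frequencies.query("population == 'rare_artifact'")["frequency"]
        assert int(round(pooled.sum() * 1000)) == 250

    def test_shifted_population_flagged(self):
        cfg = default_cyto_config(1, cells_per_sample=200)
        _, truth = simulate_cytometry(cfg)
        assert truth.flags["CD4_apoptotic"] == "planted_shift"
        assert truth.flags["CD8_resting"] == "null"

    def test_per_sample_frequencies_sum_to_one(self):
        cfg = default_cyto_config(2, cells_per_sample=777, n_donors=3)
        _, truth = simulate_cytometry(cfg)
        sums = truth.frequencies.groupby(["donor", "arm", "timepoint"])["frequency"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_zero_populations_rejected(self):
        with pytest.raises(ConfigError):
            SimCytoConfig(markers=("a", "b"), populations=(), seed=0)

    def test_frequencies_not_summing_rejected(self):
        pops = (PopulationSpec("x", (1.0, 1.0), (0.1, 0.1), 0.7),)
        with pytest.raises(ConfigError, match="sum to 1"):
            SimCytoConfig(markers=("a", "b"), populations=pops, seed=0)


class TestSimulateExpression:
    def test_same_seed_identical(self):
        cfg = SimExprConfig(n_genes=50, n_donors=2, seed=9)
        c1, _ = simulate_expression(cfg)
        c2, _ = simulate_expression(cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_counts_are_nonnegative_integers(self):
        cfg = SimExprConfig(n_genes=40, n_donors=3, seed=1)
        counts, _ = simulate_expression(cfg)
        assert (counts.to_numpy() >= 0).all()
        assert counts.to_numpy().dtype.kind == "i"

    def test_planted_log2fc_recovered_with_many_donors(self):
        """log2FC estimate from log2(CPM+1) within +-0.3 of a planted 2."""
        from immunohub.netrank import simple_paired_de

        cfg = SimExprConfig(n_genes=300, n_donors=20, planted_log2fc={7: 2.0}, seed=4)
        counts, _ = simulate_expression(cfg)
        de = simple_paired_de(counts, expression_sample_info(cfg))
        assert de.iloc[7]["log2fc"] == pytest.approx(2.0, abs=0.3)

    def test_single_donor_rejected(self):
        with pytest.raises(ConfigError):
            SimExprConfig(n_genes=10, n_donors=1, seed=0)

    def test_weak_planted_effect_rejected(self):
        with pytest.raises(ConfigError):
            SimExprConfig(n_genes=10, n_donors=2, planted_log2fc={0: 0.5}, seed=0)


class TestSimulatePPI:
    GENES = [f"G{i}" for i in range(60)]

    def test_full_density_module_is_complete(self):
        cfg = SimNetConfig(module_genes=tuple(self.GENES[:6]), module_density=1.0, seed=2)
        g = simulate_ppi(cfg, self.GENES)
        sub = g.subgraph(self.GENES[:6])
        assert sub.n_edges == 15  # complete graph on 6 nodes

    def test_preferential_attachment_has_hubs(self):
        """Max degree exceeds median degree for BA backgrounds (checked
        across seeds)."""
        for seed in range(5):
            g = simulate_ppi(SimNetConfig(seed=seed), self.GENES)
            deg = g.degrees()
            assert deg.max() > np.median(deg)

    def test_same_seed_same_edges(self):
        cfg = SimNetConfig(module_genes=tuple(self.GENES[:4]), module_density=0.5, seed=3)
        g1 = simulate_ppi(cfg, self.GENES)
        g2 = simulate_ppi(cfg, self.GENES)
        np.testing.assert_array_equal(g1.edges, g2.edges)

    def test_module_outside_universe_rejected(self):
        cfg = SimNetConfig(module_genes=("NOPE1", "NOPE2", "NOPE3"), seed=0)
        with pytest.raises(ConfigError):
            simulate_ppi(cfg, self.GENES)

    def test_no_self_loops(self):
        g = simulate_ppi(SimNetConfig(seed=1), self.GENES)
        assert (g.edges[:, 0] != g.edges[:, 1]).all()


class TestSimulateGeneSets:
    def test_planted_set_is_verbatim(self):
        sets = simulate_gene_sets([f"G{i}" for i in range(100)], ["G1", "G5"], n_null_sets=3, seed=0)
        assert sets["PLANTED_SET"] == ["G1", "G5"]
        assert len(sets) == 4
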