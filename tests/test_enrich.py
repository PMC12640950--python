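"""Gene-set analytics: signal-to-noise, GSEA running sum, ORA, GMT I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from immunohub.enrich import (
    GeneSet,
    RankedGeneList,
    gsea_es,
    gsea_significance,
    ora_hypergeometric,
    read_gmt,
    signal_to_noise_rank,
    write_gmt,
)
from immunohub.errors import ConfigError
from immunohub.oracles import gsea_es_bruteforce


def _ranked(n, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    return RankedGeneList(tuple(f"G{i:03d}" for i in range(n)), scores)


class TestSignalToNoise:
    def _expr(self, rows):
        return pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))])

    def test_equal_classes_score_zero(self):
        expr = self._expr([[5.0, 5.0, 5.0, 5.0]])
        out = signal_to_noise_rank(expr, ["A", "A", "B", "B"], "A", "B")
        assert out.scores[0] == 0.0

    def test_sigma_floor_closed_form(self):
        """A={2,2}, B={1,1}: floored sigmas 0.4 and 0.2 give s2n = 1.6667."""
        expr = self._expr([[2.0, 2.0, 1.0, 1.0]])
        out = signal_to_noise_rank(expr, ["A", "A", "B", "B"], "A", "B")
        assert out.scores[0] == pytest.approx(1 / 0.6, abs=1e-4)

    def test_label_swap_negates_scores(self):
        rng = np.random.default_rng(2)
        expr = self._expr(rng.normal(size=(30, 6)).tolist())
        labels = ["A", "B", "A", "B", "A", "B"]
        fwd = signal_to_noise_rank(expr, labels, "A", "B")
        rev = signal_to_noise_rank(expr, labels, "B", "A")
        fwd_map = dict(zip(fwd.genes, fwd.scores))
        rev_map = dict(zip(rev.genes, rev.scores))
        for g in fwd.genes:
            assert rev_map[g] == pytest.approx(-fwd_map[g], abs=1e-12)

    def test_single_sample_class_rejected(self):
        expr = self._expr([[1.0, 2.0, 3.0]])
        with pytest.raises(ConfigError):
            signal_to_noise_rank(expr, ["A", "B", "B"], "A", "B")


class TestGseaES:
    def test_single_member_at_top_unweighted(self):
        ranked = _ranked(20)
        score = gsea_es(ranked, GeneSet("s", (ranked.genes[0],)), weight_p=0)
        assert score.es == pytest.approx(1.0, abs=1e-12)
        assert score.leading_edge == (ranked.genes[0],)

    def test_single_member_at_bottom_unweighted(self):
        ranked = _ranked(20)
        score = gsea_es(ranked, GeneSet("s", (ranked.genes[-1],)), weight_p=0)
        assert score.es == pytest.approx(-1.0, abs=1e-12)
        assert score.leading_edge == (ranked.genes[-1],)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0])
    def test_matches_bruteforce_walk(self, weight_p):
        """ES equals an independent loop oracle to 1e-12 on random
        (list, set) instances."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(10, 40))
            ranked = _ranked(n, seed=int(rng.integers(1000)))
            size = int(rng.integers(1, n - 1))
            members = tuple(np.array(ranked.genes)[rng.choice(n, size, replace=False)])
            expected = gsea_es_bruteforce(ranked.genes, ranked.scores, members, weight_p)
            got = gsea_es(ranked, GeneSet("s", members), weight_p)
            assert got.es == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_metric_transform_when_unweighted(self):
        ranked = _ranked(25, seed=3)
        warped = RankedGeneList(ranked.genes, np.exp(ranked.scores))
        members = (ranked.genes[3], ranked.genes[10], ranked.genes[20])
        s1 = gsea_es(ranked, GeneSet("s", members), weight_p=0)
        s2 = gsea_es(warped, GeneSet("s", members), weight_p=0)
        assert s1.es == pytest.approx(s2.es, abs=1e-12)

    def test_set_covering_whole_list_rejected(self):
        ranked = _ranked(5)
        with pytest.raises(ConfigError):
            gsea_es(ranked, GeneSet("s", ranked.genes))

    def test_absent_set_rejected(self):
        ranked = _ranked(5)
        with pytest.raises(ConfigError):
            gsea_es(ranked, GeneSet("s", ("nope",)))


class TestGseaSignificance:
    def test_same_seed_identical_results(self):
        ranked = _ranked(200, seed=1)
        sets = [GeneSet(f"s{i}", tuple(np.array(ranked.genes)[i * 10 : i * 10 + 8])) for i in range(4)]
        r1 = gsea_significance(ranked, sets, n_perm=200, seed=3)
        r2 = gsea_significance(ranked, sets, n_perm=200, seed=3)
        assert [x.fdr_q for x in r1] == [x.fdr_q for x in r2]
        assert [x.p for x in r1] == [x.p for x in r2]

    def test_top_concentrated_set_is_significant(self):
        ranked = _ranked(300, seed=2)
        planted = GeneSet("planted", tuple(ranked.genes[:15]))
        nulls = [
            GeneSet(f"n{i}", tuple(np.array(ranked.genes)[np.random.default_rng(i).choice(300, 15, replace=False)]))
            for i in range(5)
        ]
        results = {r.name: r for r in gsea_significance(ranked, [planted, *nulls], n_perm=500, seed=0)}
        assert results["planted"].fdr_q < 0.05
        assert results["planted"].nes > 1

    def test_phenotype_mode_needs_two_per_arm(self):
        ranked = _ranked(30)
        with pytest.raises(ConfigError):
            gsea_significance(
                ranked, [GeneSet("s", ranked.genes[:3])], n_perm=100, mode="phenotype",
                expr=pd.DataFrame(np.zeros((30, 3)), index=list(ranked.genes)),
                labels=["A", "B", "B"], classes=("A", "B"),
            )


class TestORA:
    def test_closed_form_complete_overlap(self):
        """Universe 10, set 5, hits 5, overlap 5: p = 1/C(10,5)."""
        universe = [f"g{i}" for i in range(10)]
        out = ora_hypergeometric(universe[:5], GeneSet("s", tuple(universe[:5])), universe)
        assert out.loc["s", "p"] == pytest.approx(1 / comb(10, 5), rel=1e-9)

    def test_zero_overlap_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = ora_hypergeometric(universe[:2], GeneSet("s", tuple(universe[5:])), universe)
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_matches_enumeration_on_small_universes(self):
        """Upper-tail probability equals explicit enumeration over all
        overlap outcomes for universes up to 15."""
        rng = np.random.default_rng(4)
        for _ in range(30):
            M = int(rng.integers(5, 16))
            universe = [f"g{i}" for i in range(M)]
            set_size = int(rng.integers(1, M))
            n_hits = int(rng.integers(1, M))
            members = list(np.array(universe)[rng.choice(M, set_size, replace=False)])
            hits = list(np.array(universe)[rng.choice(M, n_hits, replace=False)])
            overlap = len(set(members) & set(hits))
            total = comb(M, n_hits)
            expected = sum(
                comb(set_size, k) * comb(M - set_size, n_hits - k)
                for k in range(overlap, min(set_size, n_hits) + 1)
            ) / total
            out = ora_hypergeometric(hits, GeneSet("s", tuple(members)), universe)
            assert out.loc["s", "p"] == pytest.approx(expected, rel=1e-9)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ConfigError):
            ora_hypergeometric(["x"], GeneSet("s", ("a",)), ["a", "b"])


class TestGMT:
    def test_roundtrip(self, tmp_path):
        sets = [GeneSet("alpha", ("g1", "g2"), "first"), GeneSet("beta", ("g3",), "second")]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [(s.name, s.members) for s in back] == [(s.name, s.members) for s in sets]
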