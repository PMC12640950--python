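"""Seeded validation experiments shared by the test suite and the
acceptance script.

Each function runs a self-contained experiment — oracle comparison,
planted-structure recovery, or null calibration — and returns plain
numbers. Replicate counts are parameters so callers can trade Monte-Carlo
precision against wall clock; the defaults are the sizes the package's own
documentation quotes.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import louvain_cluster
from .enrich import GeneSet, RankedGeneList, gsea_significance
from .graph import WeightedGraph
from .netrank import mcc_rank, mcode_modules, rf_importance_rank, simple_paired_de, filter_degs
from .oracles import max_modularity_bruteforce, mcc_bruteforce, modularity
from .selection import run_selection
from .simulate import (
    SimExprConfig,
    cluster_truth_map,
    default_cyto_config,
    expression_sample_info,
    simulate_cytometry,
    simulate_expression,
)
from .stats import longitudinal_compare
from .events import arcsinh_transform, concat_event_tables

__all__ = [
    "random_connected_graph",
    "louvain_oracle_suite",
    "mcc_oracle_suite",
    "mcode_planted_clique_recovery",
    "selection_recovery",
    "rf_recovery",
    "type_i_error_rate",
    "de_null_calibration",
    "gsea_null_pvalues",
]


# ---------------------------------------------------------------------------
# graph oracle suites
# ---------------------------------------------------------------------------
def random_connected_graph(rng: np.random.Generator, max_nodes: int = 8) -> WeightedGraph:
    """A random connected Erdos-Renyi graph with 3..max_nodes nodes."""
    while True:
        n = int(rng.integers(3, max_nodes + 1))
        p = rng.uniform(0.3, 0.9)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if nx.is_connected(g):
            edges = np.array(sorted((min(u, v), max(u, v)) for u, v in g.edges()), dtype=np.int64)
            return WeightedGraph(tuple(range(n)), edges, np.ones(len(edges)))


def louvain_oracle_suite(n_graphs: int = 200, seed: int = 0, max_nodes: int = 8, tol: float = 1e-9) -> float:
    """Fraction of random connected graphs on which Louvain attains the
    exhaustive maximum modularity (ties in Q allowed)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x10A]))
    matches = 0
    for i in range(n_graphs):
        g = random_connected_graph(rng, max_nodes)
        q_best, _ = max_modularity_bruteforce(g)
        part = louvain_cluster(g, seed=seed + i)
        q_louvain = modularity(g, part.labels)
        if q_louvain >= q_best - tol:
            matches += 1
    return matches / n_graphs


def mcc_oracle_suite(n_graphs: int = 100, seed: int = 0, max_nodes: int = 12) -> float:
    """Fraction of random graphs with exact MCC agreement against the
    exhaustive clique-enumeration oracle (isolated nodes included)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3CC]))
    matches = 0
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_nodes + 1))
        p = rng.uniform(0.1, 0.9)
        g_nx = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        edges = np.array(sorted((min(u, v), max(u, v)) for u, v in g_nx.edges()), dtype=np.int64)
        edges = edges.reshape(-1, 2)
        g = WeightedGraph(tuple(range(n)), edges, np.ones(len(edges)))
        expected = mcc_bruteforce(g)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = mcc_rank(g, top_n=n)
        ok = all(int(got.loc[v, "mcc"]) == expected[v] for v in g.node_names)
        matches += int(ok)
    return matches / n_graphs


def mcode_planted_clique_recovery(
    n_seeds: int = 40, seed: int = 0, n_nodes: int = 100, edge_prob: float = 0.02, clique_size: int = 6
) -> float:
    """Fraction of random backgrounds in which the top MCODE module
    contains the whole planted clique."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x3C0DE]))
    hits = 0
    for _ in range(n_seeds):
        g_nx = nx.gnp_random_graph(n_nodes, edge_prob, seed=int(rng.integers(2**31 - 1)))
        planted = list(rng.choice(n_nodes, size=clique_size, replace=False))
        for i, u in enumerate(planted):
            for v in planted[i + 1 :]:
                g_nx.add_edge(u, v)
        pairs = sorted((min(u, v), max(u, v)) for u, v in g_nx.edges())
        g = WeightedGraph(
            tuple(range(n_nodes)), np.array(pairs, dtype=np.int64), np.ones(len(pairs))
        )
        modules = mcode_modules(g)
        if modules and set(planted) <= set(modules[0].members):
            hits += 1
    return hits / n_seeds


# ---------------------------------------------------------------------------
# immunophenotyping recovery
# ---------------------------------------------------------------------------
def selection_recovery(
    n_reps: int = 50,
    seed: int = 0,
    cells_per_sample: int = 10_000,
    n_donors: int = 6,
    k: int = 30,
    purity_cutoff: float = 0.5,
) -> dict:
    """Planted-shift recovery through the full immunophenotyping pipeline.

    Each replicate simulates the study-condition cohort (planted >10-point
    arm shift in one population, planted sub-300-cell rare population),
    runs clustering + PCA selection end to end, and maps final clusters to
    planted populations by majority truth label. Reports the fraction of
    replicates whose final set contains the shifted population, the
    fraction in which the rare population stays excluded, and the fraction
    in which the shifted population's final cluster tests at p < 0.05.
    """
    recovered = excluded = significant = 0
    for r in range(n_reps):
        cfg = default_cyto_config(seed + 1000 * r, cells_per_sample=cells_per_sample, n_donors=n_donors)
        tables, truth = simulate_cytometry(cfg)
        pooled = arcsinh_transform(concat_event_tables(list(tables.values())), cfg.cofactor)
        report, assignment = run_selection(pooled, seed=seed + 1000 * r, k=k, n_restarts=1)
        tmap = cluster_truth_map(pooled, assignment.labels)
        planted = [p for p, f in truth.flags.items() if f == "planted_shift"]
        rare = [p for p, f in truth.flags.items() if f == "sub_threshold"]
        final_clusters = report.after_count_filter
        final_pops = {
            (tmap.loc[c, "population"] if tmap.loc[c, "purity"] >= purity_cutoff else None)
            for c in final_clusters
        }
        hit = any(p in final_pops for p in planted)
        recovered += int(hit)
        excluded += int(not any(p in final_pops for p in rare))
        if hit:
            from .pipelines import final_frequency_table

            freq = final_frequency_table(report)
            stats = longitudinal_compare(freq, cfg.arms)
            sig_clusters = {
                int(row["population"])
                for _, row in stats.iterrows()
                if not row["untestable"] and row["p"] < 0.05
            }
            sig_pops = {
                tmap.loc[c, "population"]
                for c in sig_clusters
                if tmap.loc[c, "purity"] >= purity_cutoff
            }
            significant += int(any(p in sig_pops for p in planted))
    return {
        "recovery_rate": recovered / n_reps,
        "sub300_exclusion_rate": excluded / n_reps,
        "significant_rate": significant / n_reps,
        "n_reps": n_reps,
    }


def type_i_error_rate(n_seeds: int = 50, seed: int = 0, cells_per_sample: int = 2000) -> float:
    """Fraction of raw p < 0.05 in arm comparisons of null synthetic cohorts.

    Uses the generator's realized true-population frequencies (no planted
    effect, no rare population) so the calibration isolates the paired
    test rather than the clustering.
    """
    n_sig = n_tests = 0
    for r in range(n_seeds):
        cfg = default_cyto_config(
            seed + 7919 * r, cells_per_sample=cells_per_sample, rare_total=0, shift_multiplier=1.0
        )
        _, truth = simulate_cytometry(cfg)
        freq = (
            truth.frequencies.pivot_table(
                index=["donor", "arm", "timepoint"], columns="population", values="frequency"
            )
            * 100.0
        )
        stats = longitudinal_compare(freq, cfg.arms)
        ok = ~stats["untestable"]
        n_sig += int((stats.loc[ok, "p"] < 0.05).sum())
        n_tests += int(ok.sum())
    return n_sig / n_tests if n_tests else float("nan")


# ---------------------------------------------------------------------------
# expression benchmarks
# ---------------------------------------------------------------------------
def rf_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n_genes: int = 500,
    n_samples: int = 40,
    n_informative: int = 10,
    effect_sd: float = 2.0,
    n_trees: int = 2000,
    top_n: int = 20,
) -> float:
    """Fraction of seeds recovering >= 8 of the planted informative genes
    in the combined random-forest top ``top_n``."""
    hits = 0
    for r in range(n_seeds):
        rng = np.random.default_rng(np.random.SeedSequence([seed + r, 0x2F]))
        X = rng.normal(size=(n_genes, n_samples))
        labels = np.array(["A", "B"])[np.arange(n_samples) % 2]
        informative = rng.choice(n_genes, size=n_informative, replace=False)
        X[np.ix_(informative, np.flatnonzero(labels == "B"))] += effect_sd
        expr = pd.DataFrame(X, index=[f"G{i:04d}" for i in range(n_genes)])
        ranking = rf_importance_rank(expr, labels, n_trees=n_trees, seed=seed + r)
        top = set(ranking.index[:top_n])
        planted_names = {f"G{i:04d}" for i in informative}
        if len(top & planted_names) >= 8:
            hits += 1
    return hits / n_seeds


def de_null_calibration(n_seeds: int = 20, seed: int = 0, n_genes: int = 300, n_donors: int = 3) -> float:
    """Mean fraction of genes passing the DEG filter on null paired counts."""
    fractions = []
    for r in range(n_seeds):
        cfg = SimExprConfig(n_genes=n_genes, n_donors=n_donors, planted_log2fc={}, seed=seed + 31 * r)
        counts, _ = simulate_expression(cfg)
        de = simple_paired_de(counts, expression_sample_info(cfg))
        fractions.append(len(filter_degs(de)) / n_genes)
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# GSEA calibration
# ---------------------------------------------------------------------------
def gsea_null_pvalues(
    n_sets: int = 500, seed: int = 0, n_genes: int = 1000, set_size: int = 20, n_perm: int = 1000
) -> np.ndarray:
    """Nominal GSEA p-values for random (null) gene sets on a random ranking."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x65]))
    scores = np.sort(rng.normal(size=n_genes))[::-1]
    genes = tuple(f"G{i:04d}" for i in range(n_genes))
    ranked = RankedGeneList(genes, scores)
    sets = []
    for i in range(n_sets):
        members = rng.choice(n_genes, size=set_size, replace=False)
        sets.append(GeneSet(f"S{i:03d}", tuple(genes[j] for j in np.sort(members))))
    results = gsea_significance(ranked, sets, n_perm=n_perm, seed=seed)
    return np.array([r.p for r in results])
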