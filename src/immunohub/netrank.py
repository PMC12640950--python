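"""Hub-gene discovery from paired RNA-seq and a protein-interaction network.

Pipeline: a deliberately simple paired differential-expression stage on
log2(CPM+1) (a precomputed DE table can be supplied instead), the DEG
filter |log2FC| >= 1 and BH-adjusted Q <= 0.05 (both boundaries
inclusive), then three independent rankings of the DEG-induced interaction
network and expression matrix —

* **MCC** (Maximal Clique Centrality): for each node, the sum over its
  maximal cliques C of (|C|-1)!. The flagship CytoHubba metric.
* **MCODE**: core-based vertex weighting, greedy seeded expansion, haircut
  post-processing; returns densely connected modules scored by
  density x size.
* **Random forest**: classify arm from expression over DEGs; rank genes by
  out-of-bag permutation importance (mean decrease in accuracy) and
  impurity importance (mean decrease in Gini), combined as the mean of the
  two rank positions.

The hub set is the exact three-way intersection, annotated with regulation
direction from the DE table.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices, _get_n_samples_bootstrap
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .graph import WeightedGraph

__all__ = [
    "simple_paired_de",
    "filter_degs",
    "mcc_rank",
    "ModuleResult",
    "mcode_modules",
    "rf_importance_rank",
    "HubReport",
    "hub_intersection",
]


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------
def simple_paired_de(counts: pd.DataFrame, sample_info: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test on log2(CPM+1) per gene; BH-adjusted Q.

    ``counts`` is genes x samples; ``sample_info`` is indexed by sample
    name with columns ``donor`` and ``arm`` (two arms, both present for
    every donor). log2FC is the mean per-donor difference of log2(CPM+1),
    second arm minus first. Genes with zero counts everywhere get
    log2FC=0, Q=1 and are flagged rather than erroring.
    """
    arms = list(dict.fromkeys(sample_info["arm"]))
    if len(arms) != 2:
        raise ConfigError(f"need exactly two arms, got {arms}")
    donors = list(dict.fromkeys(sample_info["donor"]))
    if len(donors) < 2:
        raise ConfigError("paired DE requires >= 2 donors")
    cols_a, cols_b = [], []
    for donor in donors:
        sub = sample_info[sample_info["donor"] == donor]
        for arm, acc in ((arms[0], cols_a), (arms[1], cols_b)):
            match = sub.index[sub["arm"] == arm]
            if len(match) != 1:
                raise ConfigError(f"donor {donor!r} lacks a unique sample in arm {arm!r}")
            acc.append(match[0])

    cpm = counts / counts.sum(axis=0) * 1e6
    log_expr = np.log2(cpm + 1.0)
    diff = log_expr[cols_b].to_numpy() - log_expr[cols_a].to_numpy()
    n = diff.shape[1]
    mean_d = diff.mean(axis=1)
    sd_d = diff.std(axis=1, ddof=1)

    all_zero = counts.sum(axis=1).to_numpy() == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    # degenerate variance: identical differences across donors
    zero_sd = sd_d == 0
    p[zero_sd & (mean_d == 0)] = 1.0
    t[zero_sd & (mean_d == 0)] = 0.0
    p[zero_sd & (mean_d != 0)] = 0.0
    p[all_zero] = 1.0
    t[all_zero] = 0.0
    mean_d[all_zero] = 0.0

    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "log2fc": mean_d,
            "t": t,
            "p": p,
            "q": q,
            "mean_expr": log_expr.mean(axis=1),
            "all_zero": all_zero,
        },
        index=counts.index,
    )
    out.index.name = "gene"
    out.loc[all_zero, "q"] = 1.0
    return out


def filter_degs(de: pd.DataFrame, lfc_min: float = 1.0, q_max: float = 0.05) -> pd.DataFrame:
    """DEGs: |log2FC| >= lfc_min AND Q <= q_max, both boundaries inclusive.

    Returns the filtered rows with an added ``direction`` column
    (up/down, second arm relative to first).
    """
    mask = (de["log2fc"].abs() >= lfc_min) & (de["q"] <= q_max)
    out = de.loc[mask].copy()
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


# ---------------------------------------------------------------------------
# MCC
# ---------------------------------------------------------------------------
def mcc_rank(g: WeightedGraph, top_n: int | None = None) -> pd.DataFrame:
    """Maximal Clique Centrality ranking.

    MCC(v) = sum over maximal cliques C containing v (|C| >= 2) of
    (|C|-1)!; isolated nodes score 0. Ties break by degree (descending)
    then node id. ``top_n`` larger than the graph returns everything with
    a warning.
    """
    nxg = g.to_networkx()
    scores = {v: 0 for v in nxg.nodes()}
    for clique in nx.find_cliques(nxg):
        if len(clique) < 2:
            continue
        contribution = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contribution
    deg = dict(nxg.degree())
    ranked = sorted(scores, key=lambda v: (-scores[v], -deg[v], str(v)))
    if top_n is None:
        top_n = len(ranked)
    elif top_n > len(ranked):
        warnings.warn(f"top_n={top_n} exceeds graph size {len(ranked)}; returning all", stacklevel=2)
        top_n = len(ranked)
    chosen = ranked[:top_n]
    return pd.DataFrame({"gene": chosen, "mcc": [scores[v] for v in chosen],
                         "degree": [deg[v] for v in chosen]}).set_index("gene")


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------
@dataclass
class ModuleResult:
    members: tuple
    score: float
    density: float
    seed_node: object


def _mcode_weights(nxg: nx.Graph) -> dict:
    """Core-based vertex weight: k of the highest k-core of the closed
    neighbourhood, times that core's density."""
    weights = {}
    for v in nxg.nodes():
        nbhd = list(nxg.neighbors(v)) + [v]
        sub = nxg.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            weights[v] = 0.0
            continue
        core_numbers = nx.core_number(sub)
        k_max = max(core_numbers.values())
        core_nodes = [u for u, c in core_numbers.items() if c >= k_max]
        core = sub.subgraph(core_nodes)
        n = core.number_of_nodes()
        density = 2 * core.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        weights[v] = k_max * density
    return weights


def mcode_modules(
    g: WeightedGraph,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
    fluff: bool = False,
) -> list[ModuleResult]:
    """MCODE dense-module detection with the published defaults.

    Stage 1 weights vertices by their neighbourhood's highest k-core
    (k times core density); stage 2 grows a module from each highest-weight
    unvisited seed, greedily admitting unvisited neighbours whose weight is
    at least ``seed_weight * (1 - node_score_cutoff)``; stage 3 removes
    degree-1 members (haircut) and discards modules without a
    ``k_core``-core. Module score = density x size; output sorted by
    score. The fluff post-processing stage is not implemented.
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not supported")
    if not (0 <= node_score_cutoff < 1):
        raise ConfigError("node_score_cutoff must lie in [0, 1)")
    nxg = g.to_networkx()
    if nxg.number_of_nodes() == 0:
        return []
    weights = _mcode_weights(nxg)
    order = sorted(nxg.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    modules: list[ModuleResult] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        visited.add(seed)
        while frontier:
            u = frontier.pop()
            for w in nxg.neighbors(u):
                if w not in visited and weights[w] >= threshold:
                    visited.add(w)
                    members.add(w)
                    frontier.append(w)
        sub = nxg.subgraph(members)
        if haircut:
            keep = [v for v in sub.nodes() if sub.degree(v) >= 2]
            sub = nxg.subgraph(keep)
        if sub.number_of_nodes() < 2:
            continue
        if nx.k_core(sub, k_core).number_of_nodes() == 0:
            continue
        n = sub.number_of_nodes()
        density = 2 * sub.number_of_edges() / (n * (n - 1))
        modules.append(
            ModuleResult(
                members=tuple(sorted(sub.nodes(), key=str)),
                score=density * n,
                density=density,
                seed_node=seed,
            )
        )
    modules.sort(key=lambda m: (-m.score, -len(m.members), str(m.members)))
    return modules


# ---------------------------------------------------------------------------
# random forest importance
# ---------------------------------------------------------------------------
def rf_importance_rank(
    expr: pd.DataFrame,
    labels: Sequence[str],
    n_trees: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-forest gene ranking by MDA and mean decrease in Gini.

    ``expr`` is genes x samples (typically log2(CPM+1) over the DEGs);
    ``labels`` gives each sample's arm. Mean decrease in accuracy is
    out-of-bag permutation importance: per feature, one seeded permutation
    of its column, accuracy measured on each tree's out-of-bag samples
    (batched through a single forest prediction pass). Mean decrease in
    Gini is the forest's impurity importance. The combined rank is the
    mean of the two rank positions (ascending = more important).
    """
    X = expr.to_numpy(dtype=float).T  # samples x genes
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ConfigError("labels must match the sample count")
    classes, y_enc = np.unique(y, return_inverse=True)
    if len(classes) != 2 or np.bincount(y_enc).min() < 2:
        raise ConfigError("need two arms with >= 2 samples each")
    n, p = X.shape

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xF07E]))
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(seed) & 0x7FFFFFFF, n_jobs=1, bootstrap=True
    )
    forest.fit(X, y_enc)
    mdg = forest.feature_importances_

    # one shared permutation per feature; stack all permuted matrices so each
    # tree predicts once over (p * n) rows (sklearn trees want C-order float32
    # when validation is skipped)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    X_big = np.repeat(X32[None, :, :], p, axis=0)  # (p, n, p)
    for f in range(p):
        X_big[f, :, f] = X32[rng.permutation(n), f]
    X_big = np.ascontiguousarray(X_big.reshape(p * n, p))

    # classic per-tree decrease: for each tree, accuracy on its own OOB
    # samples before and after the permutation, averaged over trees (the
    # per-tree granularity matters — forest-level majority votes are almost
    # insensitive to a single feature when informative features are
    # redundant)
    n_samples_bootstrap = _get_n_samples_bootstrap(n, forest.max_samples, None)
    mda_sum = np.zeros(p)
    n_used = 0
    for tree in forest.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n_samples_bootstrap, None)
        if len(oob) == 0:
            continue
        pred = tree.predict(X32, check_input=False).astype(int)
        acc_tree = (pred[oob] == y_enc[oob]).mean()
        pred_big = tree.predict(X_big, check_input=False).astype(int).reshape(p, n)
        acc_perm = (pred_big[:, oob] == y_enc[oob]).mean(axis=1)
        mda_sum += acc_tree - acc_perm
        n_used += 1
    mda = mda_sum / n_used if n_used else np.full(p, np.nan)

    genes = list(expr.index)
    df = pd.DataFrame({"gene": genes, "mda": mda, "mdg": mdg}).set_index("gene")
    # rank positions: descending importance, stable tie-break by gene id
    order_mda = df.sort_values(["mda"], ascending=False, kind="stable").index
    order_mdg = df.sort_values(["mdg"], ascending=False, kind="stable").index
    df["rank_mda"] = pd.Series(range(1, p + 1), index=order_mda)
    df["rank_mdg"] = pd.Series(range(1, p + 1), index=order_mdg)
    df["combined_rank"] = (df["rank_mda"] + df["rank_mdg"]) / 2.0
    return df.sort_values(["combined_rank", "gene"], kind="stable")


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------
@dataclass
class HubReport:
    mcc_set: tuple
    mcode_set: tuple
    rf_set: tuple
    final: pd.DataFrame           # gene, log2fc, direction
    venn_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mcc_set": list(self.mcc_set),
            "mcode_set": list(self.mcode_set),
            "rf_set": list(self.rf_set),
            "final": self.final.reset_index().to_dict(orient="records"),
            "venn_counts": self.venn_counts,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def hub_intersection(
    mcc_set: Sequence, mcode_set: Sequence, rf_set: Sequence, de: pd.DataFrame
) -> HubReport:
    """Exact three-way intersection with regulation direction and Venn counts."""
    a, b, c = set(mcc_set), set(mcode_set), set(rf_set)
    for gene in a | b | c:
        if gene not in de.index:
            raise ConfigError(f"gene {gene!r} absent from the DE table")
    final_genes = sorted(a & b & c, key=str)
    final = de.loc[final_genes, ["log2fc"]].copy()
    final["direction"] = np.where(final["log2fc"] >= 0, "up", "down")
    venn = {
        "mcc_only": len(a - b - c),
        "mcode_only": len(b - a - c),
        "rf_only": len(c - a - b),
        "mcc_mcode": len((a & b) - c),
        "mcc_rf": len((a & c) - b),
        "mcode_rf": len((b & c) - a),
        "all_three": len(a & b & c),
    }
    return HubReport(
        mcc_set=tuple(sorted(a, key=str)),
        mcode_set=tuple(sorted(b, key=str)),
        rf_set=tuple(sorted(c, key=str)),
        final=final,
        venn_counts=venn,
    )
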