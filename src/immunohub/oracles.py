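"""Brute-force reference computations for validating the fast paths.

These are deliberately naive, exhaustive implementations — partition
enumeration for modularity, bitmask clique enumeration for MCC, a direct
loop for the GSEA running sum — kept entirely independent of the
production code they are used to check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from .graph import WeightedGraph

__all__ = [
    "all_partitions",
    "modularity",
    "max_modularity_bruteforce",
    "mcc_bruteforce",
    "gsea_es_bruteforce",
]


def all_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i: int, max_label: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(max_label + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_label, lab))

    if n == 0:
        return
    yield from rec(1, 0)


def modularity(g: WeightedGraph, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Newman modularity of a labelled partition, directly from the definition."""
    n = g.n_nodes
    A = np.zeros((n, n))
    for (i, j), w in zip(g.edges, g.weights):
        A[i, j] = A[j, i] = w
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    B = A - resolution * np.outer(k, k) / two_m
    same = labels[:, None] == labels[None, :]
    return float((B * same).sum() / two_m)


def max_modularity_bruteforce(g: WeightedGraph) -> tuple[float, np.ndarray]:
    """Exhaustive maximum-modularity partition (feasible for n <= ~10)."""
    n = g.n_nodes
    A = np.zeros((n, n))
    for (i, j), w in zip(g.edges, g.weights):
        A[i, j] = A[j, i] = w
    two_m = A.sum()
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / two_m if two_m else A
    best_q, best_labels = -np.inf, None
    for labels in all_partitions(n):
        same = labels[:, None] == labels[None, :]
        q = (B * same).sum() / two_m if two_m else 0.0
        if q > best_q:
            best_q, best_labels = q, labels
    return float(best_q), best_labels


def mcc_bruteforce(g: WeightedGraph) -> dict:
    """MCC via exhaustive subset enumeration (feasible for n <= ~14).

    Enumerates every vertex subset, keeps the cliques, filters to maximal
    cliques, then scores each node as the sum of (|C|-1)! over maximal
    cliques of size >= 2 containing it.
    """
    n = g.n_nodes
    adj = [0] * n
    for i, j in g.edges:
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    cliques = []
    for mask in range(1, 1 << n):
        nodes = [v for v in range(n) if mask >> v & 1]
        if all(adj[u] >> v & 1 for u, v in combinations(nodes, 2)):
            cliques.append(mask)
    clique_set = set(cliques)
    maximal = []
    for mask in cliques:
        if not any(
            (mask | (1 << v)) in clique_set for v in range(n) if not mask >> v & 1
        ):
            maximal.append(mask)
    scores = {name: 0 for name in g.node_names}
    for mask in maximal:
        size = bin(mask).count("1")
        if size < 2:
            continue
        contribution = math.factorial(size - 1)
        for v in range(n):
            if mask >> v & 1:
                scores[g.node_names[v]] += contribution
    return scores


def gsea_es_bruteforce(genes, scores, members, weight_p: float) -> float:
    """GSEA enrichment score via an explicit walk down the ranked list."""
    members = set(members)
    n = len(genes)
    n_hits = sum(1 for g in genes if g in members)
    total = sum(abs(s) ** weight_p for g, s in zip(genes, scores) if g in members)
    running = []
    hit_cum = 0.0
    miss_count = 0
    for g, s in zip(genes, scores):
        if g in members:
            hit_cum += (abs(s) ** weight_p) if total > 0 else 1.0
        else:
            miss_count += 1
        denom = total if total > 0 else float(n_hits)
        running.append(hit_cum / denom - miss_count / (n - n_hits))
    best = 0.0
    for value in running:
        if abs(value) > abs(best):
            best = value
    return best
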