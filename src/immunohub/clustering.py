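"""PhenoGraph-style clustering of cytometry events.

The construction follows the classic recipe: a k-nearest-neighbour graph
on the arcsinh-transformed marker matrix (Euclidean distance), edge
weights refined to the Jaccard index of the two endpoints' kNN sets
(zero-Jaccard pairs dropped), and Louvain community detection on the
weighted graph. A t-SNE projection is provided for display only, and
per-cluster median marker profiles with hierarchical row/column ordering
summarise what each cluster is.

Implementation notes
--------------------
* Jaccard weights are computed only on the symmetrised kNN edge list (the
  restricted pair set), with a small numba kernel — the graph for a pooled
  timepoint can hold a few hundred thousand nodes.
* Louvain is implemented natively: a numba CSR local-move/aggregation pass
  from singletons at any scale, plus — on small graphs — seeded multistart
  from random initial partitions (best modularity wins), because greedy
  Louvain from singletons can stall in local optima that multistart
  escapes. Labels are relabelled by descending cluster size, which makes
  the output deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial import cKDTree
from sklearn.manifold import TSNE

from .errors import ConfigError
from .events import EventTable
from .graph import WeightedGraph

__all__ = [
    "ClusterAssignment",
    "MedianProfile",
    "build_knn_jaccard_graph",
    "louvain_cluster",
    "tsne_embed",
    "cluster_median_profile",
]


@dataclass
class ClusterAssignment:
    """Per-cell integer labels, contiguous from 0, ordered by cluster size."""

    labels: np.ndarray
    modularity: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if len(self.labels) and (uniq[0] != 0 or uniq[-1] != len(uniq) - 1):
            raise ConfigError("cluster labels must be contiguous from 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


@dataclass
class MedianProfile:
    """Clusters x markers matrix of median intensities with dendrogram orders."""

    values: pd.DataFrame
    row_order: list
    col_order: list

    def ordered(self) -> pd.DataFrame:
        return self.values.iloc[self.row_order, self.col_order]


@njit(cache=False)
def _pair_intersections(neigh_sorted, src, dst):  # pragma: no cover - jitted
    out = np.empty(len(src), np.int64)
    k = neigh_sorted.shape[1]
    for e in range(len(src)):
        a = neigh_sorted[src[e]]
        b = neigh_sorted[dst[e]]
        i = 0
        j = 0
        c = 0
        while i < k and j < k:
            if a[i] == b[j]:
                c += 1
                i += 1
                j += 1
            elif a[i] < b[j]:
                i += 1
            else:
                j += 1
        out[e] = c
    return out


def build_knn_jaccard_graph(matrix: np.ndarray, k: int) -> WeightedGraph:
    """kNN graph (Euclidean) with Jaccard-index edge weights.

    Each cell's k nearest neighbours (self excluded) define a directed
    graph; the symmetrised edge set is weighted by the Jaccard index of the
    endpoints' neighbour sets, and zero-Jaccard pairs are dropped.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ConfigError("matrix must be 2-D (cells x markers)")
    n = X.shape[0]
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k >= n:
        raise ConfigError(f"k={k} must be smaller than the number of cells ({n})")
    tree = cKDTree(X)
    _, ind = tree.query(X, k=k + 1)
    ind = ind.astype(np.int64)
    # drop self from each neighbour list; with duplicated rows self may not
    # come first (or at all), so stably sort self-entries to the back and
    # keep the first k in distance order
    is_self = ind == np.arange(n)[:, None]
    key = is_self.astype(np.int64) * (k + 2) + np.arange(k + 1)[None, :]
    order = np.argsort(key, axis=1, kind="stable")
    neigh = np.take_along_axis(ind, order, axis=1)[:, :k]
    neigh_sorted = np.sort(neigh, axis=1)

    src = np.repeat(np.arange(n, dtype=np.int64), k)
    dst = neigh.reshape(-1)
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    code = np.sort(lo * n + hi)  # sort+diff dedup (much faster than np.unique here)
    keep_first = np.empty(len(code), dtype=bool)
    keep_first[0] = True
    np.not_equal(code[1:], code[:-1], out=keep_first[1:])
    uniq_code = code[keep_first]
    lo_u = (uniq_code // n).astype(np.int64)
    hi_u = (uniq_code % n).astype(np.int64)

    inter = _pair_intersections(neigh_sorted, lo_u, hi_u)
    union = 2 * k - inter
    jac = inter / union
    keep = jac > 0
    edges = np.column_stack([lo_u[keep], hi_u[keep]])
    return WeightedGraph(tuple(range(n)), edges, jac[keep])


def _relabel_by_size(raw_labels: np.ndarray) -> np.ndarray:
    _, compact = np.unique(raw_labels, return_inverse=True)
    sizes = np.bincount(compact)
    order = np.lexsort((np.arange(len(sizes)), -sizes))  # size desc, stable
    remap = np.empty(len(sizes), dtype=np.int64)
    remap[order] = np.arange(len(sizes))
    return remap[compact]


def _dense_modularity(W: np.ndarray, labels: np.ndarray, resolution: float) -> float:
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    s = W.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((W - resolution * np.outer(s, s) / two_m) * same).sum() / two_m)


def _local_moves(W: np.ndarray, labels: np.ndarray, resolution: float, rng) -> bool:
    """One Louvain level: greedy single-node moves until convergence.

    ``W`` is the (possibly aggregated) symmetric weight matrix; diagonal
    entries hold intra-node weight counted as in ``M A M^T``. Returns
    whether any move improved modularity.
    """
    n = len(W)
    two_m = W.sum()
    s = W.sum(axis=1)
    comm_S = np.zeros(n)
    np.add.at(comm_S, labels, s)
    improved_any = False
    moved = True
    while moved:
        moved = False
        for v in rng.permutation(n):
            a = labels[v]
            link = np.zeros(n)
            np.add.at(link, labels, W[v])
            link[a] -= W[v, v]  # the (v, v) pair moves with v; exclude it
            S_excl = comm_S.copy()
            S_excl[a] -= s[v]
            gains = (link - link[a]) - resolution * s[v] * (S_excl - S_excl[a]) / two_m
            gains[a] = 0.0
            b = int(np.argmax(gains))
            if gains[b] > 1e-12:
                labels[v] = b
                comm_S[a] -= s[v]
                comm_S[b] += s[v]
                moved = True
                improved_any = True
    return improved_any


def _louvain_dense(
    A: np.ndarray, resolution: float, rng, init_labels: np.ndarray | None = None
) -> np.ndarray:
    """Full Louvain (local moves + aggregation) on a dense weight matrix,
    optionally from a random initial partition instead of singletons."""
    n0 = len(A)
    node_to_agg = np.arange(n0)
    W = A.copy()
    labels = np.arange(len(W)) if init_labels is None else init_labels.copy()
    while True:
        _local_moves(W, labels, resolution, rng)
        uniq, compact = np.unique(labels, return_inverse=True)
        node_to_agg = compact[node_to_agg]
        if len(uniq) == len(W):  # every community a singleton: converged
            break
        M = np.zeros((len(uniq), len(W)))
        M[compact, np.arange(len(W))] = 1.0
        W = M @ W @ M.T
        if len(W) == 1:
            break
        labels = np.arange(len(W))
    return node_to_agg


@njit(cache=False)
def _sparse_level(
    indptr, indices, weights, labels, order, resolution, two_m, s, comm_S, link, touched, max_sweeps
):  # pragma: no cover - jitted
    n = len(indptr) - 1
    sweeps = 0
    moved = True
    while moved and sweeps < max_sweeps:
        moved = False
        sweeps += 1
        for idx in range(n):
            v = order[idx]
            a = labels[v]
            ncomm = 0
            for e in range(indptr[v], indptr[v + 1]):
                u = indices[e]
                if u == v:
                    continue
                c = labels[u]
                if link[c] == 0.0:
                    touched[ncomm] = c
                    ncomm += 1
                link[c] += weights[e]
            Sa = comm_S[a] - s[v]
            la = link[a]
            best_gain = 1e-12
            best_c = a
            for t in range(ncomm):
                c = touched[t]
                if c == a:
                    continue
                gain = (link[c] - la) - resolution * s[v] * (comm_S[c] - Sa) / two_m
                if gain > best_gain:
                    best_gain = gain
                    best_c = c
            if best_c != a:
                labels[v] = best_c
                comm_S[a] -= s[v]
                comm_S[best_c] += s[v]
                moved = True
            for t in range(ncomm):
                link[touched[t]] = 0.0


def _louvain_sparse(
    n: int, edges: np.ndarray, edge_weights: np.ndarray, seed_rng, resolution: float, max_sweeps: int = 12
) -> np.ndarray:
    """Singleton-start Louvain on a CSR 'doubled' edge representation."""
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.concatenate([edge_weights, edge_weights]).astype(np.float64)
    order0 = np.argsort(src, kind="stable")
    indices = np.ascontiguousarray(dst[order0])
    weights = np.ascontiguousarray(w[order0])
    indptr = np.cumsum(np.bincount(src + 1, minlength=n + 1)).astype(np.int64)

    labels_global = np.arange(n)
    n_cur = n
    while True:
        two_m = weights.sum()
        deg_src = np.repeat(np.arange(n_cur), np.diff(indptr))
        s = np.bincount(deg_src, weights=weights, minlength=n_cur)
        labels = np.arange(n_cur)
        _sparse_level(
            indptr, indices, weights, labels, seed_rng.permutation(n_cur), resolution,
            two_m, s, s.copy(), np.zeros(n_cur), np.empty(n_cur, np.int64), max_sweeps,
        )
        uniq, compact = np.unique(labels, return_inverse=True)
        labels_global = compact[labels_global]
        if len(uniq) == n_cur:
            break
        n_comm = len(uniq)
        cu = compact[deg_src]
        cv = compact[indices]
        code = cu.astype(np.int64) * n_comm + cv
        o = np.argsort(code, kind="stable")
        code_s = code[o]
        w_s = weights[o]
        boundary = np.empty(len(code_s), dtype=bool)
        boundary[0] = True
        np.not_equal(code_s[1:], code_s[:-1], out=boundary[1:])
        starts = np.flatnonzero(boundary)
        weights = np.add.reduceat(w_s, starts)
        agg_code = code_s[starts]
        cu2 = (agg_code // n_comm).astype(np.int64)
        indices = (agg_code % n_comm).astype(np.int64)
        indptr = np.cumsum(np.bincount(cu2 + 1, minlength=n_comm + 1)).astype(np.int64)
        n_cur = n_comm
    return labels_global


def _sparse_modularity(
    n: int, edges: np.ndarray, weights: np.ndarray, labels: np.ndarray, resolution: float
) -> float:
    two_m = 2.0 * weights.sum()
    if two_m == 0:
        return 0.0
    intra = 2.0 * weights[labels[edges[:, 0]] == labels[edges[:, 1]]].sum()
    s = np.bincount(edges[:, 0], weights=weights, minlength=n) + np.bincount(
        edges[:, 1], weights=weights, minlength=n
    )
    S_c = np.bincount(labels, weights=s)
    return float(intra / two_m - resolution * ((S_c / two_m) ** 2).sum())


_DENSE_LIMIT = 512


def louvain_cluster(
    g: WeightedGraph,
    seed: int,
    resolution: float = 1.0,
    n_restarts: int | None = None,
) -> ClusterAssignment:
    """Louvain community detection, deterministic given the seed.

    One singleton-start multilevel pass always runs; on small graphs
    (<= 512 nodes) additional seeded restarts from random initial
    partitions run through a dense implementation, and the
    highest-modularity partition wins. ``n_restarts=None`` picks a
    size-dependent schedule (more restarts the smaller the graph;
    event-scale graphs use the single sparse pass). An edgeless graph
    yields singletons.
    """
    n = g.n_nodes
    if n == 0:
        raise ConfigError("empty graph")
    if g.n_edges == 0:
        return ClusterAssignment(np.arange(n, dtype=np.int64), modularity=0.0)
    if n_restarts is None:
        n_restarts = 60 if n <= 64 else (8 if n <= _DENSE_LIMIT else 1)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x10AD]))
    weights = g.weights.astype(float)

    best_labels = _louvain_sparse(n, g.edges, weights, rng, resolution)
    best_q = _sparse_modularity(n, g.edges, weights, best_labels, resolution)

    if n <= _DENSE_LIMIT and n_restarts > 1:
        W = np.zeros((n, n))
        for (i, j), w in zip(g.edges, weights):
            W[i, j] = W[j, i] = w
        for _ in range(n_restarts - 1):
            k_init = int(rng.integers(1, n + 1))
            init = rng.integers(0, k_init, n)
            labels = _louvain_dense(W, resolution, rng, init_labels=init)
            q = _dense_modularity(W, labels, resolution)
            if q > best_q + 1e-12:
                best_q = q
                best_labels = labels
    return ClusterAssignment(_relabel_by_size(best_labels), modularity=float(best_q))


def tsne_embed(matrix: np.ndarray, seed: int, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE projection for display (delegated to scikit-learn)."""
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if perplexity >= (n - 1) / 3:
        raise ConfigError(f"perplexity {perplexity} too large for n={n} (need < (n-1)/3)")
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=int(seed) & 0x7FFFFFFF, init="pca")
    return tsne.fit_transform(X)


def cluster_median_profile(
    table: EventTable, assignment: ClusterAssignment, linkage_method: str = "average"
) -> MedianProfile:
    """Per-cluster median marker intensities with hierarchical ordering.

    Rows (clusters) and columns (markers) are ordered by agglomerative
    clustering (Euclidean distance, the given linkage) of the median
    profiles, mirroring the usual annotated-heatmap layout.
    """
    if len(assignment.labels) != table.n_cells:
        raise ConfigError("assignment does not cover the event table")
    df = table.data[list(table.markers)].copy()
    df["_cluster"] = assignment.labels
    prof = df.groupby("_cluster").median()
    prof.index.name = "cluster"

    def _order(mat: np.ndarray) -> list:
        if mat.shape[0] < 2:
            return list(range(mat.shape[0]))
        return list(leaves_list(linkage(mat, method=linkage_method, metric="euclidean")))

    return MedianProfile(prof, _order(prof.to_numpy()), _order(prof.to_numpy().T))
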