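"""Shared undirected weighted graph container.

The same structure backs two very different graphs in the pipeline: the
cell-level kNN/Jaccard graph (hundreds of thousands of nodes, built from
arrays) and the protein-protein interaction network (hundreds of nodes,
manipulated through networkx). Edges are stored once in canonical
``(i, j), i < j`` order with strictly positive weights and no self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

__all__ = ["WeightedGraph"]


@dataclass
class WeightedGraph:
    node_names: tuple
    edges: np.ndarray  # (m, 2) int array, canonical i < j
    weights: np.ndarray  # (m,) float array, all > 0

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        n, m = len(self.node_names), len(self.edges)
        if len(self.weights) != m:
            raise ConfigError("edge and weight arrays differ in length")
        if m:
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ConfigError("edge endpoint out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ConfigError("self-loops are not allowed")
            if np.any(self.edges[:, 0] > self.edges[:, 1]):
                raise ConfigError("edges must be canonical (i < j)")
            code = np.sort(self.edges[:, 0] * n + self.edges[:, 1])
            if m > 1 and np.any(code[1:] == code[:-1]):
                raise ConfigError("duplicate edges")
            if np.any(self.weights <= 0):
                raise ConfigError("edge weights must be > 0")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_pairs(
        cls,
        node_names: Sequence,
        pairs: Iterable[tuple],
        weights: Iterable[float] | None = None,
    ) -> "WeightedGraph":
        """Build from ``(u, v)`` name pairs; parallel/reversed duplicates merge."""
        index = {name: i for i, name in enumerate(node_names)}
        if len(index) != len(node_names):
            raise ConfigError("node names must be unique")
        pairs = list(pairs)
        w = list(weights) if weights is not None else [1.0] * len(pairs)
        seen: dict[tuple[int, int], float] = {}
        for (u, v), wt in zip(pairs, w):
            if u not in index or v not in index:
                raise ConfigError(f"edge endpoint {u!r}/{v!r} not in node set")
            i, j = index[u], index[v]
            if i == j:
                continue  # drop self-loops silently on construction from lists
            key = (min(i, j), max(i, j))
            seen[key] = wt  # last write wins for duplicates
        if seen:
            edges = np.array(sorted(seen), dtype=np.int64)
            wts = np.array([seen[tuple(e)] for e in edges], dtype=float)
        else:
            edges = np.empty((0, 2), dtype=np.int64)
            wts = np.empty(0, dtype=float)
        return cls(tuple(node_names), edges, wts)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "WeightedGraph":
        names = tuple(sorted(g.nodes(), key=str))
        pairs, wts = [], []
        for u, v, data in g.edges(data=True):
            pairs.append((u, v))
            wts.append(float(data.get("weight", 1.0)))
        return cls.from_pairs(names, pairs, wts)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        names = self.node_names
        for (i, j), w in zip(self.edges, self.weights):
            g.add_edge(names[i], names[j], weight=float(w))
        return g

    def subgraph(self, keep: Iterable) -> "WeightedGraph":
        """Induced subgraph on the named nodes (order preserved from ``keep``)."""
        keep = list(dict.fromkeys(keep))
        index = {name: i for i, name in enumerate(self.node_names)}
        missing = [k for k in keep if k not in index]
        if missing:
            raise ConfigError(f"nodes not in graph: {missing[:5]}")
        old_ids = np.array([index[k] for k in keep], dtype=np.int64)
        remap = -np.ones(self.n_nodes, dtype=np.int64)
        remap[old_ids] = np.arange(len(keep))
        if self.n_edges == 0:
            return WeightedGraph(tuple(keep), np.empty((0, 2), np.int64), np.empty(0))
        a = remap[self.edges[:, 0]]
        b = remap[self.edges[:, 1]]
        mask = (a >= 0) & (b >= 0)
        lo = np.minimum(a[mask], b[mask])
        hi = np.maximum(a[mask], b[mask])
        edges = np.column_stack([lo, hi])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        return WeightedGraph(tuple(keep), edges[order], self.weights[mask][order])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read_edge_list(cls, path: str | Path) -> "WeightedGraph":
        """Read a two-column (plus optional weight) tab-separated edge list."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        if df.shape[1] < 2:
            raise SchemaError("edge list needs at least two columns")
        u, v = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
        w = df.iloc[:, 2].astype(float) if df.shape[1] > 2 else None
        names = sorted(set(u) | set(v))
        return cls.from_pairs(names, list(zip(u, v)), w)

    def write_edge_list(self, path: str | Path) -> None:
        names = self.node_names
        df = pd.DataFrame(
            {
                "node_a": [names[i] for i in self.edges[:, 0]],
                "node_b": [names[j] for j in self.edges[:, 1]],
                "weight": self.weights,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
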