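"""Spanning-tree backbone of the connectivity graph and its topology metrics.

The "minimum spanning tree of the PLI matrix", as the term is used in the
EEG network literature, retains the N-1 *strongest* connections that keep
the graph connected: it is the maximum-weight spanning tree over PLI
weights (equivalently, the minimum spanning tree over 1 - PLI). Minimizing
raw PLI would keep the weakest links and invert the meaning of every
hub/leaf metric, so the maximum-weight convention is used here and stated
prominently.

With N nodes, M = N - 1 edges, L leaves (degree-1 nodes), diameter d (the
longest path, counted in edges) and BC_max the largest betweenness
centrality on the tree (normalized to [0, 1]), the four reported metrics
are::

    degree_max_norm = max_degree / M      (hubness)
    leaf_fraction   = L / M               (star-likeness)
    diameter_norm   = d / M               (efficiency of the backbone)
    tree_hierarchy  = L / (2 * M * BC_max)  (hub reliance vs. efficiency)

All four are dimensionless and lie in (0, 1] for nondegenerate trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from qeeg.connectivity import ConnectivityMatrix


@dataclass
class TreeTopology:
    """A spanning tree with its four normalized topology metrics."""

    nodes: list[str]
    edges: list[tuple[int, int, float]]   # (i, j, weight), i < j
    metrics: dict[str, float]
    degenerate: bool = False              # all-zero input matrix

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degree_sequence(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(self.edges)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.nodes[i], self.nodes[j], w) for i, j, w in self.edges],
            columns=["source", "target", "weight"],
        )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def spanning_tree(matrix: ConnectivityMatrix | np.ndarray,
                  labels: list[str] | None = None) -> TreeTopology:
    """Maximum-weight spanning tree of a symmetric non-negative matrix.

    Kruskal over edges sorted by descending weight; ties break by
    lexicographic (i, j) node-index order, so results are identical across
    platforms. An all-zero matrix still yields a tree (pure tie-break
    order) and is flagged ``degenerate``.
    """
    if isinstance(matrix, ConnectivityMatrix):
        w = matrix.values
        labels = list(matrix.channel_labels)
    else:
        w = np.asarray(matrix, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("matrix must be square")
        if np.abs(w - w.T).max() > 1e-9:
            raise ValueError("matrix must be symmetric")
        if w.min() < 0:
            raise ValueError("weights must be non-negative")
        if labels is None:
            labels = [str(i) for i in range(w.shape[0])]
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs.sort(key=lambda ij: (-w[ij[0], ij[1]], ij[0], ij[1]))
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for i, j in pairs:
        if uf.union(i, j):
            edges.append((i, j, float(w[i, j])))
            if len(edges) == n - 1:
                break

    tree = TreeTopology(nodes=labels, edges=edges, metrics={},
                        degenerate=bool(np.all(w == 0)))
    tree.metrics = tree_metrics(tree)
    return tree


def tree_metrics(tree: TreeTopology) -> dict[str, float]:
    """The four normalized topology metrics of a spanning tree."""
    n = tree.n_nodes
    m = n - 1
    if len(tree.edges) != m:
        raise ValueError(f"not a spanning tree: {len(tree.edges)} edges for {n} nodes")
    g = tree.to_graph()
    if not nx.is_connected(g) or len(g.edges) != m:
        raise ValueError("input is not a connected acyclic spanning tree")

    deg = tree.degree_sequence()
    leaves = int(np.sum(deg == 1))
    diameter = nx.diameter(g)  # in edges
    bc = nx.betweenness_centrality(g, normalized=True)
    bc_max = max(bc.values())

    hierarchy = leaves / (2.0 * m * bc_max) if bc_max > 0 else 1.0  # N=2: no interior node
    return {
        "degree_max_norm": float(deg.max() / m),
        # capped at 1 for the two-node tree, where both nodes are leaves
        "leaf_fraction": float(min(1.0, leaves / m)),
        "diameter_norm": float(diameter / m),
        "tree_hierarchy": float(hierarchy),
    }
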