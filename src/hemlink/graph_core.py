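"""Undirected simple graphs: construction, edge-list I/O, and summary statistics.

The :class:`Graph` here is deliberately minimal: contiguous integer nodes, a
neighbor-set adjacency, and an optional table mapping internal ids back to the
labels found in an input file. All similarity indices and evaluation code work
on this one container; matrix-based indices obtain a ``scipy.sparse`` adjacency
from :meth:`Graph.adjacency_matrix`.

Preprocessing follows the usual conventions for raw interaction-network edge
lists: parallel edges collapse to one, direction is discarded, self-loops are
dropped, and analyses that need connectivity run on the giant component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .errors import (
    DisconnectedGraphError,
    EdgeListParseError,
    EmptyGraphError,
    GraphError,
)

__all__ = [
    "Graph",
    "NetworkFeatures",
    "read_edge_list",
    "write_edge_list",
    "giant_component",
    "network_features",
]


class Graph:
    """An undirected simple graph on nodes ``0..n-1``.

    Parameters
    ----------
    n_nodes:
        Number of nodes. Nodes are always the contiguous range ``0..n_nodes-1``.
    edges:
        Iterable of ``(x, y)`` pairs. Self-loops and duplicates are rejected:
        use :meth:`from_labeled_edges` to *simplify* raw input instead.
    labels:
        Optional sequence of original labels, one per node. File output uses
        these; internal computation never does.
    """

    __slots__ = ("_adj", "_labels", "_m")

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[tuple[int, int]],
        labels: Sequence[object] | None = None,
    ) -> None:
        if n_nodes < 0:
            raise GraphError("n_nodes must be non-negative")
        if labels is not None and len(labels) != n_nodes:
            raise GraphError(
                f"label table has {len(labels)} entries for {n_nodes} nodes"
            )
        adj: list[set[int]] = [set() for _ in range(n_nodes)]
        m = 0
        for x, y in edges:
            x, y = int(x), int(y)
            if not (0 <= x < n_nodes and 0 <= y < n_nodes):
                raise GraphError(f"edge ({x}, {y}) outside node range 0..{n_nodes - 1}")
            if x == y:
                raise GraphError(f"self-loop at node {x}")
            if y in adj[x]:
                raise GraphError(f"duplicate edge ({x}, {y})")
            adj[x].add(y)
            adj[y].add(x)
            m += 1
        self._adj = adj
        self._m = m
        self._labels = list(labels) if labels is not None else None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_labeled_edges(cls, pairs: Iterable[tuple[object, object]]) -> "Graph":
        """Build a simplified graph from raw labeled pairs.

        Node ids are assigned in first-appearance order. Duplicate edges (in
        either orientation) collapse to one, and self-loops are dropped after
        registering their label, so an isolated self-looping node still exists.
        """
        index: dict[object, int] = {}
        edges: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        for a, b in pairs:
            for lab in (a, b):
                if lab not in index:
                    index[lab] = len(index)
            x, y = index[a], index[b]
            if x == y:
                continue
            key = (x, y) if x < y else (y, x)
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)
        labels = list(index)
        return cls(len(labels), edges, labels=labels)

    # -- basic accessors --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return self._m

    @property
    def labels(self) -> list[object] | None:
        """Original node labels (``None`` if the graph was generated)."""
        return self._labels

    def label(self, x: int) -> object:
        return self._labels[x] if self._labels is not None else x

    def neighbors(self, x: int) -> set[int]:
        """The neighbor set Γ(x). Treat as read-only."""
        return self._adj[x]

    def degree(self, x: int) -> int:
        return len(self._adj[x])

    def degrees(self) -> np.ndarray:
        return np.array([len(s) for s in self._adj], dtype=np.int64)

    def has_edge(self, x: int, y: int) -> bool:
        return y in self._adj[x]

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield each edge once as ``(x, y)`` with ``x < y``, sorted."""
        for x in range(self.n_nodes):
            for y in sorted(self._adj[x]):
                if x < y:
                    yield (x, y)

    def edge_array(self) -> np.ndarray:
        """All edges as an ``(m, 2)`` int array with ``x < y``, sorted."""
        if self._m == 0:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(list(self.edges()), dtype=np.int64)

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.edges())

    def adjacency_matrix(self, dtype=np.float64) -> sp.csr_matrix:
        """Sparse symmetric adjacency matrix A."""
        e = self.edge_array()
        n = self.n_nodes
        if len(e) == 0:
            return sp.csr_matrix((n, n), dtype=dtype)
        row = np.concatenate([e[:, 0], e[:, 1]])
        col = np.concatenate([e[:, 1], e[:, 0]])
        data = np.ones(len(row), dtype=dtype)
        return sp.csr_matrix((data, (row, col)), shape=(n, n))

    # -- derived graphs ---------------------------------------------------

    def remove_edges(self, edges: Iterable[tuple[int, int]]) -> "Graph":
        """A copy with the given edges removed (node set unchanged)."""
        drop = {(x, y) if x < y else (y, x) for x, y in edges}
        kept = [e for e in self.edges() if e not in drop]
        return Graph(self.n_nodes, kept, labels=self._labels)

    def subgraph(self, nodes: Sequence[int]) -> "Graph":
        """Induced subgraph; node ids re-compacted in the given order."""
        nodes = list(nodes)
        remap = {old: new for new, old in enumerate(nodes)}
        keep = set(nodes)
        edges = [
            (remap[x], remap[y])
            for x, y in self.edges()
            if x in keep and y in keep
        ]
        labels = (
            [self._labels[x] for x in nodes] if self._labels is not None else None
        )
        return Graph(len(nodes), edges, labels=labels)

    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        n_comp, _ = csgraph.connected_components(self.adjacency_matrix(), directed=False)
        return n_comp == 1

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# -- I/O -------------------------------------------------------------------


def read_edge_list(path) -> Graph:
    """Read a plain-text edge list into a simplified undirected Graph.

    Format: two whitespace-separated node labels per line; extra tokens (for
    instance edge weights) are ignored; ``#`` starts a comment line. Directed
    input is read as undirected, parallel edges collapse to one, and
    self-loops are dropped.

    Raises
    ------
    EdgeListParseError
        If a non-comment line has fewer than two tokens.
    EmptyGraphError
        If the file contains no edges at all.
    """
    raw: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            tokens = text.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected two node labels, got {len(tokens)}"
                )
            raw.append((tokens[0], tokens[1]))
    if not raw:
        raise EmptyGraphError(f"{path}: no edges found")
    return Graph.from_labeled_edges(raw)


def write_edge_list(graph: Graph, path) -> None:
    """Write one line per edge (original labels, each unordered pair once).

    Edges are emitted in sorted internal order, so output is deterministic and
    a write/read round trip preserves the edge set exactly.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# hemlink edge list\n")
        fh.write(f"# nodes: {graph.n_nodes} edges: {graph.n_edges}\n")
        for x, y in graph.edges():
            fh.write(f"{graph.label(x)} {graph.label(y)}\n")


# -- giant component -------------------------------------------------------


def giant_component(graph: Graph) -> Graph:
    """Induced subgraph on the largest connected component.

    Ties between equal-sized components go to the one containing the smallest
    node index. Node ids are re-compacted (preserving relative order) and the
    label table is carried through.
    """
    if graph.n_nodes == 0:
        raise GraphError("empty graph has no components")
    n_comp, comp = csgraph.connected_components(
        graph.adjacency_matrix(), directed=False
    )
    if n_comp == 1:
        return graph
    sizes = np.bincount(comp, minlength=n_comp)
    # scipy labels components in order of first node encountered, so argmax's
    # first-winner rule is exactly the smallest-minimum-node tie-break.
    best = int(np.argmax(sizes))
    nodes = np.flatnonzero(comp == best)
    return graph.subgraph(nodes.tolist())


# -- network features ------------------------------------------------------


@dataclass(frozen=True)
class NetworkFeatures:
    """Whole-network summary statistics.

    Attributes
    ----------
    n_nodes, n_edges:
        N and M.
    mean_degree:
        K = 2M/N.
    max_degree:
        Δ, the largest node degree.
    diameter:
        D, the longest shortest path (hop count) in the connected graph.
    clustering:
        C, the mean local clustering coefficient (Watts–Strogatz definition);
        nodes of degree < 2 contribute 0.
    assortativity:
        ρ, the Pearson correlation of endpoint degrees over all edges counted
        once in each orientation; ``nan`` when the endpoint-degree variance is
        zero (e.g. regular graphs).
    transitivity:
        Global transitivity (3 × triangles / connected triples), exposed as a
        secondary clustering measure.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    max_degree: int
    diameter: int
    clustering: float
    assortativity: float
    transitivity: float

    def as_dict(self) -> dict:
        """Short-key dict (N, M, K, Delta, D, C, rho) for reports."""
        rho = self.assortativity
        return {
            "N": self.n_nodes,
            "M": self.n_edges,
            "K": self.mean_degree,
            "Delta": self.max_degree,
            "D": self.diameter,
            "C": self.clustering,
            "rho": None if math.isnan(rho) else rho,
            "transitivity": self.transitivity,
        }


def network_features(graph: Graph) -> NetworkFeatures:
    """Compute :class:`NetworkFeatures` for a connected graph with N >= 2.

    The diameter comes from breadth-first search out of every node, an
    O(N·M) pass; call :func:`giant_component` first on disconnected input.
    """
    n = graph.n_nodes
    if n < 2:
        raise GraphError("network features need at least 2 nodes")
    adjacency = graph.adjacency_matrix()
    n_comp, _ = csgraph.connected_components(adjacency, directed=False)
    if n_comp != 1:
        raise DisconnectedGraphError(
            "graph is disconnected; extract the giant_component first"
        )
    deg = graph.degrees()
    m = graph.n_edges

    dist = csgraph.shortest_path(adjacency, method="D", unweighted=True)
    diameter = int(dist.max())

    # (A @ A) .* A row sums count ordered adjacent neighbor pairs: 2 triangles
    # through each node.
    tri2 = np.asarray((adjacency @ adjacency).multiply(adjacency).sum(axis=1)).ravel()
    pairs = deg.astype(np.float64) * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        local = np.where(pairs > 0, tri2 / pairs, 0.0)
    clustering = float(local.mean())
    transitivity = float(tri2.sum() / pairs.sum()) if pairs.sum() > 0 else 0.0

    e = graph.edge_array()
    du = deg[e[:, 0]].astype(np.float64)
    dv = deg[e[:, 1]].astype(np.float64)
    x = np.concatenate([du, dv])
    y = np.concatenate([dv, du])
    if np.ptp(x) == 0:
        rho = math.nan
    else:
        rho = float(np.corrcoef(x, y)[0, 1])

    return NetworkFeatures(
        n_nodes=n,
        n_edges=m,
        mean_degree=2.0 * m / n,
        max_degree=int(deg.max()),
        diameter=diameter,
        clustering=clustering,
        assortativity=rho,
        transitivity=transitivity,
    )
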