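"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hemlink import Graph

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


# -- small explicit graphs -------------------------------------------------


@pytest.fixture
def triangle() -> Graph:
    return Graph(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def path3() -> Graph:
    """a - b - c."""
    return Graph(3, [(0, 1), (1, 2)])


@pytest.fixture
def path4() -> Graph:
    """a - b - c - d."""
    return Graph(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star5() -> Graph:
    """Hub 0 with four leaves."""
    return Graph(5, [(0, i) for i in range(1, 5)])


@pytest.fixture
def branch_graph() -> Graph:
    """x - z, z - y, z - w (x=0, z=1, y=2, w=3): a star whose walks revisit z."""
    return Graph(4, [(0, 1), (1, 2), (1, 3)])


@pytest.fixture
def ch_example() -> Graph:
    """x=0, y=1, z1=2, z2=3, w=4 with edges x-z1, x-z2, y-z1, y-z2, z1-z2, z1-w."""
    return Graph(5, [(0, 2), (0, 3), (1, 2), (1, 3), (2, 3), (2, 4)])


def random_simple_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Erdős–Rényi G(n, p) graph as a hemlink Graph (test helper)."""
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    return Graph(n, edges)


@pytest.fixture
def make_random_graph():
    return random_simple_graph


# -- independent oracles ---------------------------------------------------


def count_walks(graph: Graph, x: int, y: int, length: int) -> int:
    """Recursive walk enumeration: walks of exactly `length` steps x -> y.

    Memoized on (node, steps-remaining); exact Python integers throughout.
    Independent of the package's matrix-power implementation.
    """
    memo: dict[tuple[int, int], int] = {}

    def rec(node: int, remaining: int) -> int:
        if remaining == 0:
            return 1 if node == y else 0
        key = (node, remaining)
        if key not in memo:
            memo[key] = sum(rec(nbr, remaining - 1) for nbr in graph.neighbors(node))
        return memo[key]

    return rec(x, remaining=length)


def to_networkx(graph: Graph):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    g.add_edges_from(graph.edges())
    return g


@pytest.fixture
def nx_of():
    return to_networkx
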