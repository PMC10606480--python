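"""Seeded generators for the three evolution models the indices are built on.

* :func:`random_regular` — every node has exactly ``d`` neighbors (configuration
  model pairing with rejection of illegal stub pairs and bounded restarts).
* :func:`ba` — scale-free growth with preferential attachment: each arriving
  node draws ``m`` distinct targets with probability proportional to current
  degree, P(i) = k_i / Σ_j k_j.
* :func:`ws` / :func:`nw` — small-world ring lattices: each node starts tied to
  its K/2 nearest neighbors on each side; WS rewires each lattice edge with
  probability p, NW keeps the lattice and *adds* a random edge with
  probability p instead.

All generators are deterministic given their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, ParameterError
from .graph_core import Graph

__all__ = ["GeneratorSpec", "generate", "random_regular", "ba", "ws", "nw"]


def _check_probability(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability p={p} outside [0, 1]")


def _check_ring(n: int, K: int, p: float) -> None:
    if K % 2 != 0:
        raise ParameterError(f"ring degree K={K} must be even")
    if not 0 < K < n:
        raise ParameterError(f"need 0 < K < n (got K={K}, n={n})")
    _check_probability(p)


def random_regular(n: int, d: int, seed: int = 0, max_restarts: int = 200) -> Graph:
    """A random simple ``d``-regular graph on ``n`` nodes.

    Sampling pairs degree stubs uniformly at random, skipping pairs that
    would create a self-loop or duplicate edge; if the pairing deadlocks
    (only illegal pairs remain) the whole attempt restarts. For d << n a
    restart is rare and the loop is effectively linear in n·d.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    if d < 0 or d >= n:
        raise ParameterError(f"need 0 <= d < n (got d={d}, n={n})")
    if (n * d) % 2 != 0:
        raise ParameterError(f"n*d must be even (got n={n}, d={d})")
    if d == 0:
        return Graph(n, [])
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        edges = _pair_stubs(n, d, rng)
        if edges is not None:
            return Graph(n, edges)
    raise GenerationError(
        f"random_regular(n={n}, d={d}) failed after {max_restarts} restarts"
    )


def _pair_stubs(n: int, d: int, rng: np.random.Generator) -> list[tuple[int, int]] | None:
    stubs = np.repeat(np.arange(n), d)
    rng.shuffle(stubs)
    stubs = stubs.tolist()
    adj: list[set[int]] = [set() for _ in range(n)]
    edges: list[tuple[int, int]] = []
    failures = 0
    while len(stubs) >= 2:
        i = int(rng.integers(len(stubs)))
        stubs[i], stubs[-1] = stubs[-1], stubs[i]
        u = stubs.pop()
        j = int(rng.integers(len(stubs)))
        stubs[j], stubs[-1] = stubs[-1], stubs[j]
        v = stubs.pop()
        if u != v and v not in adj[u]:
            adj[u].add(v)
            adj[v].add(u)
            edges.append((u, v))
            failures = 0
        else:
            stubs.append(u)
            stubs.append(v)
            failures += 1
            # Deadlock detection: with s stubs left there are at most s^2
            # pairings to miss; a long failure streak means none is legal.
            if failures > max(100, len(stubs) ** 2):
                return None
    return edges


def ba(n: int, m: int, seed: int = 0) -> Graph:
    """A Barabási–Albert scale-free graph: growth plus preferential attachment.

    Starts from a complete seed graph on ``m + 1`` nodes so that every
    arriving node can immediately draw ``m`` distinct targets. Targets are
    drawn without replacement (repeat draws are rejected) with probability
    proportional to current degree. Final edge count is exactly
    ``(m+1)m/2 + (n-m-1)m``.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    if m > n - 1:
        raise ParameterError(f"need m <= n-1 (got m={m}, n={n})")
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i in range(m + 1) for j in range(i + 1, m + 1)]
    # One entry per degree unit; sampling an entry uniformly is sampling a
    # node with probability k_i / sum_j k_j.
    pool: list[int] = [i for i in range(m + 1) for _ in range(m)]
    for v in range(m + 1, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(pool[int(rng.integers(len(pool)))])
        for t in sorted(targets):
            edges.append((t, v))
            pool.append(t)
            pool.append(v)
    return Graph(n, edges)


def _ring_lattice_edges(n: int, K: int) -> list[tuple[int, int]]:
    # Visit order: all offset-1 edges around the ring, then offset-2, ...
    return [
        (i, (i + off) % n)
        for off in range(1, K // 2 + 1)
        for i in range(n)
    ]


def ws(n: int, K: int, p: float, seed: int = 0) -> Graph:
    """A Watts–Strogatz small-world graph.

    Each lattice edge is visited once in ring order; with probability ``p``
    its far endpoint is replaced by a uniform random node. Replacements that
    would create a self-loop or duplicate are redrawn (up to ``n`` attempts,
    after which the edge is left in place), so the edge count stays nK/2.
    p=0 is exactly the ring lattice; p=1 is fully randomized.
    """
    _check_ring(n, K, p)
    rng = np.random.default_rng(seed)
    adj: list[set[int]] = [set() for _ in range(n)]
    lattice = _ring_lattice_edges(n, K)
    for u, v in lattice:
        adj[u].add(v)
        adj[v].add(u)
    for u, v in lattice:
        if rng.random() >= p:
            continue
        for _ in range(n):
            w = int(rng.integers(n))
            if w != u and w not in adj[u]:
                adj[u].discard(v)
                adj[v].discard(u)
                adj[u].add(w)
                adj[w].add(u)
                break
    edges = [(u, v) for u in range(n) for v in adj[u] if u < v]
    return Graph(n, edges)


def nw(n: int, K: int, p: float, seed: int = 0) -> Graph:
    """A Newman–Watts small-world graph: ring lattice plus random shortcuts.

    No lattice edge is ever removed; for each lattice edge (visited once) an
    extra uniform random edge is added with probability ``p``. Candidate
    additions that are self-loops or duplicates are redrawn up to ``n`` times
    and then skipped, so nK/2 <= |E| <= nK.
    """
    _check_ring(n, K, p)
    rng = np.random.default_rng(seed)
    adj: list[set[int]] = [set() for _ in range(n)]
    lattice = _ring_lattice_edges(n, K)
    for u, v in lattice:
        adj[u].add(v)
        adj[v].add(u)
    for _ in lattice:
        if rng.random() >= p:
            continue
        for _ in range(n):
            u = int(rng.integers(n))
            v = int(rng.integers(n))
            if u != v and v not in adj[u]:
                adj[u].add(v)
                adj[v].add(u)
                break
    edges = [(u, v) for u in range(n) for v in adj[u] if u < v]
    return Graph(n, edges)


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one generated network.

    ``model`` is one of ``regular``, ``ba``, ``ws``, ``nw``; the remaining
    fields mirror the corresponding generator's parameters and only the ones
    that model uses need to be set.
    """

    model: str
    n: int
    d: int | None = None
    m: int | None = None
    K: int | None = None
    p: float | None = None
    seed: int = 0


def generate(spec: GeneratorSpec) -> Graph:
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    model = spec.model.lower()
    if model == "regular":
        if spec.d is None:
            raise ParameterError("regular model needs d")
        return random_regular(spec.n, spec.d, seed=spec.seed)
    if model == "ba":
        if spec.m is None:
            raise ParameterError("ba model needs m")
        return ba(spec.n, spec.m, seed=spec.seed)
    if model in ("ws", "nw"):
        if spec.K is None or spec.p is None:
            raise ParameterError(f"{model} model needs K and p")
        fn = ws if model == "ws" else nw
        return fn(spec.n, spec.K, spec.p, seed=spec.seed)
    raise ParameterError(f"unknown model {spec.model!r}")
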