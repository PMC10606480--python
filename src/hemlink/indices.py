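"""Similarity indices for link prediction.

Every index maps a *training* graph and a node pair (x, y) to a real score;
higher scores mean "more likely to be (or become) an edge". Three families are
implemented:

* neighbor/degree-based: CN, Salton, RA, CH, PA, plus the degree-balance index
  Reg = 1/(k_x k_y) and the degree-difference index DFPA = max(k)/min(k);
* walk-count based: LW(k) = (A^k + A^{k+1})_xy, LPK(k) = (A^2 + ... + A^{k+1})_xy,
  and the weighted local path LP(ε, n) = (A^2 + εA^3 + ... + ε^{n-2}A^n)_xy.
  A^k entries count *walks* (edges may be revisited), which is intentional:
  round trips on branches carry neighborhood information;
* global solves: Katz ((I − βA)^{-1} − I) and the linear-optimization index
  LO = αA(αA^T A + I)^{-1} A^T A.

Internally each index is computed as a dense n×n score matrix on the training
graph; :class:`WalkCache` memoizes adjacency powers so a bank of indices
evaluated on the same fold shares them. Pair-level wrappers extract entries
into :class:`PairScores`.

Degree clamp: cross-validation can isolate nodes, and Reg/DFPA divide by
degree. Both use k̂ = max(k, 1) so every probe pair stays scoreable; on the
regimes studied (n in the thousands) isolation is vanishingly rare and the
clamp is inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg

from .errors import ConfigurationError, ConvergenceError, ParameterError, WalkOverflowError
from .graph_core import Graph

__all__ = [
    "IndexConfig",
    "PairScores",
    "WalkCache",
    "score_matrix",
    "scores_for_pairs",
    "local_score",
    "reg_score",
    "dfpa_score",
    "walk_counts",
    "lw_score",
    "lpk_score",
    "lp_score",
    "katz_score",
    "lo_score",
    "hem_score",
    "spectral_radius",
    "DEFAULT_KATZ_BETA",
    "DEFAULT_LO_ALPHA",
    "INDEX_NAMES",
]

DEFAULT_KATZ_BETA = 0.01
DEFAULT_LO_ALPHA = 0.01

#: Exact-integer ceiling for float64 walk counts.
_WALK_LIMIT = float(2**53)

INDEX_NAMES = (
    "cn",
    "salton",
    "ra",
    "ch",
    "pa",
    "reg",
    "dfpa",
    "lw",
    "lpk",
    "lp",
    "katz",
    "lo",
    "hem",
)

_LOCAL_NAMES = ("cn", "salton", "ra", "ch", "pa")


@dataclass(frozen=True)
class IndexConfig:
    """An index name plus its free parameters.

    Only the parameters the named index uses are consulted:

    ``k``        path-range parameter of LW/LPK/HEM (integer >= 2)
    ``epsilon``  LP path-damping weight
    ``n_max``    LP maximum walk order (>= 3)
    ``beta``     Katz damping (must satisfy beta < 1/λ_max(A))
    ``alpha_lo`` LO damping
    ``alpha``    HEM mixing exponent in [0, 1]
    """

    name: str
    k: int | None = None
    epsilon: float | None = None
    n_max: int | None = None
    beta: float | None = None
    alpha_lo: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", self.name.lower())
        if self.name not in INDEX_NAMES:
            raise ConfigurationError(
                f"unknown index {self.name!r}; expected one of {INDEX_NAMES}"
            )
        if self.k is not None and self.k < 2:
            raise ConfigurationError(f"k must be >= 2 (got {self.k})")
        if self.alpha is not None and not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1] (got {self.alpha})")
        if self.n_max is not None and self.n_max < 3:
            raise ConfigurationError(f"n_max must be >= 3 (got {self.n_max})")

    def describe(self) -> str:
        parts = [self.name]
        for key in ("k", "epsilon", "n_max", "beta", "alpha_lo", "alpha"):
            value = getattr(self, key)
            if value is not None:
                parts.append(f"{key}={value}")
        return " ".join(parts)


@dataclass
class PairScores:
    """Scores for a set of unordered node pairs, with provenance."""

    pairs: np.ndarray  # (m, 2) int array, x < y
    scores: np.ndarray  # (m,) float array
    config: IndexConfig

    def as_dict(self) -> dict[tuple[int, int], float]:
        return {
            (int(x), int(y)): float(s)
            for (x, y), s in zip(self.pairs, self.scores)
        }


class WalkCache:
    """Lazily computed dense walk-count matrices A^k for one graph.

    Powers are exact nonnegative integers stored in float64; once any entry
    would exceed 2**53 the result is no longer exact and
    :class:`WalkOverflowError` is raised. A^{k+1} is built from A^k by one
    sparse-by-dense product, so a bank of indices sharing a cache pays for
    each power once.
    """

    def __init__(self, graph: Graph) -> None:
        self._A = graph.adjacency_matrix()
        self._powers: dict[int, np.ndarray] = {}

    @property
    def adjacency(self) -> sp.csr_matrix:
        return self._A

    def power(self, k: int) -> np.ndarray:
        if k < 1:
            raise ParameterError("walk order must be >= 1")
        cached = self._powers.get(k)
        if cached is not None:
            return cached
        if k == 1:
            result = self._A.toarray()
        else:
            result = self._A @ self.power(k - 1)
        if result.size and result.max() > _WALK_LIMIT:
            raise WalkOverflowError(
                f"walk counts at order {k} exceed 2**53 and are no longer exact; "
                "use a smaller k"
            )
        self._powers[k] = result
        return result


def spectral_radius(graph: Graph) -> float:
    """Largest adjacency eigenvalue λ_max (0 for an edgeless graph)."""
    if graph.n_edges == 0:
        return 0.0
    A = graph.adjacency_matrix()
    n = graph.n_nodes
    if n < 5:
        return float(np.linalg.eigvalsh(A.toarray()).max())
    try:
        vals = sp.linalg.eigsh(A, k=1, which="LA", return_eigenvectors=False)
        return float(vals[0])
    except sp.linalg.ArpackError:  # pragma: no cover - tiny/defective cases
        return float(np.linalg.eigvalsh(A.toarray()).max())


# -- matrix-level index implementations ------------------------------------


def _clamped_degrees(graph: Graph) -> np.ndarray:
    return np.maximum(graph.degrees().astype(np.float64), 1.0)


def cn_matrix(graph: Graph, cache: WalkCache) -> np.ndarray:
    return cache.power(2)


def salton_matrix(graph: Graph, cache: WalkCache) -> np.ndarray:
    deg = graph.degrees().astype(np.float64)
    denom = np.sqrt(np.outer(deg, deg))
    out = np.zeros_like(denom)
    np.divide(cache.power(2), denom, out=out, where=denom > 0)
    return out


def ra_matrix(graph: Graph, cache: WalkCache) -> np.ndarray:
    A = cache.adjacency
    inv_deg = 1.0 / _clamped_degrees(graph)
    return (A @ sp.diags(inv_deg) @ A).toarray()


def pa_matrix(graph: Graph, cache: WalkCache | None = None) -> np.ndarray:
    deg = graph.degrees().astype(np.float64)
    return np.outer(deg, deg)


def ch_matrix(graph: Graph, cache: WalkCache) -> np.ndarray:
    """Cannistraci–Hebb scores for every pair with at least one common neighbor.

    For each common neighbor z of (x, y): kzi counts z's links to the *other*
    common neighbors, kze counts z's links to nodes outside {x, y} and the
    common-neighbor set (z is adjacent to both x and y, so those two links are
    excluded by construction). The pair score is Σ_z (1 + kzi) / (1 + kze).
    """
    n = graph.n_nodes
    S = np.zeros((n, n))
    cn = sp.coo_matrix(sp.triu(sp.csr_matrix(cache.adjacency @ cache.adjacency), k=1))
    for x, y, count in zip(cn.row, cn.col, cn.data):
        if count <= 0:
            continue
        common = graph.neighbors(int(x)) & graph.neighbors(int(y))
        total = 0.0
        for z in common:
            kzi = len(graph.neighbors(z) & common)  # z is not its own neighbor
            kze = graph.degree(z) - 2 - kzi
            total += (1.0 + kzi) / (1.0 + kze)
        S[x, y] = total
        S[y, x] = total
    return S


def reg_matrix(graph: Graph, cache: WalkCache | None = None) -> np.ndarray:
    k = _clamped_degrees(graph)
    return 1.0 / np.outer(k, k)


def dfpa_matrix(graph: Graph, cache: WalkCache | None = None) -> np.ndarray:
    k = _clamped_degrees(graph)
    return np.maximum.outer(k, k) / np.minimum.outer(k, k)


def lw_matrix(graph: Graph, k: int, cache: WalkCache) -> np.ndarray:
    if k < 2:
        raise ParameterError("LW needs k >= 2")
    return cache.power(k) + cache.power(k + 1)


def lpk_matrix(graph: Graph, k: int, cache: WalkCache) -> np.ndarray:
    if k < 2:
        raise ParameterError("LPK needs k >= 2")
    total = cache.power(2).copy()
    for order in range(3, k + 2):
        total += cache.power(order)
    return total


def lp_matrix(graph: Graph, epsilon: float, n_max: int, cache: WalkCache) -> np.ndarray:
    if n_max < 3:
        raise ParameterError("LP needs n_max >= 3")
    total = cache.power(2).copy()
    weight = 1.0
    for order in range(3, n_max + 1):
        weight *= epsilon
        if weight == 0.0:
            break
        total += weight * cache.power(order)
    return total


def katz_matrix(graph: Graph, beta: float, cache: WalkCache | None = None) -> np.ndarray:
    """Katz scores via the closed form (I − βA)^{-1} − I."""
    if beta <= 0:
        raise ParameterError("Katz beta must be positive")
    lam = spectral_radius(graph)
    if lam > 0 and beta >= 1.0 / lam:
        raise ConvergenceError(
            f"beta={beta} >= 1/lambda_max={1.0 / lam:.6g}; "
            "beta must be small enough to ensure convergence"
        )
    n = graph.n_nodes
    A = cache.adjacency.toarray() if cache is not None else graph.adjacency_matrix().toarray()
    S = scipy.linalg.solve(np.eye(n) - beta * A, np.eye(n), assume_a="sym")
    S -= np.eye(n)
    return (S + S.T) / 2.0


def lo_matrix(graph: Graph, alpha: float, cache: WalkCache | None = None) -> np.ndarray:
    """Linear-optimization scores αA(αA^T A + I)^{-1} A^T A (A symmetric)."""
    if alpha <= 0:
        raise ParameterError("LO alpha must be positive")
    n = graph.n_nodes
    if graph.n_edges == 0:
        return np.zeros((n, n))
    A = cache.adjacency if cache is not None else graph.adjacency_matrix()
    A2 = (A @ A).toarray()
    try:
        M = scipy.linalg.solve(alpha * A2 + np.eye(n), A2, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ConvergenceError(
            f"LO solve is singular at alpha={alpha}; reduce alpha to improve conditioning"
        ) from exc
    S = alpha * (A.toarray() @ M)
    return (S + S.T) / 2.0


def hem_matrix(graph: Graph, alpha: float, k: int, cache: WalkCache) -> np.ndarray:
    """Hybrid score Reg^alpha · DFPA^(1-alpha) · LW(k)."""
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("HEM alpha must lie in [0, 1]")
    reg = reg_matrix(graph)
    dfpa = dfpa_matrix(graph)
    lw = lw_matrix(graph, k, cache)
    # reg > 0 and dfpa >= 1 everywhere thanks to the degree clamp, so the
    # fractional powers are well defined; alpha in {0, 1} reduces exactly to
    # the two-factor products.
    if alpha == 0.0:
        return dfpa * lw
    if alpha == 1.0:
        return reg * lw
    return (reg**alpha) * (dfpa ** (1.0 - alpha)) * lw


def score_matrix(
    graph: Graph, config: IndexConfig, cache: WalkCache | None = None
) -> np.ndarray:
    """Dense symmetric score matrix for ``config`` on the (training) graph.

    Pass a shared :class:`WalkCache` when evaluating several indices on the
    same graph so adjacency powers are computed once.
    """
    name = config.name
    needs_cache = name in ("cn", "salton", "ra", "ch", "lw", "lpk", "lp", "hem")
    if cache is None and (needs_cache or name in ("katz", "lo")):
        cache = WalkCache(graph)
    if name == "cn":
        return cn_matrix(graph, cache)
    if name == "salton":
        return salton_matrix(graph, cache)
    if name == "ra":
        return ra_matrix(graph, cache)
    if name == "ch":
        return ch_matrix(graph, cache)
    if name == "pa":
        return pa_matrix(graph)
    if name == "reg":
        return reg_matrix(graph)
    if name == "dfpa":
        return dfpa_matrix(graph)
    if name == "lw":
        if config.k is None:
            raise ConfigurationError("LW needs k")
        return lw_matrix(graph, config.k, cache)
    if name == "lpk":
        if config.k is None:
            raise ConfigurationError("LPK needs k")
        return lpk_matrix(graph, config.k, cache)
    if name == "lp":
        if config.epsilon is None or config.n_max is None:
            raise ConfigurationError("LP needs epsilon and n_max")
        return lp_matrix(graph, config.epsilon, config.n_max, cache)
    if name == "katz":
        beta = DEFAULT_KATZ_BETA if config.beta is None else config.beta
        return katz_matrix(graph, beta, cache)
    if name == "lo":
        alpha = DEFAULT_LO_ALPHA if config.alpha_lo is None else config.alpha_lo
        return lo_matrix(graph, alpha, cache)
    if name == "hem":
        if config.alpha is None or config.k is None:
            raise ConfigurationError("HEM needs alpha and k")
        return hem_matrix(graph, config.alpha, config.k, cache)
    raise ConfigurationError(f"unknown index {name!r}")  # pragma: no cover


# -- pair-level API --------------------------------------------------------


def _normalize_pairs(pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    arr = np.asarray(list(pairs), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    lo = arr.min(axis=1)
    hi = arr.max(axis=1)
    return np.column_stack([lo, hi])


def scores_for_pairs(
    graph: Graph,
    pairs: Iterable[tuple[int, int]],
    config: IndexConfig,
    cache: WalkCache | None = None,
) -> PairScores:
    """Evaluate ``config`` on the given unordered node pairs."""
    arr = _normalize_pairs(pairs)
    if arr.shape[0] == 0:
        return PairScores(arr, np.empty(0), config)
    S = score_matrix(graph, config, cache)
    return PairScores(arr, S[arr[:, 0], arr[:, 1]].astype(np.float64), config)


def local_score(graph: Graph, pairs: Iterable[tuple[int, int]], name: str) -> PairScores:
    """CN / Salton / RA / CH / PA scores for the given pairs."""
    key = name.lower()
    if key not in _LOCAL_NAMES:
        raise ConfigurationError(
            f"unknown local index {name!r}; expected one of {_LOCAL_NAMES}"
        )
    return scores_for_pairs(graph, pairs, IndexConfig(key))


def reg_score(graph: Graph, pairs: Iterable[tuple[int, int]]) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("reg"))


def dfpa_score(graph: Graph, pairs: Iterable[tuple[int, int]]) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("dfpa"))


def walk_counts(graph: Graph, orders: Iterable[int]) -> dict[int, np.ndarray]:
    """Exact walk-count matrices A^k for each requested order."""
    cache = WalkCache(graph)
    return {int(k): cache.power(int(k)) for k in orders}


def lw_score(graph: Graph, pairs: Iterable[tuple[int, int]], k: int) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("lw", k=k))


def lpk_score(graph: Graph, pairs: Iterable[tuple[int, int]], k: int) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("lpk", k=k))


def lp_score(
    graph: Graph, pairs: Iterable[tuple[int, int]], epsilon: float, n_max: int
) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("lp", epsilon=epsilon, n_max=n_max))


def katz_score(
    graph: Graph, pairs: Iterable[tuple[int, int]], beta: float = DEFAULT_KATZ_BETA
) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("katz", beta=beta))


def lo_score(
    graph: Graph, pairs: Iterable[tuple[int, int]], alpha_lo: float = DEFAULT_LO_ALPHA
) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("lo", alpha_lo=alpha_lo))


def hem_score(
    graph: Graph, pairs: Iterable[tuple[int, int]], alpha: float, k: int
) -> PairScores:
    return scores_for_pairs(graph, pairs, IndexConfig("hem", alpha=alpha, k=k))
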