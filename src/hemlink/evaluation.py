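"""Cross-validated evaluation of link-prediction indices.

The protocol: the known edge set E is split into ten folds; each fold in turn
becomes the probe set E^P while the rest form the training set E^T. Indices
are scored on the *training* graph only, and ranking quality is measured
against the nonexistent pairs U − E:

* AUC — the probability that a random probe edge outscores a random
  nonexistent pair, ties counting half: AUC = (n1 + 0.5 n2) / n over n
  comparisons. The default mode is exhaustive (an exact rank statistic equal
  to comparing every probe × nonexistent pair); a sampled estimator with a
  fixed comparison budget is used when the candidate set is too large.
* precision@L — the fraction of probe edges among the top-L candidates, where
  candidates are every non-training pair (probe and nonexistent alike).
  The sort is deterministic: score descending, then pair lexicographic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import MetricUndefinedError, ParameterError
from .graph_core import Graph
from .indices import IndexConfig, WalkCache, score_matrix

__all__ = [
    "FoldSplit",
    "EvalResult",
    "kfold_edges",
    "auc",
    "auc_from_counts",
    "precision_at",
    "cross_validate",
    "cross_validate_many",
    "EXHAUSTIVE_LIMIT",
    "DEFAULT_SAMPLE_COMPARISONS",
]

#: Candidate-pair count above which AUC falls back to sampling.
EXHAUSTIVE_LIMIT = 10_000_000
#: Comparisons per fold in sampling mode.
DEFAULT_SAMPLE_COMPARISONS = 100_000

Scorer = Callable[[Graph, WalkCache], np.ndarray]


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: training edges E^T and probe edges E^P."""

    fold_index: int
    train_edges: np.ndarray  # (m_t, 2)
    probe_edges: np.ndarray  # (m_p, 2)


def kfold_edges(graph: Graph, folds: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Shuffle the edges by ``seed`` and partition them into near-equal folds.

    Every edge is a probe exactly once; fold sizes differ by at most one.
    """
    m = graph.n_edges
    if folds < 2:
        raise ParameterError(f"folds must be >= 2 (got {folds})")
    if folds > m:
        raise ParameterError(f"folds={folds} exceeds edge count {m}")
    edges = graph.edge_array()
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    splits: list[FoldSplit] = []
    for i, probe_idx in enumerate(np.array_split(perm, folds)):
        mask = np.zeros(m, dtype=bool)
        mask[probe_idx] = True
        splits.append(
            FoldSplit(fold_index=i, train_edges=edges[~mask], probe_edges=edges[mask])
        )
    return splits


# -- AUC -------------------------------------------------------------------


def auc_from_counts(n1: int, n2: int, n: int) -> float:
    """(n1 + 0.5 n2) / n — n1 wins, n2 ties, out of n comparisons."""
    if n <= 0:
        raise ParameterError("need at least one comparison")
    if n1 + n2 > n:
        raise ParameterError("n1 + n2 cannot exceed n")
    return (n1 + 0.5 * n2) / n


def _auc_exhaustive(
    probe_scores: np.ndarray, nonexistent_scores: np.ndarray
) -> tuple[float, int, int, int]:
    neg = np.sort(nonexistent_scores)
    lo = np.searchsorted(neg, probe_scores, side="left")
    hi = np.searchsorted(neg, probe_scores, side="right")
    n1 = int(lo.sum())  # nonexistent strictly below
    n2 = int((hi - lo).sum())  # exact ties
    n = probe_scores.size * neg.size
    return auc_from_counts(n1, n2, n), n1, n2, n


def _auc_sampled(
    probe_scores: np.ndarray,
    nonexistent_scores: np.ndarray,
    n: int,
    seed: int,
) -> tuple[float, int, int, int]:
    rng = np.random.default_rng(seed)
    p = probe_scores[rng.integers(probe_scores.size, size=n)]
    q = nonexistent_scores[rng.integers(nonexistent_scores.size, size=n)]
    n1 = int(np.count_nonzero(p > q))
    n2 = int(np.count_nonzero(p == q))
    return auc_from_counts(n1, n2, n), n1, n2, n


def auc(
    probe_scores: Sequence[float] | np.ndarray,
    nonexistent_scores: Sequence[float] | np.ndarray,
    n: int | None = None,
    seed: int | None = None,
) -> float:
    """AUC of probe scores against nonexistent-pair scores.

    With ``n=None`` the exhaustive rank statistic is returned (equivalent to
    averaging over every probe × nonexistent comparison, ties worth half).
    With an integer ``n``, that many independent random comparisons are drawn
    using ``seed``.
    """
    p = np.asarray(probe_scores, dtype=np.float64)
    q = np.asarray(nonexistent_scores, dtype=np.float64)
    if p.size == 0:
        raise ParameterError("probe set is empty")
    if q.size == 0:
        raise MetricUndefinedError(
            "no nonexistent pairs (complete graph): AUC is undefined"
        )
    if n is None:
        return _auc_exhaustive(p, q)[0]
    return _auc_sampled(p, q, int(n), 0 if seed is None else seed)[0]


# -- precision@L -----------------------------------------------------------


def _top_candidate_indices(scores: np.ndarray, L: int) -> np.ndarray:
    """Indices of the top-L scores; ties at the boundary break by position.

    Callers pass candidates in lexicographic pair order, so positional
    tie-breaking implements the documented (score desc, pair lex asc) rule.
    """
    m = scores.size
    if L >= m:
        return np.arange(m)
    part = np.argpartition(-scores, L - 1)[:L]
    threshold = scores[part].min()
    above = np.flatnonzero(scores > threshold)
    at = np.flatnonzero(scores == threshold)
    take = L - above.size
    return np.concatenate([above, at[:take]])


def precision_at(
    probe_edges: Iterable[tuple[int, int]] | np.ndarray,
    candidate_pairs: np.ndarray,
    candidate_scores: np.ndarray,
    L: int = 100,
    n_nodes: int | None = None,
) -> float:
    """Fraction of probe edges among the top-L ranked candidate pairs.

    ``candidate_pairs`` must cover all non-training pairs (probe and
    nonexistent) as an (m, 2) array with x < y; ordering is normalized here.
    """
    if L < 1:
        raise ParameterError("L must be >= 1")
    pairs = np.asarray(candidate_pairs, dtype=np.int64)
    scores = np.asarray(candidate_scores, dtype=np.float64)
    if pairs.shape[0] != scores.size:
        raise ParameterError("candidate pairs and scores differ in length")
    if L > scores.size:
        raise ParameterError(f"L={L} exceeds candidate count {scores.size}")
    n = int(pairs.max()) + 1 if n_nodes is None else n_nodes
    # Lexicographic candidate order gives the deterministic tie-break.
    codes = pairs[:, 0] * n + pairs[:, 1]
    order = np.argsort(codes)
    pairs, scores, codes = pairs[order], scores[order], codes[order]
    top = _top_candidate_indices(scores, L)
    probe = np.asarray(list(probe_edges) if not isinstance(probe_edges, np.ndarray) else probe_edges)
    probe = probe.reshape(-1, 2)
    probe_codes = np.minimum(probe[:, 0], probe[:, 1]) * n + np.maximum(
        probe[:, 0], probe[:, 1]
    )
    hits = int(np.isin(codes[top], probe_codes).sum())
    return hits / L


# -- cross-validation driver ----------------------------------------------


@dataclass
class EvalResult:
    """Per-fold and mean AUC / precision@L plus the comparison counts behind them."""

    index: str
    per_fold_auc: list[float]
    per_fold_precision: list[float]
    L: int | None
    n_comparisons: int
    n1: int
    n2: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_fold_auc))

    @property
    def mean_precision(self) -> float:
        if not self.per_fold_precision:
            return float("nan")
        return float(np.mean(self.per_fold_precision))

    def as_dict(self) -> dict:
        return {
            "index": self.index,
            "mean_auc": self.mean_auc,
            "per_fold_auc": self.per_fold_auc,
            "mean_precision": None if not self.per_fold_precision else self.mean_precision,
            "per_fold_precision": self.per_fold_precision,
            "L": self.L,
            "n_comparisons": self.n_comparisons,
            "n1": self.n1,
            "n2": self.n2,
        }


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=key).generate_state(1)[0] % (2**31))


def cross_validate_many(
    graph: Graph,
    scorers: Mapping[str, IndexConfig | Scorer],
    folds: int = 10,
    seed: int = 0,
    L: int | None = 100,
    auc_mode: str = "auto",
    auc_n: int = DEFAULT_SAMPLE_COMPARISONS,
) -> dict[str, EvalResult]:
    """Evaluate several indices on identical fold splits.

    All scorers share the folds and a per-fold :class:`WalkCache`, so matrix
    powers are computed once per fold no matter how many walk-based indices
    are in the bank. ``scorers`` values are :class:`IndexConfig` or callables
    ``(train_graph, cache) -> dense score matrix``.

    ``L=None`` skips precision@L (AUC only). ``auc_mode`` is ``"exhaustive"``,
    ``"sample"`` or ``"auto"`` (exhaustive while the candidate set has at most
    ``EXHAUSTIVE_LIMIT`` pairs).
    """
    if auc_mode not in ("auto", "exhaustive", "sample"):
        raise ParameterError(f"unknown auc_mode {auc_mode!r}")
    n = graph.n_nodes
    splits = kfold_edges(graph, folds=folds, seed=_child_seed(seed, 0))
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size

    per_auc: dict[str, list[float]] = {name: [] for name in scorers}
    per_prec: dict[str, list[float]] = {name: [] for name in scorers}
    counts = {name: [0, 0, 0] for name in scorers}  # n1, n2, n

    for split in splits:
        train_graph = Graph(n, split.train_edges, labels=graph.labels)
        cache = WalkCache(train_graph)
        train_mask = np.zeros((n, n), dtype=bool)
        train_mask[split.train_edges[:, 0], split.train_edges[:, 1]] = True
        train_mask[split.train_edges[:, 1], split.train_edges[:, 0]] = True
        probe_mask = np.zeros((n, n), dtype=bool)
        probe_mask[split.probe_edges[:, 0], split.probe_edges[:, 1]] = True
        probe_mask[split.probe_edges[:, 1], split.probe_edges[:, 0]] = True
        train_flat = train_mask[iu, ju]
        probe_flat = probe_mask[iu, ju]
        nonexistent_flat = ~train_flat & ~probe_flat
        if not nonexistent_flat.any():
            raise MetricUndefinedError(
                "no nonexistent pairs (complete graph): AUC is undefined"
            )
        n_candidates = n_pairs - int(train_flat.sum())
        exhaustive = auc_mode == "exhaustive" or (
            auc_mode == "auto" and n_candidates <= EXHAUSTIVE_LIMIT
        )
        cand_idx = np.flatnonzero(~train_flat)
        cand_pairs = np.column_stack([iu[cand_idx], ju[cand_idx]])
        for name, scorer in scorers.items():
            if isinstance(scorer, IndexConfig):
                S = score_matrix(train_graph, scorer, cache)
            else:
                S = scorer(train_graph, cache)
            flat = S[iu, ju]
            probe_scores = flat[probe_flat]
            nonexistent_scores = flat[nonexistent_flat]
            if exhaustive:
                value, n1, n2, n_comp = _auc_exhaustive(probe_scores, nonexistent_scores)
            else:
                value, n1, n2, n_comp = _auc_sampled(
                    probe_scores,
                    nonexistent_scores,
                    auc_n,
                    _child_seed(seed, 1, split.fold_index),
                )
            per_auc[name].append(value)
            counts[name][0] += n1
            counts[name][1] += n2
            counts[name][2] += n_comp
            if L is not None:
                per_prec[name].append(
                    precision_at(
                        split.probe_edges, cand_pairs, flat[cand_idx], L=L, n_nodes=n
                    )
                )

    results = {}
    for name in scorers:
        label = name if isinstance(name, str) else str(name)
        results[name] = EvalResult(
            index=label,
            per_fold_auc=per_auc[name],
            per_fold_precision=per_prec[name],
            L=L,
            n1=counts[name][0],
            n2=counts[name][1],
            n_comparisons=counts[name][2],
        )
    return results


def cross_validate(
    graph: Graph,
    config: IndexConfig | Scorer,
    folds: int = 10,
    seed: int = 0,
    L: int | None = 100,
    auc_mode: str = "auto",
    auc_n: int = DEFAULT_SAMPLE_COMPARISONS,
) -> EvalResult:
    """10-fold (by default) cross-validation of a single index."""
    name = config.describe() if isinstance(config, IndexConfig) else "custom"
    return cross_validate_many(
        graph, {name: config}, folds=folds, seed=seed, L=L, auc_mode=auc_mode, auc_n=auc_n
    )[name]
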