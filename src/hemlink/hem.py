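"""The HEM hybrid index, its (α, k) grid scan, and main-factor analysis.

HEM mixes the three evolution-mechanism indices multiplicatively:

    S_xy = Reg_xy^α · DFPA_xy^(1−α) · LW(k)_xy

α in [0, 1] balances the two degree-based mechanisms (α → 1 favors the
degree-balance index Reg, α → 0 the degree-difference index DFPA) and k sets
the walk range of the topological factor LW. The standard grid samples
α ∈ {0, 0.25, 0.5, 0.75, 1} × k ∈ {2, 4, 8} (15 cells) and reports the best
cell per metric.

Two diagnostics identify which constituent factor drives prediction on a
given network:

* method 1 — cross-validate the five factors {Reg, DFPA, LW2, LW4, LW8}
  separately and keep the top two (if both are LW variants, only the best);
* method 2 — take the five best (α, k) grid cells, aggregate α* = mean α and
  k* = mode of k, and read the main factors off the aggregates: LW(k*) always,
  plus Reg when α* > 0.5 or DFPA when α* < 0.5 (neither at exactly 0.5).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .evaluation import EvalResult, cross_validate_many
from .graph_core import Graph
from .indices import IndexConfig, PairScores
from .indices import hem_score as _hem_score_pairs

__all__ = [
    "DEFAULT_ALPHAS",
    "DEFAULT_KS",
    "FACTOR_ORDER",
    "HemCell",
    "HemGrid",
    "FactorReport",
    "Method1Result",
    "Method2Result",
    "hem_score",
    "grid_scan",
    "factor_method1",
    "factor_method2",
    "select_main_factors_method1",
    "aggregate_top5",
    "factor_report",
]

DEFAULT_ALPHAS = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_KS = (2, 4, 8)

#: Fixed factor order; also the deterministic tie-break for method 1.
FACTOR_ORDER = ("Reg", "DFPA", "LW2", "LW4", "LW8")

#: Guard against float drift when comparing the mean of grid alphas to 0.5.
_ALPHA_TOL = 1e-9


def hem_score(graph: Graph, pairs: Iterable[tuple[int, int]], alpha: float, k: int) -> PairScores:
    """HEM scores for the given unordered node pairs."""
    return _hem_score_pairs(graph, pairs, alpha=alpha, k=k)


@dataclass
class HemCell:
    """One (α, k) grid cell with its cross-validated result."""

    alpha: float
    k: int
    result: EvalResult

    def metric(self, name: str = "auc") -> float:
        if name == "auc":
            return self.result.mean_auc
        if name == "precision":
            return self.result.mean_precision
        raise ConfigurationError(f"unknown metric {name!r}")


@dataclass
class HemGrid:
    """All cells of an (α, k) scan, evaluated on identical fold splits."""

    alphas: tuple[float, ...]
    ks: tuple[int, ...]
    cells: list[HemCell]

    def cell(self, alpha: float, k: int) -> HemCell:
        for c in self.cells:
            if c.k == k and abs(c.alpha - alpha) < 1e-12:
                return c
        raise KeyError((alpha, k))

    def ranked(self, metric: str = "auc") -> list[HemCell]:
        """Cells sorted by (metric desc, α asc, k asc) — deterministic."""
        return sorted(self.cells, key=lambda c: (-c.metric(metric), c.alpha, c.k))

    def best(self, metric: str = "auc") -> HemCell:
        return self.ranked(metric)[0]

    def as_dict(self, metric: str = "auc") -> dict:
        best = self.best(metric)
        return {
            "alphas": list(self.alphas),
            "ks": list(self.ks),
            "cells": [
                {"alpha": c.alpha, "k": c.k, **c.result.as_dict()} for c in self.cells
            ],
            "best": {"alpha": best.alpha, "k": best.k, "metric": metric,
                     "value": best.metric(metric)},
        }


def grid_scan(
    graph: Graph,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    ks: Sequence[int] = DEFAULT_KS,
    folds: int = 10,
    seed: int = 0,
    L: int | None = 100,
    auc_mode: str = "auto",
) -> HemGrid:
    """Cross-validate HEM at every (α, k) cell on shared fold splits."""
    if not alphas or not ks:
        raise ConfigurationError("grid_scan needs nonempty alpha and k grids")
    configs = {
        (float(a), int(k)): IndexConfig("hem", alpha=float(a), k=int(k))
        for a in alphas
        for k in ks
    }
    results = cross_validate_many(
        graph, configs, folds=folds, seed=seed, L=L, auc_mode=auc_mode
    )
    cells = [HemCell(alpha=a, k=k, result=results[(a, k)]) for (a, k) in configs]
    return HemGrid(alphas=tuple(float(a) for a in alphas), ks=tuple(int(k) for k in ks), cells=cells)


# -- method 1: factors evaluated separately --------------------------------


def factor_configs() -> dict[str, IndexConfig]:
    return {
        "Reg": IndexConfig("reg"),
        "DFPA": IndexConfig("dfpa"),
        "LW2": IndexConfig("lw", k=2),
        "LW4": IndexConfig("lw", k=4),
        "LW8": IndexConfig("lw", k=8),
    }


def select_main_factors_method1(factor_auc: Mapping[str, float]) -> tuple[str, ...]:
    """Top two factors by AUC; if both are LW variants, only the better one.

    Ties break by the fixed :data:`FACTOR_ORDER`. The returned tuple is
    presented in factor order (degree factors before LW).
    """
    names = [f for f in FACTOR_ORDER if f in factor_auc]
    if len(names) < 2:
        raise ConfigurationError("method 1 needs at least two factors")
    ranked = sorted(names, key=lambda f: (-factor_auc[f], FACTOR_ORDER.index(f)))
    top_two = ranked[:2]
    if all(f.startswith("LW") for f in top_two):
        return (top_two[0],)
    return tuple(sorted(top_two, key=FACTOR_ORDER.index))


@dataclass
class Method1Result:
    factor_auc: dict[str, float]
    main_factors: tuple[str, ...]
    results: dict[str, EvalResult]

    def as_dict(self) -> dict:
        return {
            "factor_auc": self.factor_auc,
            "main_factors": list(self.main_factors),
        }


def factor_method1(
    graph: Graph,
    folds: int = 10,
    seed: int = 0,
    L: int | None = None,
    auc_mode: str = "auto",
) -> Method1Result:
    """Cross-validate the five factors separately and pick the main ones."""
    results = cross_validate_many(
        graph, factor_configs(), folds=folds, seed=seed, L=L, auc_mode=auc_mode
    )
    factor_auc = {name: res.mean_auc for name, res in results.items()}
    return Method1Result(
        factor_auc=factor_auc,
        main_factors=select_main_factors_method1(factor_auc),
        results=results,
    )


# -- method 2: aggregate the top grid cells --------------------------------


def aggregate_top5(cells: Sequence[tuple[float, int]]) -> tuple[float, int, tuple[str, ...]]:
    """Aggregate top (α, k) combinations into (α*, k*, main factors).

    α* is the mean of the α values; k* is the mode of the k values (smallest
    modal k on ties). Main factors: LW(k*) always; Reg when α* > 0.5, DFPA
    when α* < 0.5, neither when α* is exactly 0.5 (both degree factors then
    have little effect).
    """
    if not cells:
        raise ConfigurationError("aggregate_top5 needs at least one cell")
    alphas = [float(a) for a, _ in cells]
    ks = [int(k) for _, k in cells]
    alpha_star = float(np.mean(alphas))
    counts = Counter(ks)
    top_count = max(counts.values())
    k_star = min(k for k, c in counts.items() if c == top_count)
    main: list[str] = []
    if alpha_star > 0.5 + _ALPHA_TOL:
        main.append("Reg")
    elif alpha_star < 0.5 - _ALPHA_TOL:
        main.append("DFPA")
    main.append(f"LW{k_star}")
    return alpha_star, k_star, tuple(main)


@dataclass
class Method2Result:
    top5: list[tuple[float, int]]
    alpha_star: float
    k_star: int
    main_factors: tuple[str, ...]

    def as_dict(self) -> dict:
        return {
            "top5": [{"alpha": a, "k": k} for a, k in self.top5],
            "alpha_star": self.alpha_star,
            "k_star": self.k_star,
            "main_factors": list(self.main_factors),
        }


def factor_method2(grid: HemGrid, metric: str = "auc") -> Method2Result:
    """Aggregate the five best grid cells into (α*, k*) and the main factors.

    The ranking metric defaults to AUC; pass ``metric="precision"`` to rank by
    precision@L instead (the analysis then proceeds identically).
    """
    if len(grid.cells) < 5:
        raise ConfigurationError(
            f"method 2 needs a grid of at least 5 cells (got {len(grid.cells)})"
        )
    top5 = [(c.alpha, c.k) for c in grid.ranked(metric)[:5]]
    alpha_star, k_star, main = aggregate_top5(top5)
    return Method2Result(top5=top5, alpha_star=alpha_star, k_star=k_star, main_factors=main)


# -- combined report -------------------------------------------------------


@dataclass
class FactorReport:
    """Both factor analyses for one network."""

    method1: Method1Result
    grid: HemGrid
    method2: Method2Result

    def as_dict(self) -> dict:
        return {
            "method1": self.method1.as_dict(),
            "method2": self.method2.as_dict(),
            "grid": self.grid.as_dict(),
        }


def factor_report(
    graph: Graph,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    ks: Sequence[int] = DEFAULT_KS,
    folds: int = 10,
    seed: int = 0,
    L: int | None = 100,
    metric: str = "auc",
) -> FactorReport:
    """Run the grid scan and both main-factor methods on one network."""
    grid = grid_scan(graph, alphas=alphas, ks=ks, folds=folds, seed=seed, L=L)
    m1 = factor_method1(graph, folds=folds, seed=seed, L=None)
    m2 = factor_method2(grid, metric=metric)
    return FactorReport(method1=m1, grid=grid, method2=m2)
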