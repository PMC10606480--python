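# Methods

This note records the models implemented, the conventions and numerical
choices behind them, what the generated test networks do and do not emulate,
and the design decisions made where the design was genuinely open.

## Graphs and preprocessing

All computation runs on undirected simple graphs with contiguous 0-based
integer node ids; an optional label table maps ids back to the input file's
labels (internal ids keep the dense index space that matrix powers need).
Raw edge lists are simplified on read: direction discarded, parallel edges
merged, self-loops dropped. Simplification is idempotent. Analyses that need
connectivity (feature summaries, cross-validation pipelines) run on the
giant component; ties between equal-sized components go to the one
containing the smallest node id.

Network features follow the usual definitions: N, M, mean degree K = 2M/N,
maximum degree Δ, diameter D from breadth-first search out of every node
(O(N·M)), and degree assortativity ρ as the Pearson correlation of endpoint
degrees over edges counted once in each orientation. ρ is reported as an
explicit undefined marker (NaN) when the endpoint-degree variance is zero —
regular graphs would otherwise raise on 0/0 — so generated regular networks
can still be summarized. "Clustering coefficient" is ambiguous in the
literature; C here is the **mean local** clustering coefficient (the
Watts–Strogatz definition, with degree-<2 nodes contributing 0), since the
small-world framing of the model set points there. Global transitivity is
exposed as a secondary field for users who want the other convention.

## Generators

The generators define the study conditions and are deliberately minimal:

- **random regular** (n, d): configuration-model stub pairing. Random stub
  pairs are drawn and joined when legal (no self-loop, no duplicate); a long
  streak of illegal draws means the remaining stubs are deadlocked and the
  attempt restarts. A naive variant that restarts on *any* collision is
  simpler but effectively never terminates for d ≳ 10 at n = 2000, which the
  regular-network benchmark needs (d up to 33); the per-pair rejection keeps
  the sampler practical at every benchmark degree while remaining a pairing
  model. Generation is exact: every node has degree d.
- **BA** (n, m): growth plus preferential attachment P(i) = k_i/Σk_j. The
  seed network is a complete graph on m+1 nodes — the standard minimal
  choice that lets every arrival draw m distinct targets immediately — so
  the final edge count is exactly (m+1)m/2 + (n−m−1)m. Multi-target draws
  are without replacement (repeat draws rejected), making the m new links
  distinct.
- **WS** (n, K, p): ring lattice (K/2 neighbors per side), then each lattice
  edge visited once in ring order is rewired with probability p by replacing
  its far endpoint with a uniform node. Rejected rewires (self-loop or
  duplicate) are redrawn up to n times, then the edge is left in place, so
  |E| = nK/2 always. p=0 is the lattice, p=1 a fully randomized graph.
- **NW** (n, K, p): same lattice, but shortcuts are *added* (one Bernoulli
  trial per lattice edge, uniform random endpoints, duplicates redrawn up to
  n times then skipped) and no lattice edge is ever removed.

All generators are bit-reproducible given their seed (numpy Generator).
What these emulate: the three canonical degree/topology regimes — degree
homogeneity, scale-free heterogeneity, local clustering with shortcuts.
What they do not: community structure, weighted or directed interactions,
degree correlations beyond what the mechanisms induce, and the measurement
noise of real interaction screens. Passing tests on these models therefore
demonstrate that each index exploits the mechanism it was designed for, not
that any fixed parameter setting transfers to a particular empirical
network — for real data the grid scan and factor diagnostics exist
precisely to make that choice per network.

## Indices

Scores are always computed from the **training** graph; probe edges are
never present in its adjacency matrix. Each index is materialized as a dense
n×n symmetric score matrix; a per-fold walk cache shares adjacency powers
A^k across all walk-based indices evaluated on the same fold, computing
A^{k+1} from A^k by one sparse-by-dense product.

- CN, Salton, RA, PA follow their textbook formulas. Salton returns 0 when
  either endpoint has degree 0.
- CH: for common neighbor z of (x, y), kzi counts z's links to the other
  common neighbors and kze counts z's links outside {x, y} ∪ common
  neighbors; links from z to x and y themselves are excluded from kze (other
  CH variants exist; this follows the internal/external split used here).
- Reg and DFPA use the degree clamp k̂ = max(k, 1): fold removal can isolate
  a node and both formulas divide by degree. The clamp keeps every probe
  pair scoreable and is inert in the studied regimes (isolated training
  nodes are vanishingly rare at n = 2000).
- LW/LPK/LP sum walk-count matrices; walk counts are exact integers carried
  in float64 and checked against the 2^53 representability ceiling — beyond
  it the computation aborts with advice to lower k rather than silently
  losing exactness. LP with ε = 0 reduces to CN; LPK(k) is LP with ε = 1 and
  order k+1.
- Katz uses the closed form (I − βA)^{-1} − I via a symmetric dense solve
  after verifying β < 1/λ_max(A) (λ_max from a sparse symmetric
  eigensolver). Default β = 0.01.
- LO solves αA(αA²+I)^{-1}A² (A symmetric) with a dense symmetric solve,
  then symmetrizes to remove float drift. Default α = 0.01. Note: LO's
  alternating series admits *small genuine negative entries* at working
  damping (order α²·A⁵); non-negativity holds for every other index but
  only approximately for LO. Tests bound the negativity by the second-order
  series term instead of asserting ≥ 0.
- HEM = Reg^α · DFPA^{1−α} · LW(k). The clamp guarantees Reg > 0 and
  DFPA ≥ 1, so fractional powers are well defined; α ∈ {0, 1} short-circuits
  to the exact two-factor product.

## Evaluation

Edges are shuffled once per run seed and partitioned into 10 near-equal
folds; every edge is a probe exactly once. Training graphs keep the full
node set (they may disconnect — the degree clamp and walk counts handle
that naturally); no connectivity repair is applied.

AUC compares probe edges against nonexistent pairs U − E (probe edges are
legitimate missing links, so the candidate universe excludes training edges
only). The number of comparisons behind the metric is not pinned down by
the protocol's usual statement, so the default is the **exhaustive** rank
statistic — exactly the n → ∞ limit of the sampled estimator, computed by
sorting the nonexistent scores once and binary-searching each probe score
(ties count half). This removes one noise source from benchmark
comparisons. A sampled mode (n independent probe/nonexistent draws,
default 10^5 per fold) kicks in automatically above 10^7 candidate pairs
and is exposed directly for users who want the estimator itself.

Precision@L (default L = 100) ranks all non-training pairs; the sort is
deterministic: score descending, then pair lexicographic ascending. With
tied scores the lexicographic prefix wins — documented and tested, since
any tie rule is a convention.

Reproducibility: a single run seed fans out to per-stage child seeds via
`numpy.random.SeedSequence` spawn keys, so adding a stage never perturbs
earlier stages' randomness; identical (graph, config, seed) gives identical
results bit for bit.

## HEM grid and factor diagnostics

The grid scan evaluates every (α, k) cell on identical fold splits with a
shared per-fold walk cache (default 5 × 3 = 15 cells). Cells rank by mean
AUC over folds; ranking by precision@L is a flag away and the analysis
proceeds identically. Tie-breaks are deterministic: (metric desc, α asc,
k asc).

Method 1 cross-validates the five factors {Reg, DFPA, LW2, LW4, LW8}
separately and keeps the top two by mean AUC — unless both are LW variants,
in which case only the better LW is kept. Full ties break by the fixed
factor order above.

Method 2 takes the five best grid cells, aggregates α\* = mean α and
k\* = mode of k (smallest modal k on ties — the cheapest deterministic
rule), and reads the main factors off the aggregates: LW(k\*) always, plus
Reg when α\* > 0.5 and DFPA when α\* < 0.5; at exactly 0.5 neither degree
factor is considered. On the default grid α\* is a multiple of 0.05, so the
comparison to 0.5 is exact; a 1e−9 guard absorbs float drift anyway.

## Problem sizes

The regular-network benchmark runs at its stated scale (n = 2000, seven
degrees, 10 folds, three generator seeds — chosen to average generation
noise below the ±0.02 comparison band). The scale-free and small-world
direction checks also run at n = 2000. Unit and property tests use graphs
of tens of nodes, where the exhaustive oracles (recursive walk enumeration,
Floyd–Warshall diameters, brute-force CH) are affordable. The factor
diagnostics' qualitative checks use n = 1000 generated networks, large
enough for the mechanism signal to dominate fold noise.

## Known limitations

- Weighted, directed, bipartite and temporal graphs are out of scope;
  inputs are coerced to undirected simple graphs.
- Dense score matrices cost O(n²) memory (~0.3 GB at n ≈ 6000); the
  implementation targets networks up to a few thousand nodes, matching the
  benchmark suite. Larger graphs would need a pair-block evaluation path.
- Walk orders are limited by the 2^53 exactness ceiling (reached around
  λ_max^k ≈ 9·10^15, e.g. k ≳ 11 on dense 2000-node graphs).
- α is sampled on a grid, never optimized continuously; the factor
  heuristics diagnose, they do not guarantee, the best cell.
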