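# hemlink

Link prediction on complex networks via evolution-mechanism indices and the
HEM hybrid score.

## The problem

Given an undirected interaction network G(V, E) — a protein–protein
interaction map, a collaboration graph, a power grid — link prediction ranks
the unobserved node pairs in U − E by how likely they are to be missing (or
future) edges. Similarity-based predictors assign every pair (x, y) a score
S<sub>xy</sub> from network structure alone; quality is measured by hiding a
tenth of the edges (10-fold edge cross-validation) and asking how well the
scorer ranks the hidden *probe* edges above the truly nonexistent pairs.

The angle taken here is that different network *evolution mechanisms* call
for different scorers, and that a tunable hybrid of mechanism-specific
indices adapts to real networks better than any single classical index:

- **Reg** — S<sub>xy</sub> = 1/(k<sub>x</sub>k<sub>y</sub>): degree balance.
  On (near-)regular networks the only signal left after hiding edges is the
  degree deficit of probe endpoints, which this index reads directly.
- **DFPA** — S<sub>xy</sub> = max(k<sub>x</sub>,k<sub>y</sub>)/min(k<sub>x</sub>,k<sub>y</sub>):
  degree difference. Scale-free, disassortative networks preferentially wire
  hubs to low-degree nodes.
- **LW(k)** — S<sub>xy</sub> = (A<sup>k</sup> + A<sup>k+1</sup>)<sub>xy</sub>:
  walk counts at range k (walks may retrace edges — the round trips carry
  neighborhood information). Small-world, high-clustering networks are
  dominated by short-range topology.
- **HEM** — S<sub>xy</sub> = Reg<sup>α</sup> · DFPA<sup>1−α</sup> · LW(k),
  with α ∈ [0, 1] balancing the two degree mechanisms and k setting the walk
  range. A 5 × 3 grid (α ∈ {0, 0.25, 0.5, 0.75, 1}, k ∈ {2, 4, 8}) is scanned
  under shared cross-validation folds and the best cell is reported.

A comparison bank of classical indices (CN, Salton, RA, CH, PA, LP/LPK,
Katz, LO) is included, along with seeded generators for the three reference
models (random regular, Barabási–Albert, Watts–Strogatz / Newman–Watts),
network feature summaries (N, M, K, Δ, D, C, ρ), and two diagnostics that
identify which factor of HEM drives prediction on a given network — either
by cross-validating the factors separately, or by aggregating the top five
grid cells into α\* (mean) and k\* (mode).

## Worked example

Generate a small-world network, summarize it, evaluate one index, scan the
HEM grid, and ask which factor dominates:

```bash
$ hemlink generate --model ws --n 500 --ring-k 8 --p 0.1 --seed 7 --out ws.txt
wrote 500 nodes, 2000 edges to ws.txt

$ hemlink stats --graph ws.txt
{
  "N": 500, "M": 2000, "K": 8.0, "Delta": 12, "D": 8,
  "C": 0.4736696969696969, "rho": -0.056677938668747624,
  "transitivity": 0.4617171006333568
}

$ hemlink evaluate --graph ws.txt --index lw --k 2 --folds 10 --seed 1 --L 100
{
  "index": "lw k=2",
  "mean_auc": 0.9430980794297351,
  "mean_precision": 0.177
}

$ hemlink hem-scan --graph ws.txt --folds 10 --seed 1 --L 100
{
  "alpha": 1.0, "k": 2, "metric": "auc", "value": 0.9460879857433809
}

$ hemlink factors --graph ws.txt --method 1 --folds 10 --seed 1
{
  "method1": {
    "factor_auc": {
      "Reg": 0.7503571038696538, "DFPA": 0.5475807718940937,
      "LW2": 0.9430980794297351, "LW4": 0.9391326945010183,
      "LW8": 0.9280444725050916
    },
    "main_factors": ["LW2"]
  }
}
```

Reading the numbers: at 10% rewiring the lattice's clustering survives
(C ≈ 0.47), so short walks carry most of the signal — LW2 alone reaches
AUC 0.943 (94.3% of probe-vs-nonexistent comparisons ranked correctly), the
two degree factors trail far behind, and the best HEM cell (α = 1, k = 2,
AUC 0.946) edges out every single factor. The `factors` diagnostic agrees:
the main factor of this network is LW2.

The same machinery is available as a library (`hemlink.cross_validate`,
`hemlink.grid_scan`, `hemlink.factor_report`, ...), and
`hemlink run-report --graph net.txt --out report.json` bundles the whole
pipeline — giant component, features, index bank, HEM grid, both factor
methods — into one JSON report.

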