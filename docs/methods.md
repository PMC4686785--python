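# Methods

## Model and assumptions

The package scores genes on an integrated network: an undirected PPI graph
restricted to genes with expression in both conditions and to its main
connected component. Three network-medicine working hypotheses motivate the
procedure: disease genes cluster into network modules; shortest paths between
disease genes trace disease pathways (network parsimony); and genes of
similar diseases interact directly (local hypothesis). The method therefore
looks only at shortest paths between seeds and the seeds' direct
neighborhood, weights them by expression concordance, and treats the
*difference* between conditions as the disease signal.

Key modelling choices:

- **Concordance, not correlation.** A path's co-expression is Kendall's W
  over its genes' profiles, maximized over per-gene profile inversions
  (W_max), so coordinated down-regulation counts as much as coordinated
  up-regulation. Enumeration over the 2^(m−1) sign classes is exact; the
  first gene's sign is fixed because global negation leaves W unchanged.
  Ties in expression get mid-ranks with the standard tie-correction term;
  under mid-ranks, negating a profile mirrors its ranks exactly, so
  inversion-by-negation and rank-reversal coincide.
- **Ordered pairs.** σ sums over ordered pairs (s ∈ S, t ∈ S∪N, s ≠ t),
  exactly as the double sum is written; a seed–seed pair therefore
  contributes in both orientations (its two σ contributions differ through
  d_sg). Pairs with t = s are excluded (a zero-length path has no
  concordance). d_sg is the graph distance on the full network, not the
  position within a path, and the distance penalty always refers to the
  pair's own seed.
- **Per-condition selection.** Candidate shortest paths depend only on the
  graph; their W_max values, and hence which paths survive the ε tie rule,
  are computed independently per condition. Identical expression in the two
  conditions yields identical selected sets.

## Parameters

| name | default | units / meaning |
|---|---|---|
| λ (`lambda_decay`) | 2 | per-hop decay base of the distance penalty λ^(−d); 2 halves a contribution per hop. No published reference value exists for it, so it is a documented knob. |
| ε (`epsilon`) | 0.05 | tie tolerance: paths with W_max ≥ (1−ε)·best survive |
| `w_len`, `w_step` | 2, 1 | sliding-window length and step on the X axis (X units) for the envelope fit |
| `x_ini` | 5 | intensity filter: only genes with X strictly greater take part in the analysis ranking |
| `max_path_genes` | 12 | cap on genes per path for the exact 2^(m−1) enumeration |
| `path_cap` | 10,000 | cap on shortest paths per pair (lexicographically first kept, truncation logged) |
| `min_points_per_window` | 5 | minimum genes for a window to qualify |
| `top_fraction` | 0.1 | fraction of unfiltered genes reported as the top list |

## Numerical choices

- **Quartiles** use the linear-interpolation convention (`numpy.percentile`);
  quartile conventions shift the envelope fit, so this is fixed.
- **Envelope.** Windows [x_ini + i·w_step, x_ini + i·w_step + w_len) with
  midpoint abscissae; Q3 of |Δ| per window (one symmetric envelope for both
  signs — a `signed_envelope` switch exists for separate treatment of the
  signed Q3); log(q3) on log(center) by ordinary least squares. Windows with
  Q3 = 0 are dropped. Fixed-width windows presume a densely populated X axis
  (thousands of scored genes). When fewer than two windows qualify — small
  networks or few seeds leave the X > x_ini stratum with a handful of genes —
  the fit falls back to equal-count windows (up to 8 bins of ≥3 genes,
  center = median X of the bin) over *all* scored genes, so the envelope is
  estimated across the whole intensity range on which it is evaluated. The
  fallback is logged and visible in the fit report.
- **Determinism.** Path enumeration is lexicographic (DFS over the BFS
  shortest-path DAG with sorted neighbor order); W_max ties break to the
  lexicographically smallest sign vector; ranking ties break by gene symbol;
  the largest-component tie breaks by smallest member. Identical inputs and
  parameters give byte-identical outputs.
- **Degenerate inputs.** Fully tied rank matrices define W = 0 (with a
  warning); X = 0 genes are dropped; unreachable seed–target pairs are
  skipped and counted; λ ≤ 1 and ε ∉ [0, 1) are rejected.

## Synthetic benchmark

`neri.synthetic` generates the structure the method assumes, with ground
truth: a connected preferential-attachment (Barabási–Albert) graph
(default 300 genes, attachment 2); 5 seeds drawn from nodes of degree ≥ 3
(well-characterized disease genes are not peripheral), excluding the
top-degree nodes; a planted module of 20 genes grown as a *connected*
subgraph anchored at the seeds within 2 hops, preferring candidates adjacent
to the most seed/module members — a literal rendering of the disease-module
hypothesis, and the regime the shortest-path scoring is designed for
(scattered planted genes would sit on almost no common paths); 10 decoy hubs
(the highest-degree non-seed nodes); 30 samples per condition.

Expression follows a single latent factor per condition: followers take
ρ·F + sqrt(1−ρ²)·noise with ρ = 0.9, so two followers correlate at ρ² = 0.81.
Seeds and decoy hubs follow the factor in both conditions; planted genes
follow it in disease only; everything else is independent standard normal
noise. The factor model produces exactly the monotone rank-concordance W_max
rewards. Decoy hubs emulate ascertainment bias: they should rank high by
intensity X but low by |Δ′|.

What the generator does *not* emulate: probe/batch effects, heavy-tailed
expression, correlated background modules, false/missing PPI edges, or
weighted interactions. Passing benchmarks therefore demonstrate that the
pipeline detects differential seed-anchored co-expression under its own
modelling assumptions, not field performance on microarray data.

**Scale caveat.** At the benchmark scale (300 genes, 5 seeds) the σ sums are
roughly an order of magnitude smaller than on a full interactome with tens of
seeds, so the X > 5 analysis filter retains only a core of well-trafficked
genes and most planted genes fall below it. Recovery metrics
(`neri.model.evaluate`) therefore rank *all* path-covered genes by Δ/f(X)
with the envelope extrapolated below the filter — the appropriate universe
for a whole-network precision baseline (|planted|/n_genes) — while the
analysis outputs (`scores.tsv`, `top_genes`) keep the filtered ranking.
Problem sizes used by the test suite and the acceptance script: 1,000 random
profile sets for the concordance oracle, 200 random graphs (≤ 12 nodes) for
the path oracle, and 10 generator seeds × 300-gene networks for the recovery
benchmark.

## Known limitations

- λ is not empirically calibrated; rankings at distance > 2 from seeds are
  sensitive to it.
- The ε band is relative to the per-pair maximum, so pairs whose best path is
  weak still contribute (weak) paths; there is no absolute concordance floor.
- Path truncation at `path_cap` keeps a lexicographic prefix, which on very
  dense graphs is an arbitrary (though deterministic) subset; orientation
  reuse means the reversed pair shares the same candidate subset.
- The power-law envelope is a global two-parameter fit; strong local
  curvature of the intensity–alteration relation is not captured.
- Multi-list replication statistics assume independent uniform draws for the
  random expectation, ignoring the shared network topology across studies.
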