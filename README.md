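# neri

Network-medicine gene prioritization by relative importance: integrates a
protein–protein interaction (PPI) network with case/control gene expression
and a seed list of known disease genes, and ranks candidate genes by how
strongly their concordance-weighted connectivity to the seeds *changes*
between the two conditions.

## Who this is for

Groups studying complex, polygenic diseases (the design case is psychiatric
disorders such as schizophrenia) who have (a) GWAS-derived or curated seed
genes, (b) expression profiles for control and disease cohorts, and (c) one or
more PPI edge lists, and who want candidate genes that are *disease-specific*
rather than merely well-studied. Pure topology methods (random walk with
restart and relatives) inherit ascertainment bias — heavily studied proteins
have more recorded interactions and dominate the rankings. Weighting network
paths by condition-specific co-expression and scoring the *difference* between
conditions suppresses that bias.

## Method

Inputs are merged into one undirected gene-symbol network (union of edge
lists, transcripts collapsed to genes by the median, genes kept only if
present in both network and expression, restricted to the main connected
component).

1. **Neighborhood.** The seed set S is grown to S∪N with N the seeds' direct
   neighbors. For every ordered pair (s ∈ S, t ∈ S∪N), all shortest paths are
   enumerated.
2. **Concordance.** A path is scored by W_max: Kendall's coefficient of
   concordance W over its genes' expression profiles (genes = judges, samples
   = objects), maximized over all per-gene profile inversions so up- and
   down-regulated genes count alike. Per pair, every path with
   W_max ≥ (1−ε)·max is kept (ε = 0.05 by default: a best path at 0.60 admits
   ties down to 0.57). Selection runs separately on control and disease
   samples.
3. **Scoring.** Each gene accumulates, per condition,

   σ(g) = Σ_{s∈S} Σ_{t∈S∪N} Σ_{P ∈ P*_st} λ^(−d_sg) · W_max(P) · 1[g ∈ P],

   with d_sg the graph distance from the pair's seed and λ = 2 by default
   (halving per hop), giving σ_C(g) and σ_D(g).
4. **Differential selection.** MA-plot style: intensity X = σ_C + σ_D and
   relative alteration Δ = (σ_D − σ_C)/X ∈ [−1, 1]. Because high-X genes show
   systematically smaller |Δ|, a power-law envelope f(x) = a·x^(−k) is fitted
   to sliding-window third quartiles of |Δ| and the normalized score is
   Δ′ = Δ / f(X). Genes are ranked by |Δ′| (sign: positive = stronger
   co-expression in disease); X itself ranks "party-hub"-like genes that are
   central and co-expressed in both conditions.

## Worked example

Generate a synthetic benchmark (scale-free network, 5 seeds, a planted
disease-only co-expression module of 20 genes, 10 equal-co-expression decoy
hubs) and run the pipeline on the written TSV files:

```sh
neri simulate --seed 42 --outdir demo
neri run --ppi demo/ppi.tsv --expr demo/expression.tsv \
         --labels demo/labels.tsv --seeds demo/seeds.txt --outdir demo/out
```

which prints:

```
Gene prioritization results
============================================================
network: 300 genes, 596 interactions
seeds used: 5 (dropped: 0); neighborhood size |N|: 24
pairs per condition: 140 (unreachable skipped: 0)
selected paths: control 152, disease 159
power-law envelope: f(x) = 0.2485 * x^(-0.02434) [8 windows]
scored genes: 48 (11 with x > 5)

top genes by |delta_prime| (sign: + disease-, - control-dominant):
  G0083        x=   8.880  delta= +0.446  delta_prime=  +1.892
  G0088        x=   6.210  delta= +0.299  delta_prime=  +1.257
```

Both reported genes are members of the planted module (`demo/truth.json`
holds the ground truth): they sit on many seed paths (X ≈ 6–9), and their
path concordance is much higher in disease than control (Δ ≈ +0.3–0.45),
which is exactly the signature the method targets. `demo/out/` contains
`scores.tsv` (σ_C, σ_D, X, Δ, Δ′, ranks per gene), per-condition path dumps,
the envelope fit report and a run manifest.

The same pipeline runs from Python:

```python
from neri import NERIModel, evaluate

model, truth = NERIModel.from_synthetic(rng_seed=42)
results = model.fit()
print(results.summary())
print(evaluate(truth, results, k=20))
```

`neri compare --ranking a.txt --ranking b.txt --universe-size N` computes
multi-list overlap statistics against the random expectation and top-N
intersection/Spearman agreement curves for externally produced rankings.

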