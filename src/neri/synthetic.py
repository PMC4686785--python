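"""Synthetic benchmark generator with planted ground truth.

Emulates the statistical structure the prioritization method assumes: a sparse
scale-free PPI-like network; a handful of seed genes; a planted module in the
seed neighborhood whose genes are strongly co-expressed with the seeds in the
disease condition only; and high-degree decoy hubs co-expressed with the seeds
equally in BOTH conditions (an ascertainment-bias stand-in: they should score
high on intensity X but low on the differential score Δ′).

Expression follows a single-factor model per condition: a gene that "follows"
the condition's latent factor F takes the value ρ·F + sqrt(1−ρ²)·η with η
standard normal, so two follower genes have expected correlation ρ²; all other
values are independent standard normal noise.  A shared monotone factor is
exactly the structure the inversion-maximized concordance W_max rewards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netio import CONTROL, DISEASE, EdgeList, ExpressionMatrix, _edge_key

logger = logging.getLogger("neri")

# benchmark conditions: generator defaults used by the end-to-end recovery suite
DEFAULTS = dict(
    n_genes=300,
    attachment=2,
    n_seeds=5,
    module_size=20,
    n_decoys=10,
    rho=0.9,
    n_samples=30,
)


@dataclass
class SyntheticTruth:
    """Ground-truth labels and the generator parameters that produced them."""

    seeds: list[str]
    planted: list[str]  # differentially co-expressed with seeds (disease only)
    decoy_hubs: list[str]  # co-expressed with seeds equally in both conditions
    background: list[str]
    params: dict = field(default_factory=dict)


def generate_network(n_genes: int, attachment: int, rng_seed: int) -> EdgeList:
    """Connected preferential-attachment (Barabási–Albert) graph with nodes
    relabeled G0001…; deterministic under ``rng_seed``."""
    if not n_genes > attachment >= 1:
        raise ValueError(f"need n_genes > attachment >= 1, got {n_genes}, {attachment}")
    g = nx.barabasi_albert_graph(n_genes, attachment, seed=int(rng_seed))
    name = {i: f"G{i + 1:04d}" for i in g.nodes}
    edges = {_edge_key(name[a], name[b]) for a, b in g.edges}
    return EdgeList(edges=edges, source_name=f"synthetic_ba_{rng_seed}")


def _plant_module(
    graph: nx.Graph,
    seeds: list[str],
    module_size: int,
    decoys: list[str],
    rng: np.random.Generator,
) -> list[str]:
    """Grow a connected module anchored at the seeds.

    Disease genes are assumed to form a connected network module around the
    seeds, so the module is grown greedily: at each step the candidate
    adjacent to the most seed/module members joins (random tie-break), and
    every member must lie within 2 hops of some seed.  A connected module puts
    planted genes on each other's seed paths, which is the structure the
    shortest-path scoring is meant to detect.
    """
    sset = set(seeds)
    hop: dict[str, int] = {}
    for s in seeds:
        for g, d in nx.single_source_shortest_path_length(graph, s, cutoff=2).items():
            hop[g] = min(hop.get(g, 99), d)
    module: list[str] = []
    excluded = sset | set(decoys)
    while len(module) < module_size:
        cand = set()
        for u in sset | set(module):
            cand.update(graph.neighbors(u))
        cand -= excluded | set(module)
        cand = [c for c in cand if hop.get(c, 99) <= 2]
        if not cand:
            raise ValueError(
                f"module_size={module_size} exceeds the connected gene supply "
                "within 2 hops of the seeds"
            )
        key = {
            c: (sum(1 for v in graph.neighbors(c) if v in sset or v in module), rng.random())
            for c in cand
        }
        module.append(max(cand, key=lambda c: key[c]))
    return sorted(module)


def choose_seeds(edges: EdgeList, n_seeds: int, n_decoys: int, rng: np.random.Generator) -> list[str]:
    """Sample seeds among nodes of degree ≥ 3, excluding the top-degree nodes
    reserved as decoy hubs, so the seed neighborhood is non-trivial and the
    decoys stay non-seed."""
    graph = edges.to_graph()
    by_degree = sorted(graph.nodes, key=lambda g: (-graph.degree[g], g))
    hubs = set(by_degree[:n_decoys])
    candidates = sorted(g for g in graph.nodes if graph.degree[g] >= 3 and g not in hubs)
    if len(candidates) < n_seeds:
        raise ValueError(f"only {len(candidates)} seed candidates with degree >= 3")
    idx = rng.choice(len(candidates), size=n_seeds, replace=False)
    return sorted(candidates[i] for i in idx)


def generate_expression(
    edges: EdgeList,
    seeds: list[str],
    module_size: int = 20,
    n_decoys: int = 10,
    rho: float = 0.9,
    n_samples: int = 30,
    rng_seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Factor-model expression for both conditions plus ground-truth labels.

    Seeds follow the latent factor in both conditions; the planted genes — a
    connected module grown around the seeds, within 2 hops — follow it in
    disease only; decoy hubs (the ``n_decoys`` highest-degree non-seed nodes)
    follow it in both; everything else is independent noise.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    graph = edges.to_graph()
    missing = [s for s in seeds if s not in graph]
    if missing:
        raise ValueError(f"seeds absent from network: {missing}")
    rng = np.random.default_rng(int(rng_seed))

    by_degree = sorted(graph.nodes, key=lambda g: (-graph.degree[g], g))
    decoys = [g for g in by_degree if g not in seeds][:n_decoys]

    planted = _plant_module(graph, seeds, module_size, decoys, rng)

    genes = sorted(graph.nodes)
    labeled = set(seeds) | set(planted) | set(decoys)
    background = sorted(set(genes) - labeled)

    samples = {
        CONTROL: [f"C{j + 1:03d}" for j in range(n_samples)],
        DISEASE: [f"D{j + 1:03d}" for j in range(n_samples)],
    }
    load = float(np.sqrt(1.0 - rho**2))
    columns: dict[str, np.ndarray] = {}
    blocks = []
    for cond in (CONTROL, DISEASE):
        factor = rng.standard_normal(n_samples)
        noise = rng.standard_normal((len(genes), n_samples))
        follows = np.zeros(len(genes), dtype=bool)
        for i, g in enumerate(genes):
            if g in labeled and (g not in planted or cond == DISEASE):
                follows[i] = True
        vals = noise.copy()
        vals[follows] = rho * factor[None, :] + load * noise[follows]
        blocks.append(pd.DataFrame(vals, index=genes, columns=samples[cond]))
    values = pd.concat(blocks, axis=1)

    cond_of = pd.Series(
        [CONTROL] * n_samples + [DISEASE] * n_samples,
        index=samples[CONTROL] + samples[DISEASE],
    )
    expr = ExpressionMatrix(values=values, condition_of=cond_of)
    expr.validate()
    truth = SyntheticTruth(
        seeds=sorted(seeds),
        planted=planted,
        decoy_hubs=sorted(decoys),
        background=background,
        params=dict(
            n_genes=len(genes), module_size=module_size, n_decoys=n_decoys,
            rho=rho, n_samples=n_samples, rng_seed=int(rng_seed),
        ),
    )
    return expr, truth


def simulate_dataset(
    n_genes: int = DEFAULTS["n_genes"],
    attachment: int = DEFAULTS["attachment"],
    n_seeds: int = DEFAULTS["n_seeds"],
    module_size: int = DEFAULTS["module_size"],
    n_decoys: int = DEFAULTS["n_decoys"],
    rho: float = DEFAULTS["rho"],
    n_samples: int = DEFAULTS["n_samples"],
    rng_seed: int = 0,
) -> tuple[EdgeList, ExpressionMatrix, list[str], SyntheticTruth]:
    """One complete benchmark dataset: network, expression, seeds, truth."""
    edges = generate_network(n_genes, attachment, rng_seed)
    rng = np.random.default_rng(int(rng_seed) + 1)
    seeds = choose_seeds(edges, n_seeds, n_decoys, rng)
    expr, truth = generate_expression(
        edges, seeds, module_size=module_size, n_decoys=n_decoys,
        rho=rho, n_samples=n_samples, rng_seed=int(rng_seed) + 2,
    )
    truth.params.update(n_genes=n_genes, attachment=attachment, n_seeds=n_seeds,
                        rng_seed=int(rng_seed))
    return edges, expr, seeds, truth


def evaluate_recovery(
    ranking: list[str], truth: SyntheticTruth, k: int, universe_size: int | None = None
) -> tuple[float, float]:
    """precision@k of the planted module, and its enrichment over the random
    expectation |planted| / universe."""
    if not truth.planted:
        raise ValueError("truth has no planted genes")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds ranking length {len(ranking)}")
    if universe_size is None:
        universe_size = truth.params.get("n_genes") or (
            len(truth.seeds) + len(truth.planted) + len(truth.decoy_hubs) + len(truth.background)
        )
    hits = len(set(ranking[:k]) & set(truth.planted))
    precision = hits / k
    base = len(truth.planted) / universe_size
    return precision, precision / base
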