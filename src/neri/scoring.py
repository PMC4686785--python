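"""Per-condition relative-importance score σ(g).

Each gene accumulates, over every ordered (seed, target) pair and every
selected shortest path between them that contains the gene, the product of a
distance penalty λ^(−d_sg) (d_sg = unweighted graph distance from the pair's
seed to the gene on the FULL integrated network, so a seed endpoint
contributes with factor 1) and the path's inversion-maximized concordance
W_max.  Seed contributions are additive; no normalization by seed or path
count is applied.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .neighborhood import SeedSet, SelectedPathSet
from .netio import IntegratedNetwork

logger = logging.getLogger("neri")


@dataclass
class Params:
    """Tunable parameters of the prioritization pipeline.

    ``epsilon``, ``w_len``, ``w_step`` and ``x_ini`` default to the values
    used in the reference experiments (0.05, 2, 1, 5).  ``lambda_decay`` (the
    per-hop distance penalty base; larger means steeper decay) has no
    published reference value and defaults to 2, i.e. halving per hop.
    """

    lambda_decay: float = 2.0
    epsilon: float = 0.05
    w_len: float = 2.0
    w_step: float = 1.0
    x_ini: float = 5.0
    max_path_genes: int = 12
    path_cap: int = 10_000
    min_points_per_window: int = 5
    signed_envelope: bool = False
    top_fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_decay <= 1:
            raise ValueError(f"lambda_decay must exceed 1 (got {self.lambda_decay}): "
                             "values <= 1 give no distance decay")
        if not 0 <= self.epsilon < 1:
            raise ValueError(f"epsilon must be in [0, 1), got {self.epsilon}")
        if self.w_len <= 0 or self.w_step <= 0:
            raise ValueError("w_len and w_step must be positive")
        if self.max_path_genes < 2:
            raise ValueError("max_path_genes must be at least 2")
        if self.path_cap < 1:
            raise ValueError("path_cap must be at least 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ConditionScores:
    condition: str
    sigma: dict[str, float] = field(default_factory=dict)
    n_paths: dict[str, int] = field(default_factory=dict)


def sigma(
    pathset: SelectedPathSet,
    net: IntegratedNetwork,
    seeds: SeedSet,
    params: Params,
) -> ConditionScores:
    """σ(g) = Σ_{(s,t)} Σ_{P ∈ P*_st} λ^(−d_sg) · W_max(P) · [g ∈ P].

    Distances are computed once per seed by breadth-first search and cached.
    A gene on no selected path is absent from the result (σ = 0 implicitly).
    """
    lam = params.lambda_decay
    if lam <= 1:
        raise ValueError("lambda_decay must exceed 1")
    dist = {s: nx.single_source_shortest_path_length(net.graph, s) for s in seeds.genes}
    sig: dict[str, float] = defaultdict(float)
    npaths: dict[str, int] = defaultdict(int)
    for (s, _t), plist in pathset.paths.items():
        ds = dist[s]
        for p in plist:
            for g in p.nodes:
                sig[g] += lam ** (-ds[g]) * p.w_max
                npaths[g] += 1
    return ConditionScores(condition=pathset.condition, sigma=dict(sig), n_paths=dict(npaths))
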