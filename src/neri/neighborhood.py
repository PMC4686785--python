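"""Seed neighborhood growth and concordance-based shortest-path selection.

Following the local hypothesis, the seed set S is grown to include its direct
neighbors N.  Following network parsimony, every ordered pair (s in S,
t in S∪N, s != t) is connected by ALL of its shortest paths; among those
candidates, the ones whose gene expression is most concordant survive, with an
ε tolerance treating near-best paths as tied with the best.  Selection runs
independently per condition — the candidate paths are the same (the graph does
not change), but their concordance values, and hence the surviving sets, may
differ between control and disease.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import networkx as nx

from .concordance import w_max
from .netio import CONDITIONS, IntegratedNetwork

logger = logging.getLogger("neri")


@dataclass
class SeedSet:
    genes: list[str]  # seeds present in the network, sorted
    dropped: list[str]  # input symbols absent from the network


@dataclass(frozen=True)
class Path:
    """One surviving shortest path with its concordance value in one condition."""

    nodes: tuple[str, ...]
    w_max: float
    condition: str


@dataclass
class SelectedPathSet:
    """Per ordered (seed, target) pair, the ε-tied best shortest paths, one condition."""

    condition: str
    paths: dict[tuple[str, str], list[Path]] = field(default_factory=dict)
    skipped_pairs: int = 0
    truncated_pairs: int = 0

    def n_pairs(self) -> int:
        return len(self.paths)

    def n_paths(self) -> int:
        return sum(len(v) for v in self.paths.values())


def grow_seeds(net: IntegratedNetwork, seeds: Sequence[str]) -> tuple[SeedSet, set[str]]:
    """Filter seeds to the network and collect their direct neighbors N (seeds excluded)."""
    present = sorted({s for s in seeds if s in net.graph})
    dropped = sorted({s for s in seeds if s not in net.graph})
    if dropped:
        logger.warning("grow_seeds: %d seed(s) absent from the network: %s", len(dropped), dropped)
    if not present:
        raise ValueError("none of the seed genes is present in the integrated network")
    sset = set(present)
    n = set()
    for s in present:
        n.update(net.graph.neighbors(s))
    n -= sset
    return SeedSet(genes=present, dropped=dropped), n


def _lex_shortest_paths(
    graph: nx.Graph, s: str, t: str, dist_s: dict, dist_t: dict
) -> Iterator[list[str]]:
    """DFS over the BFS shortest-path DAG, visiting neighbors in sorted order,
    which yields paths in lexicographic order of their node sequences."""
    d = dist_s[t]
    stack: list[tuple[str, list[str]]] = [(s, [s])]
    # iterative DFS with an explicit child iterator per frame
    frame_iters: list[Iterator[str]] = []
    path = [s]

    def children(u: str):
        du = dist_s[u]
        for v in sorted(graph.neighbors(u)):
            if dist_s.get(v, -1) == du + 1 and du + 1 + dist_t.get(v, d + 1) == d:
                yield v

    frame_iters.append(children(s))
    while frame_iters:
        u = path[-1]
        if u == t:
            yield list(path)
            path.pop()
            frame_iters.pop()
            continue
        try:
            v = next(frame_iters[-1])
        except StopIteration:
            path.pop()
            frame_iters.pop()
            continue
        path.append(v)
        frame_iters.append(children(v))


def all_shortest_paths(
    net: IntegratedNetwork | nx.Graph,
    s: str,
    t: str,
    cap: int = 10_000,
    dist_s: dict | None = None,
    dist_t: dict | None = None,
) -> list[list[str]]:
    """All shortest s-t paths in deterministic lexicographic order.

    Enumerated over the breadth-first shortest-path DAG: a node u lies on some
    shortest s-t path iff d(s,u) + d(u,t) = d(s,t).  Returns [] when t is
    unreachable.  If more than ``cap`` shortest paths exist, the
    lexicographically first ``cap`` are kept and the truncation is logged.
    """
    graph = net.graph if isinstance(net, IntegratedNetwork) else net
    if s == t:
        raise ValueError("endpoints must differ")
    if s not in graph or t not in graph:
        raise ValueError(f"endpoint not in network: {s if s not in graph else t}")
    if dist_s is None:
        dist_s = nx.single_source_shortest_path_length(graph, s)
    if t not in dist_s:
        return []
    if dist_t is None:
        dist_t = nx.single_source_shortest_path_length(graph, t)
    out = list(itertools.islice(_lex_shortest_paths(graph, s, t, dist_s, dist_t), cap + 1))
    if len(out) > cap:
        logger.warning("all_shortest_paths(%s, %s): >%d shortest paths, truncated", s, t, cap)
        return out[:cap]
    return out


def tie_threshold(w_best: float, epsilon: float) -> float:
    """Inclusion threshold of the ε tie rule: paths with concordance at least
    (1 - ε) times the pair's best value are considered tied with the best."""
    if not 0 <= epsilon < 1:
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    return w_best * (1.0 - epsilon)


def select_paths(
    paths: Sequence[Sequence[str]],
    net: IntegratedNetwork,
    condition: str,
    epsilon: float,
    max_path_genes: int = 12,
    _wmax_cache: dict | None = None,
) -> list[Path]:
    """Score candidate shortest paths by inversion-maximized concordance over
    one condition's samples and keep all within the ε tie band of the best."""
    if not paths:
        raise ValueError("select_paths requires a nonempty candidate list")
    scored: list[Path] = []
    for p in paths:
        nodes = tuple(p)
        key = (condition, tuple(sorted(nodes)))  # W is row-order invariant
        if _wmax_cache is not None and key in _wmax_cache:
            w = _wmax_cache[key]
        else:
            w = w_max(net.profiles(nodes, condition), max_path_genes=max_path_genes).w_max
            if _wmax_cache is not None:
                _wmax_cache[key] = w
        scored.append(Path(nodes=nodes, w_max=w, condition=condition))
    thr = tie_threshold(max(p.w_max for p in scored), epsilon)
    return [p for p in scored if p.w_max >= thr]


def build_pathsets(
    net: IntegratedNetwork,
    seed_set: SeedSet,
    neighbors: set[str],
    epsilon: float = 0.05,
    cap: int = 10_000,
    max_path_genes: int = 12,
) -> dict[str, SelectedPathSet]:
    """Enumerate ordered (seed, target) pairs over S x (S∪N), select paths in
    each condition, and return one :class:`SelectedPathSet` per condition.

    Candidate shortest paths depend only on the graph and are computed once
    per unordered pair (the opposite orientation reuses the reversed paths);
    concordance values are cached per (condition, gene set).
    """
    targets = sorted(set(seed_set.genes) | neighbors)
    dist: dict[str, dict] = {}

    def distances(u: str) -> dict:
        if u not in dist:
            dist[u] = nx.single_source_shortest_path_length(net.graph, u)
        return dist[u]

    result = {c: SelectedPathSet(condition=c) for c in CONDITIONS}
    wmax_cache: dict = {}
    candidate_cache: dict[tuple[str, str], list[list[str]]] = {}

    for s in seed_set.genes:
        for t in targets:
            if s == t:
                continue
            key = (s, t) if s <= t else (t, s)
            if key in candidate_cache:
                cands = [list(reversed(p)) for p in candidate_cache[key]] if key != (s, t) else candidate_cache[key]
            else:
                cands = all_shortest_paths(net, s, t, cap=cap, dist_s=distances(s), dist_t=distances(t))
                candidate_cache[key] = cands if key == (s, t) else [list(reversed(p)) for p in cands]
            if not cands:
                for c in CONDITIONS:
                    result[c].skipped_pairs += 1
                continue
            if len(cands) >= cap:
                for c in CONDITIONS:
                    result[c].truncated_pairs += 1
            for c in CONDITIONS:
                result[c].paths[(s, t)] = select_paths(
                    cands, net, c, epsilon, max_path_genes=max_path_genes, _wmax_cache=wmax_cache
                )
    for c in CONDITIONS:
        logger.info(
            "%s: %d pairs, %d selected paths (%d unreachable pairs skipped)",
            c, result[c].n_pairs(), result[c].n_paths(), result[c].skipped_pairs,
        )
    return result


def pathset_frame(pathset: SelectedPathSet):
    """Tabular dump of a SelectedPathSet: s, t, condition, dash-joined path, w_max."""
    import pandas as pd

    rows = [
        {"s": s, "t": t, "condition": pathset.condition,
         "path": "-".join(p.nodes), "w_max": p.w_max}
        for (s, t), plist in sorted(pathset.paths.items())
        for p in plist
    ]
    return pd.DataFrame(rows, columns=["s", "t", "condition", "path", "w_max"])
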