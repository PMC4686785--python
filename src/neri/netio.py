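"""Reading, merging and integrating PPI edge lists with expression data.

The analysis operates on an :class:`IntegratedNetwork`: the undirected
protein-protein interaction (PPI) graph restricted to genes that also carry
expression measurements in both conditions, further restricted to its main
connected component.  Gene identity is the upper-cased HGNC-style symbol;
no alias resolution is attempted beyond case/whitespace normalization —
callers provide an explicit transcript-to-gene mapping table when the
expression matrix is probe- or transcript-level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("neri")

CONTROL = "control"
DISEASE = "disease"
CONDITIONS = (CONTROL, DISEASE)

Edge = tuple[str, str]


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def _edge_key(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeList:
    """Set of undirected gene-symbol pairs from one or more PPI sources.

    ``edges`` stores each unordered pair once as a sorted tuple; ``sources``
    records which input files contained each edge (union provenance).
    """

    edges: set[Edge]
    source_name: str = ""
    sources: dict[Edge, set[str]] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.sources:
            self.sources = {e: {self.source_name} for e in self.edges}

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


def _psimi_symbol(column: str) -> str | None:
    """Extract a gene symbol from a PSI-MI TAB alias column.

    Alias fields are pipe-separated ``db:value(description)`` items; the item
    described as ``gene name`` wins, otherwise the first parseable value.
    """
    if column in ("-", ""):
        return None
    fallback: str | None = None
    for item in column.split("|"):
        desc = None
        core = item
        if "(" in item and item.endswith(")"):
            idx = item.index("(")
            core, desc = item[:idx], item[idx + 1 : -1]
        value = core.split(":", 1)[-1].strip().strip('"')
        if not value:
            continue
        if desc == "gene name":
            return value
        if fallback is None:
            fallback = value
    return fallback


def read_edge_list(path: str | Path, dialect: str = "two_column_tsv") -> EdgeList:
    """Read a PPI edge list.

    Parameters
    ----------
    path:
        TSV file.  ``two_column_tsv``: two symbol columns, headerless or with
        a ``geneA<TAB>geneB`` header.  ``psi_mi_tab``: PSI-MI TAB 2.5, from
        which the two interactor alias columns (5 and 6) are reduced to gene
        symbols.
    dialect:
        ``two_column_tsv`` (default) or ``psi_mi_tab``.

    Symbols are upper-cased and trimmed; self-pairs are dropped and duplicate
    pairs (either orientation) collapsed, with the dropped-row count logged
    and stored on the result.
    """
    path = Path(path)
    if dialect not in ("two_column_tsv", "psi_mi_tab"):
        raise ValueError(f"unknown edge-list dialect: {dialect!r}")
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise OSError(f"cannot read edge list {path}: {exc}") from exc

    edges: set[Edge] = set()
    n_rows = 0
    for i, line in enumerate(lines):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if dialect == "two_column_tsv":
            if len(cols) < 2:
                n_rows += 1
                continue
            a, b = _norm(cols[0]), _norm(cols[1])
            if i == 0 and (a, b) == ("GENEA", "GENEB"):
                continue  # header row
        else:
            if len(cols) < 6:
                n_rows += 1
                continue
            sa, sb = _psimi_symbol(cols[4]), _psimi_symbol(cols[5])
            if sa is None or sb is None:
                n_rows += 1
                continue
            a, b = _norm(sa), _norm(sb)
        n_rows += 1
        if not a or not b or a == b:
            continue
        edges.add(_edge_key(a, b))

    if not edges:
        raise ValueError(f"zero valid rows in edge list {path}")
    dropped = n_rows - len(edges)
    if dropped:
        logger.info("%s: %d rows dropped (self-pairs/duplicates/unparseable)", path.name, dropped)
    return EdgeList(edges=edges, source_name=path.name, n_dropped=dropped)


def merge_edge_lists(lists: Sequence[EdgeList]) -> EdgeList:
    """Set-union of edge lists, keeping per-edge source provenance."""
    if not lists:
        raise ValueError("merge_edge_lists requires at least one edge list")
    edges: set[Edge] = set()
    sources: dict[Edge, set[str]] = {}
    for el in lists:
        for e in el.edges:
            edges.add(e)
            sources.setdefault(e, set()).update(el.sources.get(e, {el.source_name}))
    name = "+".join(el.source_name for el in lists)
    return EdgeList(edges=edges, source_name=name, sources=sources)


@dataclass
class ExpressionMatrix:
    """Expression values (rows = transcripts or genes, columns = samples)
    with a sample-to-condition assignment."""

    values: pd.DataFrame
    condition_of: pd.Series  # sample id -> "control" | "disease"

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        unlabeled = [s for s in self.values.columns if s not in self.condition_of.index]
        if unlabeled:
            raise ValueError(f"samples without condition label: {unlabeled[:5]}")
        bad = set(self.condition_of) - set(CONDITIONS)
        if bad:
            raise ValueError(f"condition labels must be in {CONDITIONS}, got {sorted(bad)}")
        for cond in CONDITIONS:
            if len(self.samples(cond)) < 3:
                raise ValueError(f"need at least 3 samples per condition, {cond} has {len(self.samples(cond))}")

    def samples(self, condition: str) -> list[str]:
        labels = self.condition_of.reindex(self.values.columns)
        return [s for s, c in labels.items() if c == condition]


def read_expression(values_path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (first column row id, header = sample ids)
    plus a two-column sample/condition label TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = [_norm(str(r)) for r in values.index]
    values.columns = [str(c).strip() for c in values.columns]

    raw = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError(f"label file {labels_path} must have two columns")
    if raw.iloc[0, 1].strip().lower() not in CONDITIONS:
        raw = raw.iloc[1:]  # header row
    cond = pd.Series(
        [c.strip().lower() for c in raw.iloc[:, 1]],
        index=[s.strip() for s in raw.iloc[:, 0]],
    )
    em = ExpressionMatrix(values=values, condition_of=cond)
    em.validate()
    return em


def read_seed_list(path: str | Path) -> list[str]:
    """One symbol per line; normalized, de-duplicated, order-preserving."""
    seen: list[str] = []
    for line in Path(path).read_text().splitlines():
        s = _norm(line)
        if s and not s.startswith("#") and s not in seen:
            seen.append(s)
    if not seen:
        raise ValueError(f"no seed symbols in {path}")
    return seen


def aggregate_transcripts(expr: ExpressionMatrix, mapping: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse transcript-level rows to gene level by the per-sample median.

    Rows absent from ``mapping`` are dropped (logged).  The same rule also
    collapses duplicate gene rows produced by the mapping.
    """
    if not mapping:
        raise ValueError("empty transcript-to-gene mapping")
    norm_map = {_norm(k): _norm(v) for k, v in mapping.items()}
    keep = [r for r in expr.values.index if r in norm_map]
    n_drop = len(expr.values.index) - len(keep)
    if n_drop:
        logger.info("aggregate_transcripts: %d unmapped rows dropped", n_drop)
    if not keep:
        raise ValueError("no expression rows survive the transcript mapping")
    sub = expr.values.loc[keep]
    genes = [norm_map[r] for r in keep]
    agg = sub.groupby(pd.Index(genes, name="gene")).median()
    return ExpressionMatrix(values=agg, condition_of=expr.condition_of)


@dataclass
class IntegratedNetwork:
    """PPI graph restricted to expression-covered genes and to the main
    connected component, with per-condition expression for every gene."""

    graph: nx.Graph
    expression: dict[str, pd.DataFrame]  # condition -> genes x samples

    @property
    def genes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def profiles(self, genes: Sequence[str], condition: str):
        """m x n array of expression for ``genes`` over one condition's samples."""
        return self.expression[condition].loc[list(genes)].to_numpy(dtype=float)

    def swap_conditions(self) -> "IntegratedNetwork":
        """Relabel control as disease and vice versa (for antisymmetry checks)."""
        return IntegratedNetwork(
            graph=self.graph,
            expression={CONTROL: self.expression[DISEASE], DISEASE: self.expression[CONTROL]},
        )


def integrate(edges: EdgeList, expr: ExpressionMatrix) -> IntegratedNetwork:
    """Intersect network and expression gene sets, then keep the largest
    connected component (ties broken by smallest lexicographic member).

    Duplicate gene rows in the expression matrix are collapsed by median,
    the same rule used for transcript aggregation.
    """
    values = expr.values
    if values.index.has_duplicates:
        logger.info("integrate: collapsing duplicate gene rows by median")
        values = values.groupby(level=0).median()

    common = set(values.index) & edges.nodes()
    if not common:
        raise ValueError("no genes shared between the PPI network and the expression matrix")

    g = nx.Graph()
    for a, b in edges.edges:
        if a in common and b in common:
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise ValueError("no PPI edge survives the expression intersection")

    comps = list(nx.connected_components(g))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    if len(comps) > 1:
        logger.info("integrate: kept component of %d genes out of %d components", len(best), len(comps))
    if len(best) < 3:
        raise ValueError(f"main connected component has only {len(best)} genes (< 3)")
    lcc = g.subgraph(best).copy()

    genes = sorted(lcc.nodes)
    expression = {
        cond: values.loc[genes, expr.samples(cond)] for cond in CONDITIONS
    }
    logger.info(
        "integrated network: %d genes, %d interactions", lcc.number_of_nodes(), lcc.number_of_edges()
    )
    return IntegratedNetwork(graph=lcc, expression=expression)


# --- writers (round-trip with the readers above; used by the synthetic module) ---

def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\n")
        for a, b in sorted(edges.edges):
            fh.write(f"{a}\t{b}\n")


def write_expression(expr: ExpressionMatrix, values_path: str | Path, labels_path: str | Path) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format="%.10g")
    with open(labels_path, "w") as fh:
        for s in expr.values.columns:
            fh.write(f"{s}\t{expr.condition_of[s]}\n")


def write_seed_list(seeds: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in seeds))
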