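"""Kendall's coefficient of concordance W and its inversion-maximized variant.

A shortest path's biological value is judged by how concordantly its genes
are expressed across one condition's samples.  Plain Kendall's W treats an
anti-correlated gene (down-regulated where its partners are up-regulated) as
discordant, yet such a gene is co-regulated in the sense that matters here.
``w_max`` therefore maximizes W over all per-gene profile inversions, making
the score insensitive to regulation direction.

Genes are the "judges" (rows) and samples the "objects" (columns).  Ties in
expression values are handled with mid-ranks and the standard tie-correction
term; under mid-ranks, negating a profile mirrors its ranks exactly, so
inversion-by-negation and inversion-by-rank-reversal coincide.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger("neri")


def average_ranks(values) -> np.ndarray:
    """Ascending mid-ranks (smallest value gets rank 1; ties share the mean rank)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to rank")
    if np.all(values == values[0]):
        logger.debug("average_ranks: constant vector, all ranks (n+1)/2")
    return rankdata(values)


def kendall_w(ranks) -> float:
    """Kendall's W from an m x n mid-rank matrix, with tie correction.

    W = 12 S / (m^2 (n^3 - n) - m T), where S is the sum of squared column-sum
    deviations from m(n+1)/2 and T = sum over rows of sum(t^3 - t) across tie
    groups of size t.  Degenerate matrices (every row fully tied) yield 0.
    """
    R = np.asarray(ranks, dtype=float)
    if R.ndim != 2:
        raise ValueError("rank matrix must be 2-dimensional")
    m, n = R.shape
    if m < 2 or n < 2:
        raise ValueError(f"need m >= 2 genes and n >= 2 samples, got {m} x {n}")
    S = float(np.sum((R.sum(axis=0) - m * (n + 1) / 2.0) ** 2))
    T = 0.0
    for row in R:
        _, counts = np.unique(row, return_counts=True)
        T += float(np.sum(counts.astype(float) ** 3 - counts))
    denom = m * m * (n**3 - n) - m * T
    if denom <= 0:
        logger.warning("kendall_w: fully tied rank matrix, W defined as 0")
        return 0.0
    return float(np.clip(12.0 * S / denom, 0.0, 1.0))


@dataclass(frozen=True)
class ConcordanceResult:
    """W without inversions, the inversion-maximized W, and the sign vector
    (+1 keep / -1 invert per gene, first gene fixed to +1) achieving it."""

    w: float
    w_max: float
    signs: tuple[int, ...]


def w_max(profiles, max_path_genes: int = 12) -> ConcordanceResult:
    """Maximize Kendall's W over all 2^(m-1) per-gene profile inversions.

    The first gene's sign is fixed to +1: inverting every profile mirrors all
    ranks simultaneously and leaves W unchanged, so each equivalence class of
    assignments is enumerated once.  Exact enumeration is cheap because the
    paths scored here are short (m rarely exceeds 6); ``max_path_genes``
    guards against pathological inputs.  Ties in the maximum are broken by the
    lexicographically smallest sign vector (-1 sorts before +1).
    """
    E = np.asarray(profiles, dtype=float)
    if E.ndim != 2:
        raise ValueError("profiles must be an m x n matrix")
    m, n = E.shape
    if m < 2:
        raise ValueError("w_max needs at least 2 profiles")
    if n < 2:
        raise ValueError("w_max needs at least 2 samples")
    if m > max_path_genes:
        raise ValueError(
            f"{m} genes on one path exceeds max_path_genes={max_path_genes}; "
            "raise the cap if this is intentional"
        )

    pos = np.vstack([rankdata(row) for row in E])
    neg = np.vstack([rankdata(-row) for row in E])
    w_plain = kendall_w(pos)

    best_key: tuple | None = None
    best_w = -1.0
    best_signs: tuple[int, ...] = ()
    rows = np.empty_like(pos)
    for tail in itertools.product((1, -1), repeat=m - 1):
        signs = (1,) + tail
        for i, s in enumerate(signs):
            rows[i] = pos[i] if s == 1 else neg[i]
        w = kendall_w(rows)
        key = (-w, signs)
        if best_key is None or key < best_key:
            best_key, best_w, best_signs = key, w, signs
    return ConcordanceResult(w=w_plain, w_max=best_w, signs=best_signs)
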