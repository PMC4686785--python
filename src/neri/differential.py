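"""Differential alteration scoring, MA-style power-law normalization, ranking,
and ranking-comparison utilities.

The two per-condition scores are combined MA-plot style: the intensity
X(g) = σ_C(g) + σ_D(g) plays the role of A and the relative alteration
Δ(g) = (σ_D − σ_C)/X the role of M.  Because high-X genes show systematically
smaller |Δ| (the same intensity-dependence seen in fold-change analysis), Δ is
normalized by a power-law envelope f(x) = a·x^(−k) fitted by ordinary least
squares in log-log space to the sliding-window third quartiles of |Δ|,
yielding Δ′(g) = Δ(g)/f(X(g)).  Genes are ranked by |Δ′| (sign retained:
positive = disease-dominant coexpression, negative = control-dominant).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .scoring import ConditionScores

logger = logging.getLogger("neri")

SCORE_COLUMNS = [
    "sigma_control", "sigma_disease", "x", "delta", "delta_prime",
    "rank_abs_delta_prime", "rank_x", "n_paths_control", "n_paths_disease", "filtered",
]


@dataclass
class WindowSpec:
    """Sliding-window layout on the X axis: windows [x_ini + i·w_step,
    x_ini + i·w_step + w_len) for i = 0, 1, … while the start does not exceed
    max(x).  Windows with fewer than ``min_points_per_window`` genes are
    skipped."""

    w_len: float = 2.0
    w_step: float = 1.0
    x_ini: float = 5.0
    min_points_per_window: int = 5

    def __post_init__(self) -> None:
        if self.w_len <= 0 or self.w_step <= 0:
            raise ValueError("w_len and w_step must be positive")


@dataclass
class PowerLawFit:
    """f(x) = a·x^(−k), with the (window center, Q3) points it was fitted to."""

    a: float
    k: float
    window_points: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        f = self.a * x ** (-self.k)
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValueError("power-law envelope is non-positive or non-finite on the data")
        return f


def compute_xdelta(
    sc: ConditionScores, sd: ConditionScores, x_ini: float = 5.0
) -> pd.DataFrame:
    """Build the score table with x = σ_C + σ_D and Δ = (σ_D − σ_C)/x.

    The gene universe is the union of genes scored in either condition, with
    a missing σ treated as 0.  Genes with x = 0 are dropped (logged); genes
    with x ≤ x_ini are flagged ``filtered`` (only genes with intensity
    strictly larger than x_ini take part in the envelope fit and ranking).
    """
    genes = sorted(set(sc.sigma) | set(sd.sigma))
    sig_c = np.array([sc.sigma.get(g, 0.0) for g in genes])
    sig_d = np.array([sd.sigma.get(g, 0.0) for g in genes])
    x = sig_c + sig_d
    keep = x > 0
    if (~keep).any():
        logger.info("compute_xdelta: dropped %d genes with x = 0", int((~keep).sum()))
    table = pd.DataFrame(
        {
            "sigma_control": sig_c[keep],
            "sigma_disease": sig_d[keep],
            "x": x[keep],
            "n_paths_control": [sc.n_paths.get(g, 0) for g, k in zip(genes, keep) if k],
            "n_paths_disease": [sd.n_paths.get(g, 0) for g, k in zip(genes, keep) if k],
        },
        index=pd.Index([g for g, k in zip(genes, keep) if k], name="gene"),
    )
    table["delta"] = (table["sigma_disease"] - table["sigma_control"]) / table["x"]
    table["filtered"] = table["x"] <= x_ini
    return table


def _quantile_windows(x: np.ndarray, d: np.ndarray, n_bins: int = 8, min_pts: int = 3):
    """Equal-count windows: sort by x, split into up to ``n_bins`` runs of at
    least ``min_pts`` genes; center = median x, height = Q3 of the window."""
    order = np.argsort(x)
    x, d = x[order], d[order]
    parts = np.array_split(np.arange(len(x)), min(n_bins, max(2, len(x) // min_pts)))
    centers, q3s = [], []
    for idx in parts:
        if len(idx) < min_pts:
            continue
        c = float(np.median(x[idx]))
        q3 = float(np.percentile(d[idx], 75))
        if c > 0 and q3 > 0:
            centers.append(c)
            q3s.append(q3)
    return centers, q3s


def fit_powerlaw(table: pd.DataFrame, spec: WindowSpec, signed: bool = False) -> PowerLawFit:
    """Fit the intensity-dependent envelope f(x) = a·x^(−k).

    In each qualifying window the third quartile (linear-interpolation
    convention) of |Δ| — or of signed Δ when ``signed`` — is paired with the
    window midpoint; log(q3) is regressed on log(center) by OLS.  Windows
    whose Q3 is not positive are dropped from the fit (logged).

    Fixed-width windows presume a densely populated intensity axis.  When
    fewer than two of them qualify (small networks or few seeds leave the
    x > x_ini stratum too thin), the fit falls back to equal-count windows
    over all scored genes, so the envelope is estimated across the whole
    intensity range it will be evaluated on; the fallback is logged and
    visible in ``window_points``.
    """
    pts = table.loc[~table["filtered"]]
    if pts.empty:
        raise ValueError("no unfiltered genes available for the power-law fit")
    x = pts["x"].to_numpy()
    d = pts["delta"].to_numpy() if signed else np.abs(pts["delta"].to_numpy())
    xmax = float(x.max())

    centers: list[float] = []
    q3s: list[float] = []
    i = 0
    while True:
        start = spec.x_ini + i * spec.w_step
        if start > xmax:
            break
        mask = (x >= start) & (x < start + spec.w_len)
        if int(mask.sum()) >= spec.min_points_per_window:
            q3 = float(np.percentile(d[mask], 75))
            if q3 > 0:
                centers.append(start + spec.w_len / 2.0)
                q3s.append(q3)
            else:
                logger.info("fit_powerlaw: window at %.3g dropped (Q3 = 0)", start)
        i += 1

    if len(centers) < 2:
        logger.warning(
            "fit_powerlaw: only %d qualifying fixed-width window(s); "
            "falling back to equal-count windows over all scored genes",
            len(centers),
        )
        xa = table["x"].to_numpy()
        da = table["delta"].to_numpy() if signed else np.abs(table["delta"].to_numpy())
        centers, q3s = _quantile_windows(xa, da)
    if len(centers) < 2:
        raise ValueError(
            f"only {len(centers)} usable window(s) for the power-law fit; "
            "shrink w_len/x_ini or lower min_points_per_window"
        )
    slope, intercept = np.polyfit(np.log(centers), np.log(q3s), 1)
    fit = PowerLawFit(a=float(np.exp(intercept)), k=float(-slope),
                      window_points=list(zip(centers, q3s)))
    logger.info("power-law envelope: a=%.4g, k=%.4g from %d windows", fit.a, fit.k, len(centers))
    return fit


def compute_delta_prime(table: pd.DataFrame, fit: PowerLawFit) -> pd.DataFrame:
    """Δ′(g) = Δ(g)/f(X(g)) for unfiltered genes (NaN for filtered ones),
    plus descending ranks by |Δ′| and by x over the unfiltered universe."""
    table = table.copy()
    table["delta_prime"] = np.nan
    un = ~table["filtered"]
    table.loc[un, "delta_prime"] = (
        table.loc[un, "delta"].to_numpy() / fit.predict(table.loc[un, "x"].to_numpy())
    )
    table["rank_abs_delta_prime"] = np.nan
    table["rank_x"] = np.nan
    sub = table.loc[un]
    by_dp = sorted(sub.index, key=lambda g: (-abs(sub.at[g, "delta_prime"]), g))
    by_x = sorted(sub.index, key=lambda g: (-sub.at[g, "x"], g))
    table.loc[by_dp, "rank_abs_delta_prime"] = np.arange(1, len(by_dp) + 1)
    table.loc[by_x, "rank_x"] = np.arange(1, len(by_x) + 1)
    return table[[c for c in SCORE_COLUMNS if c in table.columns]]


def rank_and_select(
    table: pd.DataFrame, by: str = "abs_delta_prime", top_fraction: float = 0.1
) -> list[str]:
    """Top ceil(fraction · unfiltered count) genes, descending by |Δ′| or x,
    ties broken by gene symbol for run-to-run determinism."""
    if by not in ("abs_delta_prime", "x"):
        raise ValueError(f"unknown ranking key {by!r}")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    sub = table.loc[~table["filtered"]]
    if sub.empty:
        raise ValueError("no unfiltered genes to rank")
    if by == "abs_delta_prime":
        order = sorted(sub.index, key=lambda g: (-abs(sub.at[g, "delta_prime"]), g))
    else:
        order = sorted(sub.index, key=lambda g: (-sub.at[g, "x"], g))
    n = math.ceil(top_fraction * len(sub))
    return order[:n]


@dataclass
class OverlapStats:
    """Observed multi-list intersection vs the random expectation."""

    intersection: list[str]
    observed_proportion: float  # |∩| / mean list size
    expected_count: float  # universe · Π(size_i / universe)
    expected_proportion: float  # Π(size_i / universe)


def overlap_stats(lists: list[list[str]], universe_size: int) -> OverlapStats:
    """Replication statistics for ≥2 ranked gene lists over a common universe.

    The random expectation assumes each list is a uniform draw of its own size
    from the universe, so the expected intersection proportion is the product
    of the lists' coverage fractions.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 lists")
    sizes = [len(l) for l in lists]
    if min(sizes) == 0:
        raise ValueError("lists must be nonempty")
    if universe_size < max(sizes):
        raise ValueError("universe smaller than one of the lists")
    inter = set(lists[0])
    for l in lists[1:]:
        inter &= set(l)
    mean_size = sum(sizes) / len(sizes)
    exp_prop = float(np.prod([s / universe_size for s in sizes]))
    return OverlapStats(
        intersection=sorted(inter),
        observed_proportion=len(inter) / mean_size,
        expected_count=universe_size * exp_prop,
        expected_proportion=exp_prop,
    )


def rank_agreement(
    rank_a: list[str], rank_b: list[str], n_grid: list[int], min_overlap: int = 3
) -> pd.DataFrame:
    """Top-N intersection proportion and Spearman correlation curves.

    For each N: the proportion is |top-N(a) ∩ top-N(b)| / N; the correlation
    is Spearman's ρ between the two within-list positions of the intersection
    genes, reported as NaN when the intersection has fewer than
    ``min_overlap`` genes (tiny intersections make ρ meaningless).
    """
    pos_a = {g: i for i, g in enumerate(rank_a)}
    pos_b = {g: i for i, g in enumerate(rank_b)}
    rows = []
    for n in n_grid:
        if n > len(rank_a) or n > len(rank_b):
            raise ValueError(f"N={n} exceeds a ranking length")
        top_a, top_b = set(rank_a[:n]), set(rank_b[:n])
        inter = sorted(top_a & top_b)
        rho = np.nan
        if len(inter) >= max(min_overlap, 2):
            ra = [pos_a[g] for g in inter]
            rb = [pos_b[g] for g in inter]
            rho = float(spearmanr(ra, rb).statistic)
        rows.append({"n": n, "proportion": len(inter) / n, "spearman": rho})
    return pd.DataFrame(rows, columns=["n", "proportion", "spearman"])
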