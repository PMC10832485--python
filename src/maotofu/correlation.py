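"""Taxa-metabolite correlation heatmaps and co-occurrence networks.

Associations between bacterial taxa and flavor metabolites (amino acids,
volatiles) are measured by Spearman rank correlation (Pearson available
by flag). Two-sided p-values use the exact permutation distribution for
n <= 8 paired samples and the t approximation otherwise. Significance
stars follow the conventional thresholds *** p < 0.001, ** p < 0.01,
* p < 0.05 on raw p-values; Benjamini-Hochberg adjustment is available
but off by default.

Co-occurrence networks connect taxa whose pairwise correlation passes
both an effect-size and a significance threshold (defaults |rho| >= 0.6,
p < 0.05 — invented, configurable). Relative abundances are
compositional; correlations on them can be spurious (the closure
effect). A centered-log-ratio transform is available via ``clr=True``
but is off by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "CorrelationError",
    "STAR_THRESHOLDS",
    "filter_taxa",
    "spearman_with_p",
    "correlate",
    "build_network",
    "degrees",
    "clr_transform",
]

#: (p threshold, label), checked in order.
STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.001, "***"), (0.01, "**"), (0.05, "*"),
)


class CorrelationError(ValueError):
    """Raised on invalid correlation/network inputs."""


@dataclass
class CorrelationResult:
    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    p_adj: pd.DataFrame | None = None
    missing: dict = field(default_factory=dict)
    method: str = "spearman"


def filter_taxa(rel_abundance: pd.DataFrame, min_pct: float = 0.1) -> pd.DataFrame:
    """Keep taxa whose mean relative abundance strictly exceeds ``min_pct``.

    ``rel_abundance`` is taxa x samples in percent (a ``mean_pct``
    column, if present, is excluded from the mean and dropped).
    """
    mat = rel_abundance.drop(columns=["mean_pct"], errors="ignore")
    return mat[mat.mean(axis=1) > min_pct]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    n = len(rx)
    count = 0
    total = 0
    abs_obs = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(rx @ ry[list(perm)]) / denom
        if abs(r) >= abs_obs:
            count += 1
        total += 1
    return count / total


def spearman_with_p(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation p (all n! pairings) for n <= ``exact_max_n``;
    the t approximation otherwise. Raises :class:`CorrelationError` for
    constant vectors, where rank correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise CorrelationError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p)


def _stars(p: float) -> str:
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return ""


def correlate(
    taxa: pd.DataFrame,
    metabolites: pd.DataFrame,
    method: str = "spearman",
    adjust: bool = False,
    exact_max_n: int = 8,
) -> CorrelationResult:
    """All pairwise taxa x metabolite correlations with stars.

    Both inputs are feature x sample frames sharing sample columns in
    the same order. Pairs involving a constant vector are reported as
    NaN with the reason recorded in ``result.missing``.
    """
    if list(taxa.columns) != list(metabolites.columns):
        raise CorrelationError("taxa and metabolite matrices must share sample columns")
    if taxa.shape[1] < 3:
        raise CorrelationError("need >= 3 paired samples")
    if method not in {"spearman", "pearson"}:
        raise CorrelationError(f"unknown method {method!r}")

    rho = pd.DataFrame(index=taxa.index, columns=metabolites.index, dtype=float)
    pmat = pd.DataFrame(index=taxa.index, columns=metabolites.index, dtype=float)
    missing: dict = {}
    for t in taxa.index:
        for m in metabolites.index:
            x = taxa.loc[t].to_numpy(dtype=float)
            y = metabolites.loc[m].to_numpy(dtype=float)
            try:
                if method == "spearman":
                    r, p = spearman_with_p(x, y, exact_max_n=exact_max_n)
                else:
                    if np.ptp(x) == 0 or np.ptp(y) == 0:
                        raise CorrelationError("constant vector")
                    r, p = stats.pearsonr(x, y)
            except CorrelationError as exc:
                rho.loc[t, m] = np.nan
                pmat.loc[t, m] = np.nan
                missing[(t, m)] = str(exc)
                continue
            rho.loc[t, m] = r
            pmat.loc[t, m] = p

    stars = pmat.map(lambda p: "" if pd.isna(p) else _stars(p))
    p_adj = None
    if adjust:
        flat = pmat.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p_adj = pd.DataFrame(adj.reshape(pmat.shape), index=pmat.index,
                             columns=pmat.columns)
    return CorrelationResult(rho=rho, p=pmat, stars=stars, p_adj=p_adj,
                             missing=missing, method=method)


def clr_transform(abundance: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform per sample (column)."""
    mat = abundance + pseudocount
    log = np.log(mat)
    return log - log.mean(axis=0)


def build_network(
    taxa: pd.DataFrame,
    rho_threshold: float = 0.6,
    p_threshold: float = 0.05,
    method: str = "spearman",
    exact_max_n: int = 8,
) -> nx.Graph:
    """Taxa co-occurrence network from pairwise correlations.

    Edge (i, j) iff |rho_ij| >= rho_threshold and p_ij < p_threshold.
    Undirected, simple, no self-loops; nodes carry their mean relative
    abundance, edges carry rho and p.
    """
    if not (0 <= rho_threshold <= 1):
        raise CorrelationError(f"rho_threshold outside [0, 1]: {rho_threshold}")
    if not (0 < p_threshold <= 1):
        raise CorrelationError(f"p_threshold outside (0, 1]: {p_threshold}")
    if taxa.shape[1] < 3:
        raise CorrelationError("need >= 3 samples")

    net = nx.Graph()
    means = taxa.mean(axis=1)
    for t in taxa.index:
        net.add_node(t, mean_abundance=float(means[t]))
    for a, b in itertools.combinations(taxa.index, 2):
        x = taxa.loc[a].to_numpy(dtype=float)
        y = taxa.loc[b].to_numpy(dtype=float)
        try:
            if method == "spearman":
                r, p = spearman_with_p(x, y, exact_max_n=exact_max_n)
            else:
                r, p = stats.pearsonr(x, y)
        except CorrelationError:
            continue
        if abs(r) >= rho_threshold and p < p_threshold:
            net.add_edge(a, b, rho=float(r), p=float(p))
    return net


def degrees(net: nx.Graph) -> pd.DataFrame:
    """Node degree table sorted by descending degree, ties alphabetical."""
    rows = [{"node": n, "degree": d} for n, d in net.degree()]
    df = pd.DataFrame(rows, columns=["node", "degree"])
    df["node"] = df["node"].astype(str)
    return (
        df.sort_values(["degree", "node"], ascending=[False, True])
        .reset_index(drop=True)
    )
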