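"""Spearman correlation networks over bile acids, taxa and metabolites.

Two edge rules mirror the two study designs: for small-n rumen data
(n = 5 or 6 samples per group) an edge requires a perfect monotone
relationship (|rho| = 1, the smallest attainable permutation p at that n);
for larger serum panels edges pass Benjamini-Hochberg-adjusted Spearman
p < alpha over the whole tested family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "CorrelationNetwork",
    "spearman_matrix",
    "build_network",
    "hub_nodes",
]

_EXACT_MAX_N = 9


@lru_cache(maxsize=8)
def _rank_permutations(n: int) -> np.ndarray:
    """All n! permutations of 1..n as an array (cached per n)."""
    return np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration.

    Valid with ties: the observed (average) ranks of y are permuted over all
    n! orderings.
    """
    n = rx.size
    # Permute which y goes with which x: every ordering of the observed
    # (average) y ranks, so tied ranks keep their values.
    idx = _rank_permutations(n).astype(int) - 1
    ry_perm = ry[idx]
    rx_c = rx - rx.mean()
    denom_x = np.sqrt((rx_c**2).sum())
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((ry_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = (ry_c @ rx_c) / (denom_x * denom_y)
    obs = (ry - ry.mean()) @ rx_c / (denom_x * np.sqrt(((ry - ry.mean())**2).sum()))
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


def spearman_matrix(X: pd.DataFrame | np.ndarray,
                    exact_max_n: int = _EXACT_MAX_N):
    """Pairwise Spearman rho and two-sided p over feature columns.

    Average ranks for ties.  For n <= ``exact_max_n`` samples the p-value is
    the exact permutation probability; otherwise the t-approximation.
    Constant features yield NaN rho/p (excluded from networks downstream).
    Returns ``(r, p)`` DataFrames indexed by feature name.
    """
    df = pd.DataFrame(X)
    n, m = df.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    cols = list(df.columns)
    vals = df.to_numpy(dtype=float)
    const = vals.std(axis=0) == 0
    ranks = np.apply_along_axis(sps.rankdata, 0, vals)

    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    use_exact = n <= exact_max_n
    for i in range(m):
        if const[i]:
            continue
        for j in range(i + 1, m):
            if const[j]:
                continue
            rho, pt = sps.spearmanr(vals[:, i], vals[:, j])
            r[i, j] = r[j, i] = rho
            pv = _exact_spearman_p(ranks[:, i], ranks[:, j]) if use_exact \
                else float(pt)
            p[i, j] = p[j, i] = pv
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclass
class CorrelationNetwork:
    """Undirected correlation network with edge statistics."""

    graph: nx.Graph
    rule: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return [(u, v, d) for u, v, d in self.graph.edges(data=True)]


def build_network(r: pd.DataFrame, p: pd.DataFrame, rule: str = "exact_unit",
                  alpha: float = 0.05, node_types: dict[str, str] | None = None,
                  pairs: list[tuple[str, str]] | None = None,
                  ) -> CorrelationNetwork:
    """Threshold a correlation matrix into a network.

    rule ``exact_unit`` keeps pairs with |rho| = 1 (tolerance 1e-12 on exact
    rank arithmetic); rule ``bh_alpha`` BH-adjusts the p-values across the
    tested family and keeps adjusted p < alpha.  ``pairs`` restricts the
    family (e.g. a bipartite BA x metabolite design); default is all upper-
    triangle pairs.  NaN correlations (constant features) never form edges.
    """
    if rule not in ("exact_unit", "bh_alpha"):
        raise ValueError(f"unknown rule {rule!r}")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not r.index.equals(p.index) or not r.columns.equals(p.columns):
        raise ValueError("r and p matrices are not conformable")
    names = list(r.index)
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]

    g = nx.Graph()
    for nname in names:
        g.add_node(nname, type=(node_types or {}).get(nname, "feature"))

    if rule == "exact_unit":
        for u, v in pairs:
            rho = r.at[u, v]
            if np.isnan(rho):
                continue
            if abs(abs(rho) - 1.0) <= 1e-12:
                g.add_edge(u, v, r=float(rho), p=float(p.at[u, v]),
                           p_adj=np.nan, sign=int(np.sign(rho)))
    else:
        raw = np.array([p.at[u, v] for u, v in pairs], dtype=float)
        ok = ~np.isnan(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(raw[ok])
        for (u, v), padj in zip(pairs, adj):
            if np.isnan(padj) or padj >= alpha:
                continue
            rho = r.at[u, v]
            g.add_edge(u, v, r=float(rho), p=float(p.at[u, v]),
                       p_adj=float(padj), sign=int(np.sign(rho)))
    return CorrelationNetwork(graph=g, rule=rule)


def hub_nodes(network: CorrelationNetwork, k: int = 1) -> list[dict]:
    """Top-k nodes by degree; alphabetical tie-break, ties flagged."""
    degrees = dict(network.graph.degree())
    if not degrees:
        return []
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    out = []
    for name, deg in ranked[:k]:
        tied = sum(1 for _, d in ranked if d == deg) > 1
        out.append({"node": name, "degree": deg, "tied": tied})
    return out
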