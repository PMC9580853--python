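"""Node centrality panel for residue interaction networks.

Measures: degree, betweenness (unnormalized shortest-path), closeness,
Burt's constraint, authority score and PageRank, each with a percentile
twin.  The percentile of a value is the percentage of *other* nodes with
a strictly smaller value, so ties share a percentile and an all-equal
column maps to all zeros.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "degree",
    "betweenness",
    "closeness",
    "burts_constraint",
    "authority",
    "pagerank",
    "to_percentiles",
    "centrality_table",
    "measure_correlations",
]

MEASURES = ["degree", "betweenness", "closeness", "burts_constraint",
            "authority", "pagerank"]


def degree(g: nx.Graph) -> pd.Series:
    return pd.Series(dict(g.degree()), name="degree")


def betweenness(g: nx.Graph) -> pd.Series:
    """Unnormalized shortest-path betweenness, equal-length paths split evenly."""
    return pd.Series(nx.betweenness_centrality(g, normalized=False), name="betweenness")


def closeness(g: nx.Graph, wf_improved: bool = True) -> pd.Series:
    """Closeness centrality; disconnected parts handled per component
    (Wasserman-Faust scaling by default)."""
    return pd.Series(nx.closeness_centrality(g, wf_improved=wf_improved),
                     name="closeness")


def burts_constraint(g: nx.Graph) -> pd.Series:
    """Burt's constraint with proportional tie strengths p_ij = 1/degree(i).

    c(i) = sum_j (p_ij + sum_q p_iq p_qj)^2 over neighbours j, indirect
    terms over shared neighbours q.  Isolated nodes get a missing value.
    """
    vals = nx.constraint(g)
    return pd.Series({n: (np.nan if isinstance(v, float) and np.isnan(v) else float(v))
                      for n, v in vals.items()}, name="burts_constraint")


def authority(g: nx.Graph) -> pd.Series:
    """HITS authority score (for undirected graphs equal to the hub score).

    Computed per connected component (where the principal eigenvector is
    unique) and renormalized to sum to 1 over the whole graph; isolated
    nodes score 0.
    """
    out: dict = {}
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        _, auth = nx.hits(g.subgraph(comp), max_iter=1000, normalized=True)
        out.update(auth)
    s = pd.Series(out, name="authority").abs()
    total = s.sum()
    return s / total if total > 0 else s


def pagerank(g: nx.Graph, damping: float = 0.85) -> pd.Series:
    return pd.Series(nx.pagerank(g, alpha=damping, tol=1e-12, max_iter=10000),
                     name="pagerank")


def to_percentiles(values: pd.Series, tol: float = 1e-9) -> pd.Series:
    """Percentile = 100 * #{other nodes with strictly smaller value}/(n-1).

    Missing values propagate and do not count as "other nodes".  Values
    within ``tol`` (absolute, scaled by magnitude) count as tied, so
    iteratively computed measures keep symmetric nodes at one percentile.
    """
    valid = values.dropna()
    n = len(valid)
    if n < 2:
        raise ValueError("percentiles require at least 2 non-missing values")
    arr = valid.to_numpy(dtype=float)
    eps = tol * np.maximum(1.0, np.abs(arr[:, None]))
    counts = (arr[None, :] < arr[:, None] - eps).sum(axis=1)
    pct = pd.Series(100.0 * counts / (n - 1), index=valid.index)
    return pct.reindex(values.index)


def centrality_table(g: nx.Graph) -> pd.DataFrame:
    """Raw centrality panel plus a ``*_pct`` percentile twin per measure."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    df = pd.DataFrame({
        "degree": degree(g),
        "betweenness": betweenness(g),
        "closeness": closeness(g),
        "burts_constraint": burts_constraint(g),
        "authority": authority(g),
        "pagerank": pagerank(g),
    })
    for m in MEASURES:
        df[m + "_pct"] = to_percentiles(df[m])
    return df


def measure_correlations(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Symmetric Spearman correlation matrix across measure columns.

    Average ranks for ties; pairs need >= 3 complete observations,
    otherwise (or for constant columns) the entry is missing and logged.
    """
    cols = columns if columns is not None else [c for c in table.columns
                                                if table[c].dtype.kind in "fib"]
    k = len(cols)
    out = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = table[cols[i]], table[cols[j]]
            mask = a.notna() & b.notna()
            if mask.sum() < 3 or a[mask].nunique() < 2 or b[mask].nunique() < 2:
                logger.warning("correlation %s~%s undefined (constant or <3 obs)",
                               cols[i], cols[j])
                rho = np.nan
            else:
                rho = stats.spearmanr(a[mask], b[mask]).statistic
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out
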