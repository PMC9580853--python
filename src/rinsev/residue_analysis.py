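"""Criticality analyses on the centrality panel.

Residues are grouped by their degree/betweenness percentiles (HDHB,
LDHB, LDLB), cross-domain "link" residues are extracted from the typed
contact list, and a Pareto front over (degree up, betweenness up, Burt's
constraint down) yields the supercritical set.  Group contrasts use the
unpaired two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .rin import ContactEdge
from .structure_io import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "group_residues",
    "find_link_nodes",
    "pareto_supercritical",
    "group_contrast",
]

HIGH_PCT = 80.0
LOW_PCT = 30.0


def group_residues(cent: pd.DataFrame, high_pct: float = HIGH_PCT,
                   low_pct: float = LOW_PCT) -> pd.Series:
    """Label nodes HDHB / LDHB / LDLB / unassigned from percentile columns.

    HDHB: degree and betweenness percentiles both >= ``high_pct``;
    LDHB: degree <= ``low_pct`` and betweenness >= ``high_pct``;
    LDLB: both <= ``low_pct``.  Thresholds are recorded in ``attrs``.
    """
    if high_pct <= low_pct:
        raise ValueError("high_pct must exceed low_pct")
    d, b = cent["degree_pct"], cent["betweenness_pct"]
    labels = pd.Series("unassigned", index=cent.index, name="group")
    labels[(d >= high_pct) & (b >= high_pct)] = "HDHB"
    labels[(d <= low_pct) & (b >= high_pct)] = "LDHB"
    labels[(d <= low_pct) & (b <= low_pct)] = "LDLB"
    labels.attrs["high_pct"] = high_pct
    labels.attrs["low_pct"] = low_pct
    return labels


def find_link_nodes(edges: list[ContactEdge], model: StructureModel) -> set[str]:
    """Residues with at least one contact into a different domain.

    Residues without a domain label are skipped (logged).
    """
    domain = {r.key: r.domain for r in model}
    out: set[str] = set()
    skipped = 0
    for e in edges:
        di, dj = domain.get(e.residue_i), domain.get(e.residue_j)
        if di is None or dj is None:
            skipped += 1
            continue
        if di != dj:
            out.update((e.residue_i, e.residue_j))
    if skipped:
        logger.warning("%d contact(s) skipped: endpoint lacks a domain label", skipped)
    return out


def pareto_supercritical(cent: pd.DataFrame) -> set:
    """Pareto-optimal nodes: maximize degree and betweenness, minimize
    Burt's constraint (weak dominance; ties on all three keep both)."""
    cols = ["degree", "betweenness", "burts_constraint"]
    sub = cent[cols].dropna()
    # orient all criteria as "larger is better"
    pts = sub.to_numpy(dtype=float) * np.array([1.0, 1.0, -1.0])
    n = len(pts)
    dominated = np.zeros(n, dtype=bool)
    for i in range(n):
        ge = (pts >= pts[i]).all(axis=1)
        gt = (pts > pts[i]).any(axis=1)
        if np.any(ge & gt & (np.arange(n) != i)):
            dominated[i] = True
    return set(sub.index[~dominated])


def group_contrast(values_a, values_b, method: str = "auto"):
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns (U statistic of sample a, two-sided p-value); tie-corrected.
    ``method`` follows scipy: 'exact' for small tie-free samples under
    'auto', normal approximation otherwise.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
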