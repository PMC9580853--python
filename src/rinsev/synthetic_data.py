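"""Fully synthetic inputs for every pipeline stage.

The mutation generator plants a linear-logistic severity signal in the
features the severity analyses report as informative: burial, network
centrality, conservation and the amino-acid substitution distance.  A
latent score

    z = w_b * buried + w_d * degree_pct/100 + w_c * conservation/9
        + w_a * aa_distance_norm + Normal(0, sigma)

is computed per sampled (position, mutant) pair and the top fraction by
``z`` (matching the requested class balance) is labelled severe.  The
generator is deliberately linear; it reproduces the monotone
feature-severity relationships the pipeline is meant to recover, not any
claim about protein biophysics, so recovery experiments are a fair test
of the machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import structure_io, structure_props, rin, centrality
from .aa_index import AADistanceIndex, PropertyMatrix, build_distance_index
from .chem import AA_ORDER
from .ml_framework import FeatureAssembler, position_feature_table

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "generate_property_matrix",
    "synthetic_structure_bundle",
    "generate_mutation_dataset",
    "generate_conflicting_reports",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic mutation dataset.

    The class balance defaults to 213:180 (mild/moderate : severe), the
    balance of the curated clinical table the protocol was designed
    around.  Effect weights put comparable mass on burial, centrality
    and conservation with a smaller substitution-distance term; sigma is
    the latent Gaussian noise scale.
    """

    n_mutations: int = 400
    severe_fraction: float = 180.0 / 393.0
    w_burial: float = 1.0
    w_degree: float = 1.0
    w_conservation: float = 1.0
    w_aadist: float = 0.5
    sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.severe_fraction < 1:
            raise ValueError("severe_fraction must be in (0, 1)")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for w in (self.w_burial, self.w_degree, self.w_conservation, self.w_aadist):
            if not np.isfinite(w):
                raise ValueError("effect weights must be finite")


def generate_property_matrix(n_properties: int = 60, n_factors: int = 5,
                             noise: float = 0.05, seed: int = 0) -> PropertyMatrix:
    """Synthetic AAindex-style property matrix with low-rank structure.

    Properties are noisy linear combinations of ``n_factors`` latent
    amino-acid factors, so PCA at a high variance target recovers a
    small component count.
    """
    rng = np.random.default_rng(seed)
    factors = rng.normal(size=(n_factors, 20))
    loadings = rng.normal(size=(n_properties, n_factors))
    data = loadings @ factors + noise * rng.normal(size=(n_properties, 20))
    ids = [f"SYN{i:04d}" for i in range(n_properties)]
    return PropertyMatrix(pd.DataFrame(data, index=ids, columns=list(AA_ORDER)))


def synthetic_structure_bundle(n_residues: int = 60, seed: int = 0,
                               kind: str = "globule") -> dict:
    """A toy structure with computed properties, RIN and centralities.

    Returns a dict with ``model``, ``props``, ``graph``, ``cent``,
    ``position_features`` and a synthetic 1-9 ``conservation`` table.
    Conservation is sampled per residue with a mild tilt toward buried
    residues being conserved, mirroring real structures.
    """
    rng = np.random.default_rng(seed)
    pdb = structure_io.generate_toy_structure(kind, n_residues, seed=seed)
    model = structure_io.read_structure(pdb)
    props = structure_props.compute_props(model)
    cons = {}
    for r, buried in zip(model, props["buried"]):
        base = 6.0 if buried else 4.0
        cons[f"{r.number}{r.icode}"] = int(np.clip(round(rng.normal(base, 2.0)), 1, 9))
    structure_io.attach_annotations(model, conservation=cons)
    graph = rin.build_rin_from_structure(model)
    cent = centrality.centrality_table(graph)
    pft = position_feature_table(model, props, cent)
    # residues outside the RIN lack centralities; keep rows complete
    pft = pft.dropna(subset=["degree"])
    return {"model": model, "props": props, "graph": graph, "cent": cent,
            "position_features": pft, "conservation": cons}


def generate_mutation_dataset(cfg: GeneratorConfig,
                              position_features: pd.DataFrame,
                              aa_dist: AADistanceIndex):
    """Sample labelled point mutations with a planted severity signal.

    Returns (mutation table, ground-truth latent DataFrame).  The label
    is ``severe`` where the latent score exceeds the balance-matching
    quantile, so for a continuous latent the requested balance holds
    within rounding; the latent scores are returned for recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = [p for p in position_features.index
                 if not position_features.loc[p, ["buried", "degree_pct"]].isna().any()]
    combos = [(p, m) for p in positions
              for m in AA_ORDER if m != position_features.loc[p, "aa"]]
    if cfg.n_mutations > len(combos):
        raise ValueError(f"requested {cfg.n_mutations} mutations but only "
                         f"{len(combos)} (position, mutant) pairs exist")
    pick = rng.choice(len(combos), size=cfg.n_mutations, replace=False)
    dmax = float(np.nanmax(aa_dist.matrix.to_numpy()))
    rows = []
    for idx in pick:
        pos, mut = combos[idx]
        feat = position_features.loc[pos]
        wt = feat["aa"]
        cons = feat.get("conservation", np.nan)
        cons = 5.0 if pd.isna(cons) else float(cons)
        d_norm = aa_dist[(wt, mut)] / dmax if dmax > 0 else 0.0
        z = (cfg.w_burial * float(feat["buried"])
             + cfg.w_degree * float(feat["degree_pct"]) / 100.0
             + cfg.w_conservation * cons / 9.0
             + cfg.w_aadist * d_norm
             + rng.normal(0.0, cfg.sigma))
        rows.append({"position": pos, "wt_aa": wt, "mut_aa": mut, "latent": z})
    df = pd.DataFrame(rows)
    threshold = float(np.quantile(df["latent"], 1.0 - cfg.severe_fraction))
    df["severity"] = np.where(df["latent"] > threshold, "severe", "mild_moderate")
    muts = df[["position", "wt_aa", "mut_aa", "severity"]].copy()
    truth = df[["position", "wt_aa", "mut_aa", "latent", "severity"]].copy()
    return muts, truth


def generate_conflicting_reports(muts: pd.DataFrame, flip_fraction: float,
                                 seed: int = 0) -> pd.DataFrame:
    """Duplicate a fraction of mutations with the opposite label.

    Emulates databases where the same substitution carries disagreeing
    clinical reports.  The original label stays in the majority for each
    conflicting pair (2 original copies + 1 flipped), so the majority
    class is recoverable by construction.
    """
    if not 0 <= flip_fraction <= 1:
        raise ValueError("flip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_flip = int(round(flip_fraction * len(muts)))
    flip_idx = rng.choice(len(muts), size=n_flip, replace=False)
    other = {"severe": "mild_moderate", "mild_moderate": "severe"}
    reports = []
    for i, row in muts.reset_index(drop=True).iterrows():
        reports.append({**row, "report_id": f"r{i}a", "conflict": i in set(flip_idx)})
        if i in set(flip_idx):
            reports.append({**row, "report_id": f"r{i}b", "conflict": True})
            flipped = dict(row)
            flipped["severity"] = other[row["severity"]]
            reports.append({**flipped, "report_id": f"r{i}c", "conflict": True})
    return pd.DataFrame(reports)


def default_assembler(bundle: dict, aa_dist: AADistanceIndex | None = None,
                      seed: int = 0) -> FeatureAssembler:
    """Convenience: assembler over a synthetic bundle and distance index."""
    if aa_dist is None:
        aa_dist = build_distance_index(generate_property_matrix(seed=seed))
    return FeatureAssembler(bundle["position_features"], aa_dist)
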