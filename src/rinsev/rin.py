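"""Residue interaction network (RIN) construction from atomic geometry.

Nodes are residues; an edge means at least one typed atomic contact
between two residues.  Contacts are classified by which atoms touch
(main chain vs side chain) and whether the pair satisfies a hydrogen
bond criterion.  The simplified graph collapses all typed edges between
a residue pair into a single undirected edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .structure_io import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEdge",
    "detect_contacts",
    "detect_hbonds",
    "build_rin",
    "build_rin_from_structure",
    "edges_to_frame",
]

DEFAULT_CUTOFF = 5.0
DEFAULT_MIN_SEQ_SEP = 2


@dataclass(frozen=True)
class ContactEdge:
    """A typed atomic contact between two residues (keys ordered)."""

    residue_i: str
    residue_j: str
    contact_class: str  # 'mc_mc' | 'sc_mc' | 'sc_sc'
    bond_type: str      # 'noncovalent' | 'hydrogen_bond'
    min_atom_distance: float


def _contact_class(backbone_i: bool, backbone_j: bool) -> str:
    if backbone_i and backbone_j:
        return "mc_mc"
    if backbone_i or backbone_j:
        return "sc_mc"
    return "sc_sc"


def _ordered(model: StructureModel):
    """Per-residue (chain, author number, ordinal) for sequence separation."""
    ordinal = {}
    counter: dict[str, int] = {}
    for r in model:
        counter[r.chain] = counter.get(r.chain, 0) + 1
        ordinal[r.key] = (r.chain, r.number, counter[r.chain])
    return ordinal


def _seq_separated(ordinal, key_i, key_j, min_seq_sep) -> bool:
    """Separation by author numbering (different chains always pass).

    Residues distinguished only by insertion code (same number) fall
    back to their ordinal distance in the chain.
    """
    ci, ni, oi = ordinal[key_i]
    cj, nj, oj = ordinal[key_j]
    if ci != cj:
        return True
    sep = abs(ni - nj) if ni != nj else abs(oi - oj)
    return sep >= min_seq_sep


def detect_contacts(model: StructureModel, cutoff: float = DEFAULT_CUTOFF,
                    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> list[ContactEdge]:
    """Heavy-atom distance contacts between residues.

    Two residues are in contact if any heavy-atom pair lies within
    ``cutoff`` A and their separation along the chain is at least
    ``min_seq_sep`` positions (covalently adjacent residues excluded by
    default).  One edge is emitted per (pair, contact class) with the
    minimum achieving distance.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    residues = list(model)
    atoms = [(ri, a) for ri, r in enumerate(residues) for a in r.heavy_atoms()]
    coords = np.array([a.coord for _, a in atoms])
    res_of = np.array([ri for ri, _ in atoms])
    bb = np.array([a.backbone for _, a in atoms])
    ordinal = _ordered(model)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    best: dict[tuple, float] = {}
    for ai, aj in pairs:
        ri, rj = res_of[ai], res_of[aj]
        if ri == rj:
            continue
        if ri > rj:
            ri, rj, ai, aj = rj, ri, aj, ai
        ki, kj = residues[ri].key, residues[rj].key
        if not _seq_separated(ordinal, ki, kj, min_seq_sep):
            continue
        cls = _contact_class(bool(bb[ai]), bool(bb[aj]))
        d = float(np.linalg.norm(coords[ai] - coords[aj]))
        k = (ki, kj, cls)
        if d < best.get(k, np.inf):
            best[k] = d
    return [ContactEdge(ki, kj, cls, "noncovalent", d)
            for (ki, kj, cls), d in sorted(best.items())]


def _angle(a, b, c) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(model: StructureModel, d_max: float = 3.5,
                  angle_min: float = 120.0,
                  min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> list[ContactEdge]:
    """Hydrogen bonds by heavy-atom geometry (no explicit protons).

    Criterion: donor-acceptor distance <= ``d_max`` and the
    antecedent-donor-acceptor angle >= ``angle_min``.  Donor/acceptor
    atoms come from per-residue chemistry tables (backbone amide N and
    carbonyl O always included).
    """
    residues = list(model)
    ordinal = _ordered(model)
    donors = []   # (res_idx, donor_coord, antecedent_coord, is_backbone)
    acceptors = []
    for ri, r in enumerate(residues):
        for datom, ante in chem.donors(r.aa):
            d_at, a_at = r.atom(datom), r.atom(ante)
            if d_at is not None and a_at is not None:
                donors.append((ri, d_at.coord, a_at.coord, d_at.backbone))
        for aatom in chem.acceptors(r.aa):
            at = r.atom(aatom)
            if at is not None:
                acceptors.append((ri, at.coord, at.backbone))

    best: dict[tuple, float] = {}
    for ri, dcoord, antecoord, dbb in donors:
        for rj, acoord, abb in acceptors:
            if ri == rj:
                continue
            ki, kj = residues[ri].key, residues[rj].key
            if not _seq_separated(ordinal, ki, kj, min_seq_sep):
                continue
            dist = float(np.linalg.norm(dcoord - acoord))
            if dist > d_max:
                continue
            if _angle(antecoord, dcoord, acoord) < angle_min:
                continue
            i, j = (ri, rj) if ri < rj else (rj, ri)
            cls = _contact_class(dbb, abb)
            k = (residues[i].key, residues[j].key, cls)
            if dist < best.get(k, np.inf):
                best[k] = dist
    return [ContactEdge(ki, kj, cls, "hydrogen_bond", d)
            for (ki, kj, cls), d in sorted(best.items())]


def build_rin(edges: list[ContactEdge], include_isolated: bool = False,
              model: StructureModel | None = None) -> nx.Graph:
    """Simplify typed contact edges into an undirected simple graph.

    Two residues interact if there is at least one edge between them,
    independently of the edge type; parallel typed edges collapse to one
    graph edge.  By default the node set is exactly the residues that
    take part in at least one contact; with ``include_isolated`` every
    residue of ``model`` becomes a node.
    """
    g = nx.Graph()
    if include_isolated:
        if model is None:
            raise ValueError("include_isolated=True requires the structure model")
        g.add_nodes_from(r.key for r in model)
    for e in edges:
        if e.residue_i == e.residue_j:
            continue
        if g.has_edge(e.residue_i, e.residue_j):
            data = g.edges[e.residue_i, e.residue_j]
            data["types"] = sorted(set(data["types"]) | {(e.contact_class, e.bond_type)})
            data["distance"] = min(data["distance"], e.min_atom_distance)
        else:
            g.add_edge(e.residue_i, e.residue_j,
                       types=[(e.contact_class, e.bond_type)],
                       distance=e.min_atom_distance)
    return g


def build_rin_from_structure(model: StructureModel, cutoff: float = DEFAULT_CUTOFF,
                             min_seq_sep: int = DEFAULT_MIN_SEQ_SEP,
                             hbonds: bool = True,
                             include_isolated: bool = False) -> nx.Graph:
    """Contacts + hydrogen bonds -> simplified RIN, with metadata."""
    edges = detect_contacts(model, cutoff=cutoff, min_seq_sep=min_seq_sep)
    if hbonds:
        edges = edges + detect_hbonds(model, min_seq_sep=min_seq_sep)
    g = build_rin(edges, include_isolated=include_isolated, model=model)
    g.graph.update(cutoff=cutoff, min_seq_sep=min_seq_sep, hbonds=hbonds)
    return g


def edges_to_frame(edges: list[ContactEdge]):
    """Edge list as a DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [(e.residue_i, e.residue_j, e.contact_class, e.bond_type,
          e.min_atom_distance) for e in edges],
        columns=["residue_i", "residue_j", "contact_class", "bond_type", "distance"],
    )
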