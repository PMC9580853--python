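"""Per-residue structural measures: surface areas, exposure, dihedrals.

The solvent-accessible surface area (areaSAS) is computed with the
rolling-probe machinery of :func:`biotite.structure.sasa`.  A true
solvent-excluded (molecular) surface is expensive and is not required
downstream: every consumer of areaSES uses either the Gly-X-Gly ratio or
the buried flag, both of which are strongly rank-correlated between the
two definitions.  areaSES therefore defaults to the SASA value (probe
1.4 A); an exact SES backend can be plugged in via ``ses_backend``.
The choice is recorded in the output's ``attrs`` metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import biotite.structure as bst

from .chem import GXG_REFERENCE_AREA, KD_HYDROPHOBICITY
from .structure_io import StructureModel, dihedral_angle

logger = logging.getLogger(__name__)

__all__ = [
    "compute_sasa",
    "relative_exposure",
    "classify_buried",
    "dihedrals",
    "assign_ss_fallback",
    "compute_props",
    "ReferenceAreaTable",
]

BURIED_THRESHOLD = 0.25


class ReferenceAreaTable(dict):
    """Map amino acid (1-letter) -> reference area in a Gly-X-Gly tripeptide."""

    def __init__(self, values: dict[str, float] | None = None):
        super().__init__(values if values is not None else GXG_REFERENCE_AREA)
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self)
        if missing:
            raise ValueError(f"reference table missing amino acids: {sorted(missing)}")
        if any(v <= 0 for v in self.values()):
            raise ValueError("reference areas must be positive")


def _to_atom_array(model: StructureModel):
    atoms = [(i, r, a) for i, r in enumerate(model) for a in r.heavy_atoms()]
    arr = bst.AtomArray(len(atoms))
    arr.coord = np.array([a.coord for _, _, a in atoms])
    arr.element = np.array([a.element.upper() for _, _, a in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.res_name = np.array([r.aa3 for _, r, _ in atoms])
    arr.res_id = np.array([i for i, _, _ in atoms])
    arr.chain_id = np.array([r.chain for _, r, _ in atoms])
    return arr, np.array([i for i, _, _ in atoms])


def compute_sasa(model: StructureModel, probe_radius: float = 1.4,
                 point_number: int = 300) -> pd.Series:
    """Solvent-accessible surface area (A^2) per residue.

    Element-based van der Waals radii are used so that partial side
    chains (toy structures) are handled gracefully.  Residues without
    heavy atoms get a missing value.
    """
    arr, res_idx = _to_atom_array(model)
    per_atom = bst.sasa(arr, probe_radius=probe_radius, vdw_radii="Single",
                        point_number=point_number)
    per_atom = np.nan_to_num(per_atom)
    sums = np.bincount(res_idx, weights=per_atom, minlength=len(model))
    out = pd.Series(sums, index=[r.key for r in model], name="areaSAS")
    for r in model:
        if not r.heavy_atoms():
            out[r.key] = np.nan
            logger.warning("residue %s has no heavy atoms; SASA missing", r.key)
    return out


def relative_exposure(area: pd.Series, model: StructureModel,
                      ref: ReferenceAreaTable | None = None) -> pd.Series:
    """Residue area divided by the same residue type's Gly-X-Gly reference."""
    ref = ref if ref is not None else ReferenceAreaTable()
    out = {}
    for r in model:
        if r.aa not in ref:
            raise KeyError(f"no reference area for residue type {r.aa!r} at {r.key}")
        out[r.key] = area[r.key] / ref[r.aa]
    return pd.Series(out, name="rel_exposure")


def classify_buried(rel_norm: pd.Series, threshold: float = BURIED_THRESHOLD) -> pd.Series:
    """Buried/exposed call: strictly below ``threshold`` is buried.

    ``rel_norm`` is the relative exposure after division by its maximum
    over the structure, i.e. values in [0, 1].
    """
    return (rel_norm < threshold).rename("buried")


def dihedrals(model: StructureModel) -> pd.DataFrame:
    """Backbone (phi, psi) in degrees; missing at chain termini.

    IUPAC sign convention.  Residues with missing backbone atoms get
    missing values (logged).
    """
    rows = {}
    residues = list(model)
    for i, r in enumerate(residues):
        prev_r = residues[i - 1] if i > 0 and residues[i - 1].chain == r.chain else None
        next_r = residues[i + 1] if i + 1 < len(residues) and residues[i + 1].chain == r.chain else None
        n, ca, c = r.atom("N"), r.atom("CA"), r.atom("C")
        phi = psi = np.nan
        if None in (n, ca, c):
            logger.warning("residue %s lacks backbone atoms; dihedrals missing", r.key)
        else:
            if prev_r is not None and prev_r.atom("C") is not None:
                phi = dihedral_angle(prev_r.atom("C").coord, n.coord, ca.coord, c.coord)
            if next_r is not None and next_r.atom("N") is not None:
                psi = dihedral_angle(n.coord, ca.coord, c.coord, next_r.atom("N").coord)
        rows[r.key] = (phi, psi)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["phi", "psi"])


# Ramachandran boxes for the fallback assigner; T is never produced.
_HELIX_BOX = ((-100.0, -30.0), (-80.0, -5.0))
_STRAND_PHI = (-180.0, -45.0)


def assign_ss_fallback(phi: float, psi: float) -> str:
    """Coarse Ramachandran-region secondary structure: H, E or C.

    This is a fallback for when no external secondary-structure table
    (e.g. from STRIDE or DSSP) is supplied; it only distinguishes the
    canonical helix and strand basins.
    """
    if np.isnan(phi) or np.isnan(psi):
        return "C"
    if _HELIX_BOX[0][0] <= phi <= _HELIX_BOX[0][1] and _HELIX_BOX[1][0] <= psi <= _HELIX_BOX[1][1]:
        return "H"
    if _STRAND_PHI[0] <= phi <= _STRAND_PHI[1] and (psi >= 90.0 or psi <= -160.0):
        return "E"
    return "C"


def compute_props(model: StructureModel, probe_radius: float = 1.4,
                  ref: ReferenceAreaTable | None = None,
                  ses_backend=None, point_number: int = 300) -> pd.DataFrame:
    """Full per-residue property table.

    Columns: residue_number, aa, areaSAS, areaSES, rel_exposure,
    relSESA_norm, buried, kd_hydrophobicity, phi, psi, ss.  ``ss`` uses
    any attached annotation and falls back to the Ramachandran rule.
    """
    sas = compute_sasa(model, probe_radius=probe_radius, point_number=point_number)
    ses = ses_backend(model) if ses_backend is not None else sas.copy()
    rel = relative_exposure(ses, model, ref=ref)
    rel_max = np.nanmax(rel.values)
    rel_norm = rel / rel_max if rel_max > 0 else rel * 0.0
    dih = dihedrals(model)
    df = pd.DataFrame({
        "residue_number": [f"{r.number}{r.icode}" for r in model],
        "aa": [r.aa for r in model],
        "areaSAS": sas,
        "areaSES": ses.rename("areaSES"),
        "rel_exposure": rel,
        "relSESA_norm": rel_norm.rename("relSESA_norm"),
        "buried": classify_buried(rel_norm),
        "kd_hydrophobicity": [KD_HYDROPHOBICITY[r.aa] for r in model],
        "phi": dih["phi"],
        "psi": dih["psi"],
    }, index=[r.key for r in model])
    df["ss"] = [r.ss if r.ss is not None else assign_ss_fallback(p, q)
                for r, p, q in zip(model, df["phi"], df["psi"])]
    df.attrs["ses_backend"] = "sasa-approximation" if ses_backend is None else "custom"
    df.attrs["probe_radius"] = probe_radius
    df.attrs["buried_threshold"] = BURIED_THRESHOLD
    return df
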