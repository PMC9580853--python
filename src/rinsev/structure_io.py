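"""Protein structure containers, PDB input and toy-structure generation.

Residue numbering follows the author numbering of the input file and is
never re-indexed; for factor IX(a) this is the HGVS mature-protein
numbering that clinical variant databases use (e.g. Phe424 in the serine
protease domain).  Insertion codes are kept as part of the residue key
and sort after the bare number.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .chem import AA_1TO3, AA_3TO1, BACKBONE_ATOMS

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "StructureParseError",
    "read_structure",
    "attach_annotations",
    "generate_toy_structure",
    "write_structure",
]


class StructureParseError(ValueError):
    """Raised when PDB content cannot be parsed or selects no residues."""


@dataclass
class AtomRecord:
    """A single heavy (or hydrogen) atom with Cartesian coordinates in A."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite values")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class ResidueRecord:
    """One amino-acid residue: atoms plus structural / domain annotations."""

    chain: str
    number: int
    aa: str
    atoms: list[AtomRecord]
    icode: str = ""
    domain: str | None = None
    ss: str | None = None
    conservation: float | None = None

    def __post_init__(self) -> None:
        if self.aa not in AA_1TO3:
            raise ValueError(f"{self.aa!r} is not a standard amino acid")
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")

    @property
    def aa3(self) -> str:
        return AA_1TO3[self.aa]

    @property
    def key(self) -> str:
        """Unique residue key, e.g. ``'A:424'`` or ``'A:100A'``."""
        return f"{self.chain}:{self.number}{self.icode}"

    @property
    def sort_key(self) -> tuple:
        return (self.chain, self.number, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]


class StructureModel:
    """An ordered list of residues with provenance metadata."""

    def __init__(self, residues: list[ResidueRecord], source: str = "",
                 meta: dict | None = None):
        if not residues:
            raise StructureParseError("structure contains no residues")
        self.residues = residues
        self.source = source
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i: int) -> ResidueRecord:
        return self.residues[i]

    def get(self, key: str) -> ResidueRecord | None:
        """Look up a residue by key ('A:42') or bare author number."""
        skey = str(key)
        for r in self.residues:
            if r.key == skey or f"{r.number}{r.icode}" == skey:
                return r
        return None

    def by_number(self) -> dict:
        """Map author residue number (with icode suffix) -> residue."""
        return {f"{r.number}{r.icode}": r for r in self.residues}

    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain not in seen:
                seen.append(r.chain)
        return seen


def _pick_altloc(bp_atom):
    """Resolve a possibly disordered Biopython atom to one conformer.

    Highest occupancy wins; ties go to the first-listed altloc.
    """
    if not bp_atom.is_disordered():
        return bp_atom
    children = bp_atom.disordered_get_list()
    return max(children, key=lambda a: (a.get_occupancy() or 0.0))


def read_structure(pdb_text: str, chain_filter: set[str] | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Keeps the 20 standard amino acids of the selected chains; waters,
    ions and other heteroatoms are dropped.  Alternate locations are
    resolved to the highest-occupancy conformer.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("model", io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureParseError(f"malformed PDB input: {exc}") from exc

    residues: list[ResidueRecord] = []
    model = next(structure.get_models(), None)
    if model is None:
        raise StructureParseError("PDB input contains no model")
    for chain in model:
        cid = chain.id.strip() or "A"
        if chain_filter is not None and cid not in chain_filter:
            continue
        for res in chain:
            hetflag, resseq, icode = res.get_id()
            if hetflag.strip():
                continue  # waters / heteroatoms
            aa1 = AA_3TO1.get(res.get_resname().strip())
            if aa1 is None:
                continue  # non-standard residue
            atoms = []
            for a in res:
                a = _pick_altloc(a)
                elem = (a.element or a.get_name()[0]).strip() or a.get_name()[0]
                atoms.append(AtomRecord(a.get_name(), elem, a.get_coord()))
            if atoms:
                residues.append(ResidueRecord(
                    chain=cid, number=int(resseq), icode=icode.strip(),
                    aa=aa1, atoms=atoms))
    if not residues:
        raise StructureParseError(
            "no standard amino-acid residues in selection "
            f"(chains requested: {sorted(chain_filter) if chain_filter else 'all'})")
    keys = [r.key for r in residues]
    if len(set(keys)) != len(keys):
        raise StructureParseError("duplicate residue keys in input")
    return StructureModel(residues, source="<pdb-text>",
                          meta={"chain_filter": sorted(chain_filter) if chain_filter else None})


def _as_mapping(table) -> dict:
    """Accept dict / Series / two-column DataFrame keyed by residue number."""
    if table is None:
        return {}
    if hasattr(table, "columns"):  # DataFrame with residue_number, value
        cols = list(table.columns)
        return dict(zip(table[cols[0]].astype(str), table[cols[1]]))
    if hasattr(table, "items"):
        return {str(k): v for k, v in dict(table).items()}
    raise TypeError("annotation table must be a dict, Series or DataFrame")


def attach_annotations(model: StructureModel, domains=None, conservation=None,
                       ss=None) -> StructureModel:
    """Attach per-residue domain / conservation / secondary-structure tables.

    Tables are keyed by author residue number (string or int).  Keys that
    do not match any residue are counted as orphans and logged; residues
    missing from a table keep a ``None`` (flagged missing) value.
    """
    tables = {"domain": _as_mapping(domains),
              "conservation": _as_mapping(conservation),
              "ss": _as_mapping(ss)}
    index = model.by_number()
    orphans: dict[str, list[str]] = {}
    for name, mapping in tables.items():
        missing = [k for k in mapping if k not in index]
        if missing:
            orphans[name] = missing
            logger.warning("%d %s annotation(s) matched no residue: %s",
                           len(missing), name, missing[:5])
        for key, value in mapping.items():
            res = index.get(key)
            if res is None:
                continue
            if name == "conservation":
                res.conservation = float(value)
            else:
                setattr(res, name, value)
    model.meta["annotation_orphans"] = {k: len(v) for k, v in orphans.items()}
    return model


# ---------------------------------------------------------------------------
# Toy-structure generation
# ---------------------------------------------------------------------------

# Engh-Huber style ideal backbone geometry (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.521
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom d so that |cd|=bond, angle(b,c,d)=angle, dih(a,b,c,d)=dihedral."""
    ang, dih = math.radians(angle), math.radians(dihedral)
    bc = np.asarray(c, float) - np.asarray(b, float)
    bc /= np.linalg.norm(bc)
    n = np.cross(np.asarray(b, float) - np.asarray(a, float), bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(dih),
                        bond * math.sin(ang) * math.sin(dih)])
    return np.asarray(c, float) + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict]:
    """NeRF chain build from per-residue (phi, psi); omega fixed at 180."""
    n = len(phi_psi)
    res: list[dict] = []
    N0 = np.zeros(3)
    CA0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    C0 = CA0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    res.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        Ni = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CAi = place_atom(prev["CA"], prev["C"], Ni, _B_N_CA, _A_C_N_CA, 180.0)
        Ci = place_atom(prev["C"], Ni, CAi, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        res.append({"N": Ni, "CA": CAi, "C": Ci})
    # carbonyl O: trans to the next amide N (dihedral N-CA-C-O = psi + 180)
    for i in range(n):
        psi = phi_psi[i][1] if i < n - 1 else -40.0
        res[i]["O"] = place_atom(res[i]["N"], res[i]["CA"], res[i]["C"],
                                 _B_C_O, _A_CA_C_O, psi + 180.0)
    return res


def _add_cb(backbone: list[dict], sequence: str) -> None:
    for bb, aa in zip(backbone, sequence):
        if aa != "G":
            # N-C-CA-CB improper dihedral ~ +122.5 deg gives L-chirality
            bb["CB"] = place_atom(bb["N"], bb["C"], bb["CA"],
                                  _B_CA_CB, 110.4, 122.5)


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_ATOM_ORDER = ["N", "CA", "C", "O", "CB"]


def write_structure(residues: list[tuple[str, int, str, dict]], chain: str = "A") -> str:
    """Serialize (aa1, number, icode, {atom: coord}) tuples to PDB text."""
    lines = []
    serial = 1
    for aa1, number, icode, atoms in residues:
        res3 = AA_1TO3[aa1]
        for name in _ATOM_ORDER:
            if name not in atoms:
                continue
            x, y, z = atoms[name]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3:>3s} {chain}{number:4d}{icode or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {_ELEMENT[name]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _model_to_tuples(model: StructureModel):
    return [(r.aa, r.number, r.icode, {a.name: a.coord for a in r.atoms})
            for r in model]


def serialize_structure(model: StructureModel) -> str:
    """Re-serialize a StructureModel to PDB text (single chain per call order)."""
    return write_structure(_model_to_tuples(model), chain=model.residues[0].chain)


def generate_toy_structure(kind: str, n_residues: int, seed: int = 0,
                           gap: float = 25.0) -> str:
    """Generate deterministic PDB text with ideal toy geometry.

    kind:
        ``helix``      ideal alpha helix (phi=-57, psi=-47)
        ``strand``     extended beta strand (phi=-120, psi=+130)
        ``two_domain`` two helical clusters separated by ``gap`` A along x,
                       contiguous numbering, so cross-cluster contacts are
                       controlled by ``gap``
        ``globule``    compact cubic-lattice arrangement (5 A spacing) with
                       locally planted backbone atoms; interior residues are
                       occluded, which makes burial and contact patterns
                       non-trivial.  Dihedrals of this fixture are not
                       physically meaningful.
    """
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    rng = np.random.default_rng(seed)
    sequence = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n_residues))

    if kind == "helix":
        bb = _build_backbone([HELIX_PHI_PSI] * n_residues)
    elif kind == "strand":
        bb = _build_backbone([STRAND_PHI_PSI] * n_residues)
    elif kind == "two_domain":
        half = n_residues // 2
        bb1 = _build_backbone([HELIX_PHI_PSI] * half)
        bb2 = _build_backbone([HELIX_PHI_PSI] * (n_residues - half))
        shift = np.array([gap, 0.0, 0.0])
        for r in bb2:
            for k in r:
                r[k] = r[k] + shift
        bb = bb1 + bb2
    elif kind == "globule":
        side = max(2, math.ceil(n_residues ** (1.0 / 3.0)))
        bb = []
        for i in range(n_residues):
            ix, iy, iz = i % side, (i // side) % side, i // (side * side)
            ca = 5.0 * np.array([ix, iy, iz]) + rng.normal(0.0, 0.3, 3)
            u = rng.normal(size=3); u /= np.linalg.norm(u)
            v = rng.normal(size=3); v -= v @ u * u; v /= np.linalg.norm(v)
            w = np.cross(u, v)
            bb.append({"N": ca + _B_N_CA * u, "CA": ca,
                       "C": ca + _B_CA_C * v,
                       "O": ca + _B_CA_C * v + _B_C_O * w})
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")

    if kind in ("helix", "strand", "two_domain"):
        _add_cb(bb, sequence)
    tuples = [(sequence[i], i + 1, "", bb[i]) for i in range(n_residues)]
    return write_structure(tuples)
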