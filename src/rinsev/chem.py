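"""Static amino-acid chemistry tables used across the package.

All tables are keyed by one-letter codes in the fixed order of
:data:`AA_ORDER`, which is also the canonical column order of the
amino-acid property matrix and the 20x20 distance index.
"""

from __future__ import annotations

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}

#: Kyte-Doolittle hydropathy scale.
KD_HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Reference surface area (A^2) of residue X in an extended Gly-X-Gly
#: tripeptide; theoretical maximum ASA values of Tien et al. (2013).
#: Overridable wherever a ReferenceAreaTable is accepted.
GXG_REFERENCE_AREA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

#: Hydrogen-bond donor heavy atoms per residue type, as
#: (donor_atom, antecedent_atom) pairs.  The backbone amide N (antecedent
#: CA) is a donor for every residue type except proline.
SIDECHAIN_DONORS = {
    "S": [("OG", "CB")],
    "T": [("OG1", "CB")],
    "Y": [("OH", "CZ")],
    "N": [("ND2", "CG")],
    "Q": [("NE2", "CD")],
    "K": [("NZ", "CE")],
    "R": [("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")],
    "H": [("ND1", "CG"), ("NE2", "CD2")],
    "W": [("NE1", "CD1")],
}

#: Hydrogen-bond acceptor heavy atoms per residue type.  The backbone
#: carbonyl O (and terminal OXT) accepts for every residue type.
SIDECHAIN_ACCEPTORS = {
    "D": ["OD1", "OD2"],
    "E": ["OE1", "OE2"],
    "N": ["OD1"],
    "Q": ["OE1"],
    "S": ["OG"],
    "T": ["OG1"],
    "Y": ["OH"],
    "H": ["ND1", "NE2"],
}


def donors(aa: str) -> list[tuple[str, str]]:
    """Donor (atom, antecedent) pairs for a residue type, backbone included."""
    out = [] if aa == "P" else [("N", "CA")]
    out.extend(SIDECHAIN_DONORS.get(aa, []))
    return out


def acceptors(aa: str) -> list[str]:
    """Acceptor heavy-atom names for a residue type, backbone included."""
    return ["O", "OXT"] + SIDECHAIN_ACCEPTORS.get(aa, [])
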