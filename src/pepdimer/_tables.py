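"""Fixed physical-constant tables shared across modules.

Atomic masses (u), Bondi van-der-Waals radii (Å) and the hydrogen-bond
donor/acceptor table for the residue types occurring in the studied
peptides (MSTYTGIFTDQ flanked by Cys in the cyclic chain).
"""

from __future__ import annotations

#: Atomic masses in unified atomic mass units.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: Bondi van-der-Waals radii in Å.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K: float = 0.0019872041

#: Atom names considered "backbone" for backbone-only selections.
BACKBONE_NAMES: frozenset[str] = frozenset({"N", "CA", "C", "O"})

# H-bond donor table: residue -> list of (heavy atom, [attached hydrogens]).
# Backbone N-H is handled separately (all residues except PRO).
SIDECHAIN_DONORS: dict[str, list[tuple[str, list[str]]]] = {
    "SER": [("OG", ["HG"])],
    "THR": [("OG1", ["HG1"])],
    "TYR": [("OH", ["HH"])],
    "CYS": [("SG", ["HG"])],
    "ASN": [("ND2", ["HD21", "HD22"])],
    "GLN": [("NE2", ["HE21", "HE22"])],
}

# H-bond acceptor table: residue -> side-chain acceptor atoms. Backbone
# carbonyl O (and terminal OXT) accepted for every residue.
SIDECHAIN_ACCEPTORS: dict[str, list[str]] = {
    "SER": ["OG"],
    "THR": ["OG1"],
    "TYR": ["OH"],
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"],
    "GLN": ["OE1"],
}

#: Aromatic ring heavy atoms used for minimum-contact distances.
RING_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

#: Residues forming the hydrophobic face of the studied peptides.
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset({"MET", "TYR", "ILE", "PHE"})

ONE_TO_THREE: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
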