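"""Compact chemical reference data.

A desk-scale subset of the information normally drawn from the PDB chemical
component dictionary (CCD): heavy-atom compositions of the standard amino
acids and nucleotides, parent codes for a few common modified residues,
residue-level atom-name symmetries, van der Waals radii for heuristic bond
perception, and a small table of ideal bond lengths/angles used by the
stereochemistry pre-checks.

The tables are deliberately small and shipped as plain Python data; a full
CCD can be supplied at runtime for exotic compounds (see
:class:`ChemCompDictionary` in :mod:`structscore.model`).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Heavy-atom composition of standard residues (PDB v3 atom names)
# ---------------------------------------------------------------------------

_BB = ["N", "CA", "C", "O"]

PEPTIDE_ATOMS: dict[str, list[str]] = {
    "GLY": _BB,
    "ALA": _BB + ["CB"],
    "SER": _BB + ["CB", "OG"],
    "CYS": _BB + ["CB", "SG"],
    "THR": _BB + ["CB", "OG1", "CG2"],
    "VAL": _BB + ["CB", "CG1", "CG2"],
    "LEU": _BB + ["CB", "CG", "CD1", "CD2"],
    "ILE": _BB + ["CB", "CG1", "CG2", "CD1"],
    "MET": _BB + ["CB", "CG", "SD", "CE"],
    "PRO": _BB + ["CB", "CG", "CD"],
    "PHE": _BB + ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": _BB + ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": _BB + ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "ASP": _BB + ["CB", "CG", "OD1", "OD2"],
    "GLU": _BB + ["CB", "CG", "CD", "OE1", "OE2"],
    "ASN": _BB + ["CB", "CG", "OD1", "ND2"],
    "GLN": _BB + ["CB", "CG", "CD", "OE1", "NE2"],
    "HIS": _BB + ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "LYS": _BB + ["CB", "CG", "CD", "CE", "NZ"],
    "ARG": _BB + ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
}

_SUGAR_RNA = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'"]
_SUGAR_DNA = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'"]

_PURINE_A = ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"]
_PURINE_G = ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"]
_PYRIMIDINE_C = ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"]
_PYRIMIDINE_U = ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"]
_PYRIMIDINE_T = ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"]

NUCLEOTIDE_ATOMS: dict[str, list[str]] = {
    "A": _SUGAR_RNA + _PURINE_A,
    "G": _SUGAR_RNA + _PURINE_G,
    "C": _SUGAR_RNA + _PYRIMIDINE_C,
    "U": _SUGAR_RNA + _PYRIMIDINE_U,
    "DA": _SUGAR_DNA + _PURINE_A,
    "DG": _SUGAR_DNA + _PURINE_G,
    "DC": _SUGAR_DNA + _PYRIMIDINE_C,
    "DT": _SUGAR_DNA + _PYRIMIDINE_T,
}

# Modified residues: own atom list plus parent code used by polymer cleanup.
# Atom lists are the parent's plus the modification; cleanup keeps only
# atoms present in the parent entry.
MODIFIED_RESIDUES: dict[str, tuple[str, list[str]]] = {
    "SEP": ("SER", PEPTIDE_ATOMS["SER"] + ["P", "O1P", "O2P", "O3P"]),
    "TPO": ("THR", PEPTIDE_ATOMS["THR"] + ["P", "O1P", "O2P", "O3P"]),
    "PTR": ("TYR", PEPTIDE_ATOMS["TYR"] + ["P", "O1P", "O2P", "O3P"]),
    "MSE": ("MET", [a if a != "SD" else "SE" for a in PEPTIDE_ATOMS["MET"]]),
    "PSU": ("U", NUCLEOTIDE_ATOMS["U"]),
}

ONE_LETTER: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "A": "A", "G": "G", "C": "C", "U": "U",
    "DA": "A", "DG": "G", "DC": "C", "DT": "T",
}

STANDARD_PEPTIDES = frozenset(PEPTIDE_ATOMS)
STANDARD_NUCLEOTIDES = frozenset(NUCLEOTIDE_ATOMS)

# Ions / simple nonpolymers commonly encountered; single atom, no bonds.
ION_CODES = frozenset({"MG", "ZN", "NA", "K", "CA", "FE", "CL", "MN", "CU"})

# ---------------------------------------------------------------------------
# Residue atom-name symmetries (chemically indistinguishable labelings)
# ---------------------------------------------------------------------------

# Each entry is a list of alternative atom-name permutations (the identity is
# implicit).  A permutation is a dict old-name -> new-name applied jointly.
RESIDUE_SYMMETRIES: dict[str, list[dict[str, str]]] = {
    "ASP": [{"OD1": "OD2", "OD2": "OD1"}],
    "GLU": [{"OE1": "OE2", "OE2": "OE1"}],
    "ARG": [{"NH1": "NH2", "NH2": "NH1"}],
    "PHE": [{"CD1": "CD2", "CD2": "CD1", "CE1": "CE2", "CE2": "CE1"}],
    "TYR": [{"CD1": "CD2", "CD2": "CD1", "CE1": "CE2", "CE2": "CE1"}],
}
_OP_SWAP = {"OP1": "OP2", "OP2": "OP1"}
for _code in NUCLEOTIDE_ATOMS:
    RESIDUE_SYMMETRIES[_code] = [dict(_OP_SWAP)]

# ---------------------------------------------------------------------------
# van der Waals radii (Å) for heuristic bond perception
# ---------------------------------------------------------------------------

VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "B": 1.92,
    "MG": 1.73, "ZN": 1.39, "FE": 1.52, "NA": 2.27, "K": 2.75,
    "CA": 2.31, "MN": 1.61, "CU": 1.40,
}

# Bond iff d < HEURISTIC_BOND_FACTOR * (r_i + r_j); last-resort path only.
HEURISTIC_BOND_FACTOR = 0.6

# ---------------------------------------------------------------------------
# Stereochemistry reference values (ideal value, standard deviation)
# ---------------------------------------------------------------------------

# Backbone + CA-CB bonds for peptides; sugar-phosphate bonds for nucleotides.
# Values are conventional small-molecule/protein averages.  Side chains past
# CB are covered by the clash check only.
PEPTIDE_BONDS: list[tuple[str, str, float, float]] = [
    ("N", "CA", 1.458, 0.019),
    ("CA", "C", 1.525, 0.021),
    ("C", "O", 1.231, 0.020),
    ("CA", "CB", 1.530, 0.020),
]
PEPTIDE_LINK_BOND = ("C", "N", 1.329, 0.014)  # inter-residue peptide bond

PEPTIDE_ANGLES: list[tuple[str, str, str, float, float]] = [
    ("N", "CA", "C", 111.0, 2.7),
    ("CA", "C", "O", 120.1, 2.1),
    ("N", "CA", "CB", 110.5, 1.7),
    ("C", "CA", "CB", 110.1, 1.9),
]

NUCLEOTIDE_BONDS: list[tuple[str, str, float, float]] = [
    ("P", "OP1", 1.485, 0.017),
    ("P", "OP2", 1.485, 0.017),
    ("P", "O5'", 1.593, 0.010),
    ("O5'", "C5'", 1.440, 0.016),
    ("C5'", "C4'", 1.510, 0.013),
    ("C4'", "O4'", 1.453, 0.012),
    ("C4'", "C3'", 1.524, 0.011),
    ("C3'", "O3'", 1.423, 0.014),
    ("C3'", "C2'", 1.525, 0.011),
    ("C2'", "O2'", 1.413, 0.013),
    ("C2'", "C1'", 1.528, 0.010),
    ("O4'", "C1'", 1.414, 0.012),
]
NUCLEOTIDE_LINK_BOND = ("O3'", "P", 1.607, 0.012)

NUCLEOTIDE_ANGLES: list[tuple[str, str, str, float, float]] = [
    ("C5'", "C4'", "C3'", 115.5, 1.5),
    ("C4'", "C3'", "C2'", 102.7, 1.0),
    ("C3'", "C2'", "C1'", 101.5, 0.9),
    ("C2'", "C1'", "O4'", 105.8, 1.0),
    ("C1'", "O4'", "C4'", 109.7, 0.9),
]

# Covalent radii for the clash criterion (clash when nonbonded atoms are
# closer than sum of covalent radii minus 0.4 Å).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "MG": 1.41, "ZN": 1.22, "FE": 1.32, "NA": 1.66, "K": 2.03,
    "CA": 1.76, "MN": 1.39, "CU": 1.32,
}


def element_of_atom_name(name: str) -> str:
    """Guess the element from a PDB-style atom name (fallback path only).

    Ambiguous two-letter names that collide with common polymer atom labels
    (e.g. ``CA``) resolve to the single-letter element.
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if len(stripped) == 2 and stripped in {"MG", "ZN", "NA", "FE", "MN", "CU", "CL", "BR", "SE"}:
        return stripped
    return stripped[0]
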