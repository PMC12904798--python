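"""In-memory structure model and polymer cleanup.

The data model is a thin hierarchy (Structure -> Chain -> Residue -> Atom)
tailored to benchmarking: residues carry author numbering plus insertion
codes, chains are typed as peptide / nucleotide / nonpolymer, and small
molecules live in a parallel ``ligands`` list (see
:class:`structscore.ligands.Ligand`).

Cleanup implements the preprocessing applied before any polymer score:
modified residues are replaced by their parent (e.g. phosphoserine SEP ->
SER), residues unknown to the component dictionary are dropped, hydrogens,
terminal OXT atoms and atoms whose names do not match the dictionary entry
are removed, and short chains (< 6 peptide residues, < 4 nucleotides) are
excluded from scoring.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

from . import chemdata

logger = logging.getLogger(__name__)

PEPTIDE = "peptide"
NUCLEOTIDE = "nucleotide"
NONPOLYMER = "nonpolymer"


@dataclass
class Atom:
    """A heavy (or hydrogen) atom with Cartesian coordinates in Å."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be 3 finite components")
        self.element = self.element.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    """A residue identified by (number, insertion code) within its chain."""

    name: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> tuple[int, str]:
        return (self.number, self.icode)

    @property
    def is_peptide(self) -> bool:
        return self.name in chemdata.STANDARD_PEPTIDES or (
            self.name in chemdata.MODIFIED_RESIDUES
            and chemdata.MODIFIED_RESIDUES[self.name][0] in chemdata.STANDARD_PEPTIDES
        )

    @property
    def is_nucleotide(self) -> bool:
        return self.name in chemdata.STANDARD_NUCLEOTIDES or (
            self.name in chemdata.MODIFIED_RESIDUES
            and chemdata.MODIFIED_RESIDUES[self.name][0] in chemdata.STANDARD_NUCLEOTIDES
        )

    @property
    def one_letter(self) -> str:
        code = self.name
        if code in chemdata.MODIFIED_RESIDUES:
            code = chemdata.MODIFIED_RESIDUES[code][0]
        return chemdata.ONE_LETTER.get(code, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def remove_atoms(self, names: Iterable[str]) -> None:
        drop = set(names)
        self.atoms = [a for a in self.atoms if a.name not in drop]

    def backbone_rep(self, chain_type: str) -> Optional[Atom]:
        """Representative backbone atom: Cα for peptides, C3′ for nucleotides."""
        return self.atom("CA" if chain_type == PEPTIDE else "C3'")

    def sidechain_rep(self) -> Optional[Atom]:
        """QS-score representative: Cβ, falling back to Cα (glycine)."""
        return self.atom("CB") or self.atom("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    chain_type: str = PEPTIDE
    entity_id: Optional[str] = None

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    ligands: list = field(default_factory=list)  # list[Ligand]
    source_format: str = "mmcif"
    name: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    @property
    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.chain_type != NONPOLYMER]

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


class ChemCompDictionary:
    """Lookup of per-compound atom names, bonds and parent residues.

    By default it is backed by the compact tables in
    :mod:`structscore.chemdata`.  Extra components (e.g. from a full CCD
    export) can be registered with :meth:`add_component`.
    """

    def __init__(self) -> None:
        self._atoms: dict[str, frozenset[str]] = {}
        self._parents: dict[str, str] = {}
        self._bonds: dict[str, list[tuple[str, str]]] = {}
        for code, names in chemdata.PEPTIDE_ATOMS.items():
            self._atoms[code] = frozenset(names)
        for code, names in chemdata.NUCLEOTIDE_ATOMS.items():
            self._atoms[code] = frozenset(names)
        for code, (parent, names) in chemdata.MODIFIED_RESIDUES.items():
            self._atoms[code] = frozenset(names)
            self._parents[code] = parent
        for code in chemdata.ION_CODES:
            self._atoms[code] = frozenset({code})
            self._bonds[code] = []

    def __contains__(self, code: str) -> bool:
        return code in self._atoms

    def atom_names(self, code: str) -> frozenset[str]:
        return self._atoms[code]

    def parent(self, code: str) -> Optional[str]:
        return self._parents.get(code)

    def bonds(self, code: str) -> Optional[list[tuple[str, str]]]:
        """Explicit bond list for a component, or None if unknown."""
        return self._bonds.get(code)

    def add_component(
        self,
        code: str,
        atom_names: Iterable[str],
        bonds: Optional[Iterable[tuple[str, str]]] = None,
        parent: Optional[str] = None,
    ) -> None:
        self._atoms[code] = frozenset(atom_names)
        if bonds is not None:
            self._bonds[code] = [tuple(b) for b in bonds]
        if parent is not None:
            self._parents[code] = parent


DEFAULT_DICTIONARY = ChemCompDictionary()

MIN_LEN_PEPTIDE = 6
MIN_LEN_NUCLEOTIDE = 4


def classify_chain_type(residues: Iterable[Residue]) -> str:
    """Type a chain from residue names (legacy PDB has no entity records).

    A chain is a nucleotide chain if at least half of its classifiable
    residues are nucleotides, a peptide chain if any residue is a standard
    amino acid, otherwise nonpolymer.
    """
    n_pep = sum(1 for r in residues if r.is_peptide)
    n_nuc = sum(1 for r in residues if r.is_nucleotide)
    if n_pep == 0 and n_nuc == 0:
        return NONPOLYMER
    return NUCLEOTIDE if n_nuc >= max(1, n_pep + n_nuc) * 0.5 and n_nuc >= n_pep else PEPTIDE


def cleanup_polymer(
    structure: Structure,
    dictionary: Optional[ChemCompDictionary] = None,
    replace_nonstandard: bool = True,
) -> Structure:
    """Preprocess polymer chains before scoring.  Total; removals are logged.

    With ``replace_nonstandard`` (polymer scores) modified residues are
    renamed to their parent and atoms absent from the parent are dropped;
    without it (ligand-score receptors) modified residues keep their identity
    but still lose hydrogens/OXT/unknown atoms.
    """
    dictionary = dictionary or DEFAULT_DICTIONARY
    out = structure.copy()
    kept_chains: list[Chain] = []
    for chain in out.chains:
        if chain.chain_type == NONPOLYMER:
            kept_chains.append(chain)
            continue
        new_residues: list[Residue] = []
        for res in chain.residues:
            if res.name not in dictionary:
                logger.info("cleanup: removing residue %s %s%s (no dictionary entry)",
                            res.name, res.number, res.icode)
                continue
            code = res.name
            parent = dictionary.parent(code)
            if replace_nonstandard and parent is not None:
                allowed = dictionary.atom_names(parent)
                res.name = parent
            else:
                allowed = dictionary.atom_names(code)
            removed = [a.name for a in res.atoms
                       if a.is_hydrogen or a.name == "OXT" or a.name not in allowed]
            if removed:
                logger.info("cleanup: residue %s %s%s: removing atoms %s",
                            res.name, res.number, res.icode, ",".join(removed))
                res.remove_atoms(removed)
            # collapse altloc duplicates: keep highest occupancy, tie -> first altloc
            seen: dict[str, Atom] = {}
            for a in res.atoms:
                prev = seen.get(a.name)
                if prev is None or a.occupancy > prev.occupancy or (
                        a.occupancy == prev.occupancy and a.altloc < prev.altloc):
                    seen[a.name] = a
            if len(seen) != len(res.atoms):
                res.atoms = [seen[a.name] for a in res.atoms if seen[a.name] is a]
            if res.atoms:
                new_residues.append(res)
        chain.residues = new_residues
        min_len = MIN_LEN_PEPTIDE if chain.chain_type == PEPTIDE else MIN_LEN_NUCLEOTIDE
        if len(chain.residues) < min_len:
            logger.info("cleanup: dropping chain %s (%d residues < %d)",
                        chain.id, len(chain.residues), min_len)
            continue
        kept_chains.append(chain)
    out.chains = kept_chains
    return out


def extract_sequence(chain: Chain) -> str:
    """One-letter sequence of a polymer chain; unknown residues become X."""
    if chain.chain_type == NONPOLYMER:
        raise ValueError(f"chain {chain.id} is not a polymer chain")
    return "".join(r.one_letter for r in chain.residues)
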