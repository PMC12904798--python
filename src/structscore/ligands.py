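"""Small-molecule ligand model, SDF V2000 I/O and graph matching.

Ligands are molecular graphs: element-labelled atoms plus explicit bonds.
Connectivity is taken, in order of preference, from an SDF file, from the
chemical component dictionary, or from a heuristic based on van der Waals
radii.  Matching between reference and model ligands is by graph
isomorphism (optionally subgraph isomorphism of the reference into the
model, for incomplete reference density), enumerated with element-labelled
nodes so every chemically equivalent atom correspondence — i.e. every
symmetry, such as a phenyl flip — is available to the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from . import chemdata
from .model import Atom

logger = logging.getLogger(__name__)


class SdfFormatError(ValueError):
    """Raised for malformed SDF input."""


@dataclass
class Ligand:
    """A small molecule: heavy atoms + explicit bonds (atom-index pairs)."""

    name: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    source: str = "sdf"  # sdf | ccd | heuristic
    chain_id: str = ""
    residue_number: int = 1
    # SDF bookkeeping, preserved but unused for matching
    charges: dict[int, int] = field(default_factory=dict)
    isotopes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"ligand {self.name}: bond ({i},{j}) out of range")

    @property
    def id(self) -> str:
        return f"{self.chain_id or '_'}.{self.name}.{self.residue_number}"

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, a in enumerate(self.atoms):
            g.add_node(i, element=a.element)
        g.add_edges_from(self.bonds)
        return g

    @property
    def n_fragments(self) -> int:
        g = self.graph()
        if g.number_of_nodes() == 0:
            return 0
        return nx.number_connected_components(g)


def heuristic_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Last-resort bond perception from van der Waals radii."""
    bonds = []
    for i in range(len(atoms)):
        ri = chemdata.VDW_RADII.get(atoms[i].element, 1.7)
        for j in range(i + 1, len(atoms)):
            rj = chemdata.VDW_RADII.get(atoms[j].element, 1.7)
            d = float(np.linalg.norm(atoms[i].pos - atoms[j].pos))
            if d < chemdata.HEURISTIC_BOND_FACTOR * (ri + rj):
                bonds.append((i, j))
    return bonds


# ---------------------------------------------------------------------------
# SDF V2000
# ---------------------------------------------------------------------------

def parse_sdf(text: str, name_hint: str = "") -> Ligand:
    """Parse the first molecule of an SDF/MOL V2000 block.

    Hydrogens are removed (only hydrogens are ever removed from ligands);
    charge and isotope annotations are preserved but play no role in
    matching.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise SdfFormatError("SDF input too short: missing header/counts line")
    name = lines[0].strip() or name_hint or "UNL"
    counts = lines[3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise SdfFormatError(f"unreadable counts line: {counts!r}") from exc
    atom_lines = lines[4:4 + n_atoms]
    if len(atom_lines) < n_atoms:
        raise SdfFormatError(
            f"counts line declares {n_atoms} atoms but atom block has {len(atom_lines)}")
    atoms: list[Atom] = []
    isotopes: dict[int, int] = {}
    charges: dict[int, int] = {}
    for idx, ln in enumerate(atom_lines):
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            elem = ln[31:34].strip()
        except (ValueError, IndexError) as exc:
            raise SdfFormatError(f"unreadable atom line {idx + 5}: {ln!r}") from exc
        if not elem or not elem[0].isalpha():
            raise SdfFormatError(f"atom line {idx + 5}: invalid element {elem!r}")
        mass_diff = ln[34:36].strip()
        chg = ln[36:39].strip()
        if mass_diff and mass_diff != "0":
            isotopes[idx] = int(mass_diff)
        if chg and chg != "0":
            # old-style charge codes: 1..7 map to +3..-3 (4 = radical)
            charges[idx] = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}.get(int(chg), 0)
        atoms.append(Atom(name=f"{elem.upper()}{idx + 1}", element=elem, pos=(x, y, z)))
    bond_lines = lines[4 + n_atoms:4 + n_atoms + n_bonds]
    if len(bond_lines) < n_bonds:
        raise SdfFormatError(
            f"counts line declares {n_bonds} bonds but bond block has {len(bond_lines)}")
    if n_bonds == 0 and n_atoms > 1:
        raise SdfFormatError("SDF molecule with several atoms lacks a bond block")
    bonds: list[tuple[int, int]] = []
    for ln in bond_lines:
        try:
            i, j = int(ln[0:3]) - 1, int(ln[3:6]) - 1
        except (ValueError, IndexError) as exc:
            raise SdfFormatError(f"unreadable bond line: {ln!r}") from exc
        if not (0 <= i < n_atoms and 0 <= j < n_atoms):
            raise SdfFormatError(f"bond references atom out of range: {ln!r}")
        bonds.append((i, j))
    # M  CHG lines override atom-block charges
    for ln in lines[4 + n_atoms + n_bonds:]:
        if ln.startswith("M  CHG"):
            parts = ln.split()
            n = int(parts[2])
            for k in range(n):
                charges[int(parts[3 + 2 * k]) - 1] = int(parts[4 + 2 * k])
        if ln.startswith("M  END") or ln.startswith("$$$$"):
            break
    # drop hydrogens, remapping bonds
    keep = [i for i, a in enumerate(atoms) if not a.is_hydrogen]
    remap = {old: new for new, old in enumerate(keep)}
    lig = Ligand(
        name=name,
        atoms=[atoms[i] for i in keep],
        bonds=[(remap[i], remap[j]) for i, j in bonds if i in remap and j in remap],
        source="sdf",
        charges={remap[i]: c for i, c in charges.items() if i in remap},
        isotopes={remap[i]: c for i, c in isotopes.items() if i in remap},
    )
    if lig.n_fragments > 1:
        logger.info("ligand %s: %d disconnected fragments", lig.name, lig.n_fragments)
    return lig


def read_ligand_sdf(path) -> Ligand:
    """Read a ligand (first molecule) from an SDF file."""
    with open(path) as fh:
        return parse_sdf(fh.read(), name_hint=str(path))


def write_sdf(ligand: Ligand, title: Optional[str] = None) -> str:
    """Serialize a ligand as an SDF V2000 block (fixture/report writer)."""
    out = [title or ligand.name, "  structscore", "", ]
    out.append(f"{len(ligand.atoms):3d}{len(ligand.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in ligand.atoms:
        el = a.element.capitalize()
        out.append(f"{a.pos[0]:10.4f}{a.pos[1]:10.4f}{a.pos[2]:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for i, j in ligand.bonds:
        out.append(f"{i + 1:3d}{j + 1:3d}  1  0")
    out.append("M  END")
    out.append("$$$$")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Graph matching
# ---------------------------------------------------------------------------

@dataclass
class LigandMatch:
    """Atom correspondences between a reference and a model ligand.

    ``correspondences`` maps reference atom index -> model atom index; one
    entry per graph (sub)isomorphism, i.e. per symmetry alternative.
    ``coverage`` is the fraction of model atoms covered by the reference.
    """

    reference_ligand: Ligand
    model_ligand: Ligand
    correspondences: list[dict[int, int]]
    coverage: float
    subgraph_mode: bool = False


class SymmetryCapExceeded(RuntimeError):
    """Too many graph isomorphisms; raise the symmetry cap to proceed."""


def match_ligands(
    reference_ligand: Ligand,
    model_ligand: Ligand,
    allow_subgraph: bool = False,
    max_symmetries: int = 100000,
) -> Optional[LigandMatch]:
    """Enumerate element-preserving atom correspondences, or None.

    Full graph isomorphism by default; with ``allow_subgraph`` the reference
    graph may be an (induced) subgraph of the model graph, which supports
    incomplete reference ligands while still requiring the model to contain
    the entire reference.
    """
    if not reference_ligand.atoms or not model_ligand.atoms:
        raise ValueError("cannot match empty ligands")
    g_ref = reference_ligand.graph()
    g_mdl = model_ligand.graph()
    node_match = nx.algorithms.isomorphism.categorical_node_match("element", "")
    gm = nx.algorithms.isomorphism.GraphMatcher(g_mdl, g_ref, node_match=node_match)
    correspondences: list[dict[int, int]] = []
    if allow_subgraph and g_ref.number_of_nodes() < g_mdl.number_of_nodes():
        it = gm.subgraph_isomorphisms_iter()
    elif g_ref.number_of_nodes() == g_mdl.number_of_nodes():
        it = gm.isomorphisms_iter()
    else:
        return None
    for mapping in it:  # mapping: model node -> ref node
        correspondences.append({r: m for m, r in mapping.items()})
        if len(correspondences) > max_symmetries:
            raise SymmetryCapExceeded(
                f"more than {max_symmetries} atom correspondences between "
                f"{reference_ligand.name} and {model_ligand.name}; raise max_symmetries")
    if not correspondences:
        return None
    coverage = len(reference_ligand.atoms) / len(model_ligand.atoms)
    return LigandMatch(
        reference_ligand=reference_ligand,
        model_ligand=model_ligand,
        correspondences=correspondences,
        coverage=coverage,
        subgraph_mode=allow_subgraph and g_ref.number_of_nodes() < g_mdl.number_of_nodes(),
    )
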