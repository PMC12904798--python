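"""Deterministic synthetic complexes and ligands with known ground truth.

Test inputs are generated, never downloaded: chains are laid out on
helix-like parametric curves and arranged on a cyclic ring so that adjacent
chains form interfaces; ligands are simple templated molecules (aromatic
ring, linear chain, single ion, disconnected fragments).  The generator is
fully deterministic given a seed, and every structure can be emitted as
mmCIF, legacy PDB or SDF text.  Coordinates are rounded to 0.001 Å so that
the text encodings round-trip bit-exactly.

These toys emulate the shape of the benchmarking problem (stoichiometry,
interfaces, symmetry, perturbations with known magnitude) — not protein
physics.  Stereochemistry is only approximate; purpose-built ideal/violating
fixtures are used for the stereochemistry checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ligands import Ligand
from .model import NUCLEOTIDE, PEPTIDE, Atom, Chain, Residue, Structure

# residues whose CCD entries contain at least N, CA, C, O, CB
_PEPTIDE_POOL = ["ALA", "SER", "VAL", "LEU", "THR", "ASP", "LYS", "PHE", "GLU", "ARG"]
_NUC_POOL = ["A", "U", "G", "C"]


def _round3(x: np.ndarray) -> np.ndarray:
    return np.round(x, 3)


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    return _rotation(axis, rng.uniform(0, 2 * np.pi))


@dataclass
class FixtureSpec:
    """Recipe for a synthetic reference/model pair.

    ``stoichiometry`` strings look like ``"A3"`` (homotrimer) or ``"A2B2"``;
    each entity letter gets its own random sequence.  Model-side
    perturbations are controlled individually; all randomness derives from
    ``seed``.
    """

    stoichiometry: str = "A2"
    chain_length: int = 12
    chain_type: str = PEPTIDE
    ring_spacing: float = 8.5      # Å between adjacent chain axes
    seed: int = 0
    # model perturbations
    noise_sigma: float = 0.0       # per-atom Gaussian noise, Å
    global_rigid: bool = False     # apply one rigid transform to whole model
    relabel: Optional[dict[str, str]] = None  # reference chain id -> model id
    displace_chain: Optional[str] = None      # chain id translated away
    displace_distance: float = 30.0
    hinge_chain: Optional[str] = None         # rotate last half of this chain
    hinge_angle_deg: float = 60.0
    drop_model_chains: tuple[str, ...] = ()   # chains removed from the model
    drop_reference_chains: tuple[str, ...] = ()


@dataclass
class FixtureTruth:
    """Ground truth associated with a generated pair."""

    mapping: dict[str, str]            # reference chain id -> model chain id
    entities: dict[str, str]           # chain id -> entity letter
    expected_identity: bool            # model congruent to reference per chain


def parse_stoichiometry(stoich: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    i = 0
    while i < len(stoich):
        letter = stoich[i]
        i += 1
        num = ""
        while i < len(stoich) and stoich[i].isdigit():
            num += stoich[i]
            i += 1
        out.append((letter, int(num or "1")))
    return out


def _entity_sequence(letter: str, length: int, chain_type: str, seed: int) -> list[str]:
    rng = np.random.default_rng((seed * 131 + ord(letter)) % (2 ** 31))
    pool = _PEPTIDE_POOL if chain_type == PEPTIDE else _NUC_POOL
    return [pool[k] for k in rng.integers(0, len(pool), size=length)]


def _peptide_residue(name: str, number: int, ca: np.ndarray,
                     tangent: np.ndarray, normal: np.ndarray) -> Residue:
    res = Residue(name=name, number=number)
    binormal = np.cross(tangent, normal)
    offsets = {
        "N": -0.7 * tangent + 1.2 * normal,
        "CA": np.zeros(3),
        "C": 0.8 * tangent + 1.1 * normal,
        "O": 0.9 * tangent + 2.3 * normal,
        "CB": 1.2 * binormal - 0.8 * normal,
    }
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
    for an, off in offsets.items():
        res.atoms.append(Atom(name=an, element=elements[an], pos=_round3(ca + off)))
    return res


def _nucleotide_residue(name: str, number: int, c3: np.ndarray,
                        tangent: np.ndarray, normal: np.ndarray) -> Residue:
    res = Residue(name=name, number=number)
    binormal = np.cross(tangent, normal)
    offsets = {
        "P": -1.8 * tangent + 1.6 * normal,
        "OP1": -2.2 * tangent + 2.5 * normal + 0.9 * binormal,
        "OP2": -2.2 * tangent + 2.5 * normal - 0.9 * binormal,
        "O5'": -1.2 * tangent + 0.9 * normal,
        "C5'": -0.8 * tangent + 0.3 * normal,
        "C4'": -0.4 * tangent,
        "C3'": np.zeros(3),
        "O3'": 0.9 * tangent - 0.6 * normal,
        "C2'": 0.4 * tangent + 1.2 * binormal,
        "C1'": -0.3 * tangent + 2.0 * binormal,
        "N1": 0.1 * tangent + 3.2 * binormal,
    }
    elements = {k: ("P" if k == "P" else ("O" if k.startswith("O") else
                    ("N" if k.startswith("N") else "C"))) for k in offsets}
    for an, off in offsets.items():
        res.atoms.append(Atom(name=an, element=elements[an], pos=_round3(c3 + off)))
    return res


def _build_chain(cid: str, names: list[str], chain_type: str,
                 origin: np.ndarray, azimuth: float) -> Chain:
    """A helix-like chain climbing in z, rotated to ``azimuth`` on the ring."""
    chain = Chain(id=cid, chain_type=chain_type)
    rot = _rotation(np.array([0.0, 0.0, 1.0]), azimuth)
    radius, turn, rise = (2.3, np.deg2rad(100.0), 1.5) if chain_type == PEPTIDE \
        else (4.0, np.deg2rad(40.0), 2.8)
    for i, name in enumerate(names):
        theta = turn * i
        local = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        d_local = np.array([-radius * turn * np.sin(theta),
                            radius * turn * np.cos(theta), rise])
        tangent = d_local / np.linalg.norm(d_local)
        normal = np.array([np.cos(theta), np.sin(theta), 0.0])
        pos = rot @ local + origin
        tangent = rot @ tangent
        normal = rot @ normal
        if chain_type == PEPTIDE:
            chain.residues.append(_peptide_residue(name, i + 1, pos, tangent, normal))
        else:
            chain.residues.append(_nucleotide_residue(name, i + 1, pos, tangent, normal))
    return chain


def make_reference(spec: FixtureSpec) -> tuple[Structure, dict[str, str]]:
    """Build the reference complex; returns (structure, chain -> entity)."""
    entities = parse_stoichiometry(spec.stoichiometry)
    seqs = {letter: _entity_sequence(letter, spec.chain_length, spec.chain_type, spec.seed)
            for letter, _ in entities}
    # interleave entity copies around the ring to guarantee hetero interfaces
    order: list[str] = []
    counters = {letter: count for letter, count in entities}
    while any(c > 0 for c in counters.values()):
        for letter, _ in entities:
            if counters[letter] > 0:
                order.append(letter)
                counters[letter] -= 1
    n = len(order)
    chain_ids = [chr(ord("A") + k) for k in range(n)]
    structure = Structure(name=f"ref_{spec.stoichiometry}_{spec.seed}")
    entity_of: dict[str, str] = {}
    if n == 1:
        placements = [(np.zeros(3), 0.0)]
    else:
        ring_r = spec.ring_spacing / (2.0 * np.sin(np.pi / n))
        placements = [(np.array([ring_r * np.cos(2 * np.pi * k / n),
                                 ring_r * np.sin(2 * np.pi * k / n), 0.0]),
                       2 * np.pi * k / n) for k in range(n)]
    for cid, letter, (origin, az) in zip(chain_ids, order, placements):
        chain = _build_chain(cid, seqs[letter], spec.chain_type, origin, az)
        if cid in spec.drop_reference_chains:
            continue
        structure.chains.append(chain)
        entity_of[cid] = letter
    return structure, entity_of


def _transform_structure(structure: Structure, rot: np.ndarray, trans: np.ndarray) -> None:
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                a.pos = _round3(rot @ a.pos + trans)
    for lig in structure.ligands:
        for a in lig.atoms:
            a.pos = _round3(rot @ a.pos + trans)


def make_complex(spec: FixtureSpec) -> tuple[Structure, Structure, FixtureTruth]:
    """Generate a (reference, model, truth) triple from a spec."""
    reference, entity_of = make_reference(spec)
    model_spec = FixtureSpec(**{**spec.__dict__, "drop_reference_chains": ()})
    model, _ = make_reference(model_spec)
    model.name = f"mdl_{spec.stoichiometry}_{spec.seed}"
    rng = np.random.default_rng(spec.seed + 7)

    model.chains = [c for c in model.chains if c.id not in spec.drop_model_chains]

    if spec.hinge_chain is not None:
        chain = model.chain(spec.hinge_chain)
        if chain is not None:
            half = len(chain.residues) // 2
            pivot = np.array(chain.residues[half].atoms[0].pos, dtype=float)
            rot = _rotation(np.array([1.0, 0.0, 0.0]), np.deg2rad(spec.hinge_angle_deg))
            for res in chain.residues[half:]:
                for a in res.atoms:
                    a.pos = _round3(rot @ (a.pos - pivot) + pivot)
    if spec.displace_chain is not None:
        chain = model.chain(spec.displace_chain)
        if chain is not None:
            shift = np.array([spec.displace_distance, 0.0, 0.0])
            for res in chain.residues:
                for a in res.atoms:
                    a.pos = _round3(a.pos + shift)
    if spec.noise_sigma > 0:
        for chain in model.chains:
            for res in chain.residues:
                for a in res.atoms:
                    a.pos = _round3(a.pos + rng.normal(0, spec.noise_sigma, 3))
    if spec.global_rigid:
        _transform_structure(model, random_rotation(rng), rng.uniform(-20, 20, 3))

    mapping = {c.id: c.id for c in reference.chains if model.chain(c.id) is not None}
    if spec.relabel:
        for chain in model.chains:
            chain.id = spec.relabel.get(chain.id, chain.id)
        mapping = {ref: spec.relabel.get(ref, ref) for ref in mapping}
    truth = FixtureTruth(
        mapping=mapping,
        entities=entity_of,
        expected_identity=(spec.noise_sigma == 0 and spec.hinge_chain is None
                           and spec.displace_chain is None),
    )
    return reference, model, truth


# ---------------------------------------------------------------------------
# Ligand templates
# ---------------------------------------------------------------------------

def make_ligand(template: str = "ring",
                rot: Optional[np.ndarray] = None,
                trans: Optional[np.ndarray] = None,
                name: Optional[str] = None) -> Ligand:
    """Templated ligand: ``ring`` (aromatic C6), ``linear`` (C-C-C-O),
    ``ion`` (Mg) or ``fragments`` (ring plus a distant 2-atom piece)."""
    if template == "ring":
        r = 1.39
        atoms = [Atom(name=f"C{i+1}", element="C",
                      pos=_round3(np.array([r * np.cos(i * np.pi / 3),
                                            r * np.sin(i * np.pi / 3), 0.0])))
                 for i in range(6)]
        bonds = [(i, (i + 1) % 6) for i in range(6)]
    elif template == "linear":
        coords = [(0.0, 0.0, 0.0), (1.5, 0.0, 0.0), (2.3, 1.3, 0.0), (3.7, 1.3, 0.4)]
        elems = ["C", "C", "C", "O"]
        atoms = [Atom(name=f"{e}{i+1}", element=e, pos=_round3(np.array(c)))
                 for i, (e, c) in enumerate(zip(elems, coords))]
        bonds = [(0, 1), (1, 2), (2, 3)]
    elif template == "ion":
        atoms = [Atom(name="MG", element="MG", pos=np.zeros(3))]
        bonds = []
    elif template == "fragments":
        ring = make_ligand("ring")
        atoms = list(ring.atoms)
        far = np.array([12.0, 0.0, 0.0])
        atoms.append(Atom(name="C7", element="C", pos=_round3(far)))
        atoms.append(Atom(name="O8", element="O", pos=_round3(far + [1.4, 0, 0])))
        bonds = list(ring.bonds) + [(6, 7)]
    else:
        raise ValueError(f"unknown ligand template {template!r}")
    lig = Ligand(name=name or {"ring": "RNG", "linear": "LIN", "ion": "MG",
                               "fragments": "FRG"}[template],
                 atoms=atoms, bonds=bonds, source="sdf", chain_id="L")
    if rot is not None or trans is not None:
        rot = np.eye(3) if rot is None else rot
        trans = np.zeros(3) if trans is None else np.asarray(trans, dtype=float)
        for a in lig.atoms:
            a.pos = _round3(rot @ a.pos + trans)
    return lig


def place_ligand_near_chain(ligand: Ligand, chain: Chain, distance: float = 3.5,
                            residue_index: Optional[int] = None) -> Ligand:
    """Translate a ligand so its centroid sits ``distance`` Å outward from a
    chain residue's Cβ/Cα (or C3′) position."""
    idx = residue_index if residue_index is not None else len(chain.residues) // 2
    res = chain.residues[idx]
    anchor_atom = res.sidechain_rep() or res.atoms[0]
    anchor = np.array(anchor_atom.pos, dtype=float)
    center = np.mean([a.pos for a in chain.residues[idx].atoms], axis=0)
    outward = anchor - center
    nrm = np.linalg.norm(outward)
    outward = outward / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
    lig_centroid = np.mean([a.pos for a in ligand.atoms], axis=0)
    shift = anchor + outward * distance - lig_centroid
    for a in ligand.atoms:
        a.pos = _round3(a.pos + shift)
    return ligand
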