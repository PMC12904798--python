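"""Local distance difference test (LDDT) for proteins and nucleotides.

LDDT measures how well a model preserves the reference's interatomic
distances: every heavy-atom pair within an inclusion radius (15 Å by
default, 30 Å when nucleotides are involved) and not within one residue is
a *contact*; a contact is preserved at a threshold t when the model
reproduces its distance within t.  The score is the fraction of preserved
contacts averaged over the thresholds 0.5, 1, 2 and 4 Å.  Contacts whose
model atoms are missing count as unpreserved.

Variants: ``backbone`` restricts contacts to representative backbone atoms
(Cα for peptides, C3′ for nucleotides); ``interface_only`` (i-LDDT) keeps
only inter-chain contacts.  Atom-name symmetries within residues (e.g.
glutamate OE1/OE2, nucleotide OP1/OP2) are resolved per residue, choosing
the chemically equivalent relabeling that maximizes that residue's
preserved contacts.  An optional stereochemistry pre-check removes model
side chains/residues with badly distorted bonds, angles or clashes so that
their contacts score as unpreserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .grouping import PairAlignment
from .model import NONPOLYMER, NUCLEOTIDE, PEPTIDE, Chain, Residue, Structure

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class LddtParams:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    variant: str = "full"  # full | backbone | interface_only
    stereo_checks: bool = False
    stereo_tolerance: float = 12.0  # standard deviations
    symmetry: bool = True

    def __post_init__(self) -> None:
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be ascending")
        if self.inclusion_radius <= max(self.thresholds):
            raise ValueError("inclusion radius must exceed the largest threshold")


AtomKey = tuple[str, int, str]  # (chain id, residue index within chain, atom name)


@dataclass
class ContactTable:
    """Reference contacts: atom keys, coordinates and within-radius pairs."""

    atom_keys: list[AtomKey]
    coords: np.ndarray                 # (n_atoms, 3)
    pairs: np.ndarray                  # (n_contacts, 2) int indices, i < j
    distances: np.ndarray              # (n_contacts,)
    inter_chain: np.ndarray            # (n_contacts,) bool
    params: LddtParams
    residue_names: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)


def _select_atoms(structure: Structure, variant: str) -> tuple[list[AtomKey], np.ndarray]:
    keys: list[AtomKey] = []
    coords: list[np.ndarray] = []
    for chain in structure.polymer_chains:
        for ri, res in enumerate(chain.residues):
            if variant == "backbone":
                atoms = [a for a in (res.backbone_rep(chain.chain_type),) if a is not None]
            else:
                atoms = [a for a in res.atoms if not a.is_hydrogen]
            for a in atoms:
                keys.append((chain.id, ri, a.name))
                coords.append(a.pos)
    return keys, np.array(coords, dtype=float) if coords else np.zeros((0, 3))


def build_contact_table(reference: Structure, params: Optional[LddtParams] = None) -> ContactTable:
    """All reference heavy-atom pairs within the inclusion radius, excluding
    intra-residue pairs (and intra-chain pairs for the interface variant)."""
    params = params or LddtParams()
    keys, coords = _select_atoms(reference, params.variant)
    res_names = {(c.id, ri): r.name for c in reference.polymer_chains
                 for ri, r in enumerate(c.residues)}
    if len(keys) == 0:
        return ContactTable(keys, coords, np.zeros((0, 2), dtype=int),
                            np.zeros(0), np.zeros(0, dtype=bool), params, res_names)
    tree = cKDTree(coords)
    raw = tree.query_pairs(params.inclusion_radius, output_type="ndarray")
    if len(raw):
        same_residue = np.array([keys[i][:2] == keys[j][:2] for i, j in raw])
        raw = raw[~same_residue]
    inter = np.array([keys[i][0] != keys[j][0] for i, j in raw], dtype=bool) \
        if len(raw) else np.zeros(0, dtype=bool)
    if params.variant == "interface_only":
        raw = raw[inter]
        inter = np.ones(len(raw), dtype=bool)
    dists = np.linalg.norm(coords[raw[:, 0]] - coords[raw[:, 1]], axis=1) \
        if len(raw) else np.zeros(0)
    return ContactTable(keys, coords, raw, dists, inter, params, res_names)


@dataclass
class LddtResult:
    """Overall and per-residue LDDT.  ``score`` is None when no reference
    contact exists (not computable — distinct from 0)."""

    score: Optional[float]
    per_threshold: Optional[list[float]]
    per_residue: dict[tuple[str, int], Optional[float]]
    n_contacts: int
    reason: Optional[str] = None


def _model_positions(
    table: ContactTable,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
) -> tuple[np.ndarray, dict[tuple[str, int], Residue], dict[tuple[str, int], list[int]]]:
    """Model coordinates per reference atom index (NaN when missing), the
    model residue matched to each reference residue, and atom indices per
    reference residue."""
    n = len(table.atom_keys)
    pos = np.full((n, 3), np.nan)
    res_map: dict[tuple[str, int], Residue] = {}
    atoms_of_res: dict[tuple[str, int], list[int]] = {}
    mdl_chains = {c.id: c for c in model.polymer_chains}
    pair_lookup: dict[str, dict[int, int]] = {}
    for ref_cid, mdl_cid in mapping.items():
        aln = alignments.get(ref_cid)
        if aln is None or mdl_cid not in mdl_chains:
            continue
        pair_lookup[ref_cid] = dict(aln.pairs)
    for idx, (cid, ri, aname) in enumerate(table.atom_keys):
        atoms_of_res.setdefault((cid, ri), []).append(idx)
        lut = pair_lookup.get(cid)
        if lut is None or ri not in lut:
            continue
        mdl_chain = mdl_chains[mapping[cid]]
        mdl_res = mdl_chain.residues[lut[ri]]
        res_map[(cid, ri)] = mdl_res
        atom = mdl_res.atom(aname)
        if atom is not None:
            pos[idx] = atom.pos
    return pos, res_map, atoms_of_res


def _preserved_counts(table: ContactTable, pos: np.ndarray,
                      rows: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-threshold preserved-contact counts for all (or selected) rows."""
    pairs = table.pairs if rows is None else table.pairs[rows]
    dists = table.distances if rows is None else table.distances[rows]
    d_mdl = np.linalg.norm(pos[pairs[:, 0]] - pos[pairs[:, 1]], axis=1)
    delta = np.abs(d_mdl - dists)  # NaN when a model atom is missing
    with np.errstate(invalid="ignore"):
        return np.array([(delta <= t).sum() for t in table.params.thresholds])


def _resolve_symmetries(table: ContactTable, pos: np.ndarray,
                        res_map: dict[tuple[str, int], Residue],
                        atoms_of_res: dict[tuple[str, int], list[int]]) -> None:
    """Greedy per-residue choice among chemically equivalent atom
    relabelings of the model residue; ties keep the identity labeling."""
    contacts_of_atom: dict[int, list[int]] = {}
    for row, (i, j) in enumerate(table.pairs):
        contacts_of_atom.setdefault(int(i), []).append(row)
        contacts_of_atom.setdefault(int(j), []).append(row)
    for (cid, ri), mdl_res in res_map.items():
        perms = chemdata.RESIDUE_SYMMETRIES.get(table.residue_names.get((cid, ri), ""))
        if not perms:
            continue
        idxs = atoms_of_res.get((cid, ri), [])
        rows = sorted({r for idx in idxs for r in contacts_of_atom.get(idx, [])})
        if not rows:
            continue
        rows_arr = np.array(rows, dtype=int)
        name_to_idx = {table.atom_keys[idx][2]: idx for idx in idxs}
        base = _preserved_counts(table, pos, rows_arr).sum()
        best_perm = None
        best = base
        for perm in perms:
            alt = pos.copy()
            applicable = False
            for old, new in perm.items():
                if old in name_to_idx:
                    src = mdl_res.atom(new)
                    alt[name_to_idx[old]] = src.pos if src is not None else np.nan
                    applicable = True
            if not applicable:
                continue
            count = _preserved_counts(table, alt, rows_arr).sum()
            if count > best:
                best = count
                best_perm = perm
        if best_perm is not None:
            for old, new in best_perm.items():
                if old in name_to_idx:
                    src = mdl_res.atom(new)
                    pos[name_to_idx[old]] = src.pos if src is not None else np.nan


def lddt(
    model: Structure,
    table: ContactTable,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
    params: Optional[LddtParams] = None,
) -> LddtResult:
    """LDDT of a model against a precomputed reference contact table.

    ``mapping`` is the reference-chain -> model-chain assignment and
    ``alignments`` the per-reference-chain residue correspondences (keyed by
    reference chain id).
    """
    params = params or table.params
    per_res_keys = sorted({(cid, ri) for cid, ri, _ in table.atom_keys})
    if table.n_contacts == 0:
        return LddtResult(None, None, {k: None for k in per_res_keys}, 0,
                          reason="no reference contacts within inclusion radius")
    work_model = model
    if params.stereo_checks:
        work_model, _ = stereo_filter(model, tolerance=params.stereo_tolerance)
    pos, res_map, atoms_of_res = _model_positions(table, work_model, mapping, alignments)
    if params.symmetry:
        _resolve_symmetries(table, pos, res_map, atoms_of_res)
    counts = _preserved_counts(table, pos)
    fractions = counts / table.n_contacts
    # per-residue: every contact contributes to both residues
    d_mdl = np.linalg.norm(pos[table.pairs[:, 0]] - pos[table.pairs[:, 1]], axis=1)
    delta = np.abs(d_mdl - table.distances)
    res_index = {key: k for k, key in enumerate(per_res_keys)}
    totals = np.zeros(len(per_res_keys))
    preserved = np.zeros(len(per_res_keys))
    for row, (i, j) in enumerate(table.pairs):
        p = sum(1 for t in params.thresholds if delta[row] <= t) \
            if np.isfinite(delta[row]) else 0
        for idx in (int(i), int(j)):
            key = table.atom_keys[idx][:2]
            totals[res_index[key]] += len(params.thresholds)
            preserved[res_index[key]] += p
    per_residue = {key: (preserved[k] / totals[k] if totals[k] else None)
                   for key, k in res_index.items()}
    return LddtResult(float(fractions.mean()), [float(f) for f in fractions],
                      per_residue, table.n_contacts)


def lddt_score(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
    params: Optional[LddtParams] = None,
) -> LddtResult:
    """Convenience wrapper: build the contact table and score in one call."""
    params = params or default_params_for(reference)
    table = build_contact_table(reference, params)
    return lddt(model, table, mapping, alignments, params)


def default_params_for(reference: Structure, variant: str = "full") -> LddtParams:
    """Default LDDT parameters: 15 Å inclusion radius, or 30 Å as soon as
    nucleotide chains are involved."""
    has_nuc = any(c.chain_type == NUCLEOTIDE for c in reference.polymer_chains)
    return LddtParams(inclusion_radius=30.0 if has_nuc else 15.0, variant=variant)


# ---------------------------------------------------------------------------
# Stereochemistry pre-checks
# ---------------------------------------------------------------------------

@dataclass
class StereoViolation:
    chain_id: str
    residue_number: int
    kind: str        # bond | angle | clash
    detail: str
    deviation_sd: float


_PEP_SIDECHAIN_SAFE = {"N", "CA", "C", "O"}


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def stereo_filter(model: Structure, tolerance: float = 12.0,
                  clash_slack: float = 0.4) -> tuple[Structure, list[StereoViolation]]:
    """Remove model atoms with serious stereochemical irregularities.

    Bond lengths and angles are compared against the ideal-value table;
    deviations beyond ``tolerance`` standard deviations are violations.
    Nonbonded heavy-atom pairs closer than the sum of covalent radii minus
    ``clash_slack`` are clashes.  Side-chain violations remove the side
    chain; backbone violations remove the residue.  The filter is total and
    returns the violation report alongside the filtered structure.
    """
    out = model.copy()
    violations: list[StereoViolation] = []
    for chain in out.polymer_chains:
        is_pep = chain.chain_type == PEPTIDE
        bonds = chemdata.PEPTIDE_BONDS if is_pep else chemdata.NUCLEOTIDE_BONDS
        angles = chemdata.PEPTIDE_ANGLES if is_pep else chemdata.NUCLEOTIDE_ANGLES
        link = chemdata.PEPTIDE_LINK_BOND if is_pep else chemdata.NUCLEOTIDE_LINK_BOND
        drop_side: set[int] = set()
        drop_res: set[int] = set()
        for ri, res in enumerate(chain.residues):
            for a1, a2, ideal, sd in bonds:
                p1, p2 = res.atom(a1), res.atom(a2)
                if p1 is None or p2 is None:
                    continue
                dev = abs(float(np.linalg.norm(p1.pos - p2.pos)) - ideal) / sd
                if dev > tolerance:
                    violations.append(StereoViolation(chain.id, res.number, "bond",
                                                      f"{a1}-{a2}", dev))
                    if is_pep and a2 == "CB":
                        drop_side.add(ri)
                    else:
                        drop_res.add(ri)
            for a1, a2, a3, ideal, sd in angles:
                p = [res.atom(x) for x in (a1, a2, a3)]
                if any(x is None for x in p):
                    continue
                dev = abs(_angle(p[0].pos, p[1].pos, p[2].pos) - ideal) / sd
                if dev > tolerance:
                    violations.append(StereoViolation(chain.id, res.number, "angle",
                                                      f"{a1}-{a2}-{a3}", dev))
                    if is_pep and "CB" in (a1, a2, a3):
                        drop_side.add(ri)
                    else:
                        drop_res.add(ri)
            if ri + 1 < len(chain.residues):
                nxt = chain.residues[ri + 1]
                p1, p2 = res.atom(link[0]), nxt.atom(link[1])
                if p1 is not None and p2 is not None:
                    d = float(np.linalg.norm(p1.pos - p2.pos))
                    # a broken chain (distance far beyond bonding) is a gap,
                    # not a stereochemistry violation
                    if d < 2.5:
                        dev = abs(d - link[2]) / link[3]
                        if dev > tolerance:
                            violations.append(StereoViolation(
                                chain.id, res.number, "bond",
                                f"{link[0]}-{link[1]}(+1)", dev))
                            drop_res.add(ri)
        for ri in drop_res:
            chain.residues[ri].atoms = []
            logger.info("stereo: removing residue %s %s", chain.id,
                        chain.residues[ri].number)
        for ri in drop_side - drop_res:
            res = chain.residues[ri]
            res.atoms = [a for a in res.atoms if a.name in _PEP_SIDECHAIN_SAFE]
            logger.info("stereo: removing side chain %s %s", chain.id, res.number)
        # emptied residues stay as placeholders so residue indices (and any
        # precomputed alignments) remain valid
    # clash check across all polymer atoms (unchanged classic criterion)
    keys, coords = _select_atoms(out, "full")
    if len(keys):
        tree = cKDTree(coords)
        clash_atoms: set[int] = set()
        for i, j in tree.query_pairs(3.0):
            if keys[i][:2] == keys[j][:2]:
                continue
            ci, ri_, ni = keys[i]
            cj, rj_, nj = keys[j]
            # skip the peptide/phosphodiester link between consecutive residues
            if ci == cj and abs(ri_ - rj_) == 1 and {ni, nj} & {"C", "N", "O3'", "P"}:
                continue
            ei = chemdata.COVALENT_RADII.get(_elem_of(out, keys[i]), 0.77)
            ej = chemdata.COVALENT_RADII.get(_elem_of(out, keys[j]), 0.77)
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d < ei + ej - clash_slack:
                clash_atoms.update((i, j))
                violations.append(StereoViolation(ci, 0, "clash",
                                                  f"{ci}{ri_}:{ni}~{cj}{rj_}:{nj}", d))
        if clash_atoms:
            by_res: dict[tuple[str, int], set[str]] = {}
            for idx in clash_atoms:
                cid, ri_, name = keys[idx]
                by_res.setdefault((cid, ri_), set()).add(name)
            for (cid, ri_), names in by_res.items():
                chain = out.chain(cid)
                res = chain.residues[ri_]
                res.atoms = [a for a in res.atoms if a.name not in names]
    return out, violations


def _elem_of(structure: Structure, key: AtomKey) -> str:
    chain = structure.chain(key[0])
    atom = chain.residues[key[1]].atom(key[2])
    return atom.element if atom is not None else "C"
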