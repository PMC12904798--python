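"""DockQ-family scores for dimeric interfaces: fnat, i-RMSD, L-RMSD, DockQ.

The CAPRI-derived components are computed on one interface (two mapped
chain pairs):

* fnat — fraction of reference (native) residue contacts reproduced by the
  model; contacts are residue pairs with any heavy-atom pair within 5 Å.
* i-RMSD — backbone RMSD over interface residues (reference residues with
  any heavy atom within 10 Å of the partner chain) after superposing the
  interface backbones.
* L-RMSD — backbone RMSD of the smaller ("ligand") chain after superposing
  the larger ("receptor") chain.
* DockQ = (fnat + 1/(1+(iRMSD/1.5)^2) + 1/(1+(LRMSD/8.5)^2)) / 3.

The CAPRI peptide parameterization (``capri_peptide``) tightens the contact
distance to 4 Å and the interface definition to Cβ within 8 Å (Cα for
glycine).  DockQ-ave / DockQ-wave aggregate per-interface DockQ values over
higher-order assemblies (plain mean, and mean weighted by the number of
native contacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .grouping import PairAlignment
from .model import Chain, NUCLEOTIDE, Structure
from .superpose import apply_transform, kabsch, rmsd

BACKBONE_PEPTIDE = ("N", "CA", "C", "O")
BACKBONE_NUCLEOTIDE = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                       "C3'", "O3'", "C2'", "O2'", "C1'")


@dataclass
class DockQComponents:
    fnat: float
    fnonnat: float
    i_rmsd: Optional[float]
    l_rmsd: Optional[float]
    dockq: Optional[float]
    n_native_contacts: int
    n_model_contacts: int
    receptor: str = ""
    ligand: str = ""


def _residue_contact_pairs(chain_a: Chain, chain_b: Chain, dist: float) -> set[tuple[int, int]]:
    coords_a, idx_a = [], []
    for i, res in enumerate(chain_a.residues):
        for a in res.atoms:
            if not a.is_hydrogen:
                coords_a.append(a.pos)
                idx_a.append(i)
    coords_b, idx_b = [], []
    for j, res in enumerate(chain_b.residues):
        for a in res.atoms:
            if not a.is_hydrogen:
                coords_b.append(a.pos)
                idx_b.append(j)
    if not coords_a or not coords_b:
        return set()
    tree_b = cKDTree(np.asarray(coords_b))
    out: set[tuple[int, int]] = set()
    for ai, neighbours in enumerate(cKDTree(np.asarray(coords_a)).query_ball_tree(tree_b, dist)):
        for bj in neighbours:
            out.add((idx_a[ai], idx_b[bj]))
    return out


def _backbone(res, chain_type: str) -> list:
    names = BACKBONE_PEPTIDE if chain_type != NUCLEOTIDE else BACKBONE_NUCLEOTIDE
    return [res.atom(n) for n in names if res.atom(n) is not None]


def _interface_residues(chain_a: Chain, chain_b: Chain, dist: float,
                        cb_only: bool) -> tuple[set[int], set[int]]:
    def rep_coords(chain):
        coords, idx = [], []
        for i, res in enumerate(chain.residues):
            atoms = [res.sidechain_rep()] if cb_only else res.atoms
            for a in atoms:
                if a is not None and not a.is_hydrogen:
                    coords.append(a.pos)
                    idx.append(i)
        return np.asarray(coords), idx

    ca_, ia = rep_coords(chain_a)
    cb_, ib = rep_coords(chain_b)
    res_a: set[int] = set()
    res_b: set[int] = set()
    if len(ca_) == 0 or len(cb_) == 0:
        return res_a, res_b
    tree_b = cKDTree(cb_)
    for k, neighbours in enumerate(cKDTree(ca_).query_ball_tree(tree_b, dist)):
        if neighbours:
            res_a.add(ia[k])
            res_b.update(ib[j] for j in neighbours)
    return res_a, res_b


def dockq(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
    interface: tuple[str, str],
    capri_peptide: bool = False,
) -> DockQComponents:
    """DockQ components for one reference chain pair.

    The larger reference chain acts as receptor, the smaller as ligand
    (ties: lexicographically smaller chain id is the receptor).
    """
    ra, rb = interface
    ref_a, ref_b = reference.chain(ra), reference.chain(rb)
    if ref_a is None or ref_b is None or ra not in mapping or rb not in mapping:
        raise ValueError(f"interface {interface} is not fully mapped")
    mdl_a, mdl_b = model.chain(mapping[ra]), model.chain(mapping[rb])
    aln_a, aln_b = dict(alignments[ra].pairs), dict(alignments[rb].pairs)

    contact_dist = 4.0 if capri_peptide else 5.0
    native = _residue_contact_pairs(ref_a, ref_b, contact_dist)
    model_pairs_raw = _residue_contact_pairs(mdl_a, mdl_b, contact_dist)
    inv_a = {v: k for k, v in aln_a.items()}
    inv_b = {v: k for k, v in aln_b.items()}
    model_pairs = {(inv_a[i], inv_b[j]) for i, j in model_pairs_raw
                   if i in inv_a and j in inv_b}
    shared = native & model_pairs
    fnat = len(shared) / len(native) if native else 0.0
    fnonnat = (len(model_pairs_raw) - len(shared)) / len(model_pairs_raw) \
        if model_pairs_raw else 0.0

    # interface RMSD
    if capri_peptide:
        ia, ib = _interface_residues(ref_a, ref_b, 8.0, cb_only=True)
    else:
        ia, ib = _interface_residues(ref_a, ref_b, 10.0, cb_only=False)
    ref_bb, mdl_bb = [], []
    for chain, mchain, aln, sel in ((ref_a, mdl_a, aln_a, ia), (ref_b, mdl_b, aln_b, ib)):
        for ri in sorted(sel):
            if ri not in aln:
                continue
            mres = mchain.residues[aln[ri]]
            for atom in _backbone(chain.residues[ri], chain.chain_type):
                matom = mres.atom(atom.name)
                if matom is not None:
                    ref_bb.append(atom.pos)
                    mdl_bb.append(matom.pos)
    i_rmsd = None
    if len(ref_bb) >= 3:
        rot, t = kabsch(np.asarray(mdl_bb), np.asarray(ref_bb))
        i_rmsd = rmsd(apply_transform(np.asarray(mdl_bb), rot, t), np.asarray(ref_bb))

    # ligand RMSD: superpose receptor backbone, measure ligand backbone
    size_a = len(ref_a.residues)
    size_b = len(ref_b.residues)
    if size_a > size_b or (size_a == size_b and ra <= rb):
        rec, lig = (ref_a, mdl_a, aln_a), (ref_b, mdl_b, aln_b)
        rec_id, lig_id = ra, rb
    else:
        rec, lig = (ref_b, mdl_b, aln_b), (ref_a, mdl_a, aln_a)
        rec_id, lig_id = rb, ra

    def paired_backbone(chain, mchain, aln):
        refc, mdlc = [], []
        for ri, mi in sorted(aln.items()):
            mres = mchain.residues[mi]
            for atom in _backbone(chain.residues[ri], chain.chain_type):
                matom = mres.atom(atom.name)
                if matom is not None:
                    refc.append(atom.pos)
                    mdlc.append(matom.pos)
        return np.asarray(refc), np.asarray(mdlc)

    l_rmsd = None
    rec_ref, rec_mdl = paired_backbone(*rec)
    lig_ref, lig_mdl = paired_backbone(*lig)
    if len(rec_ref) >= 3 and len(lig_ref) >= 1:
        rot, t = kabsch(rec_mdl, rec_ref)
        l_rmsd = rmsd(apply_transform(lig_mdl, rot, t), lig_ref)

    dq = None
    if i_rmsd is not None and l_rmsd is not None:
        dq = (fnat
              + 1.0 / (1.0 + (i_rmsd / 1.5) ** 2)
              + 1.0 / (1.0 + (l_rmsd / 8.5) ** 2)) / 3.0
    return DockQComponents(fnat=fnat, fnonnat=fnonnat, i_rmsd=i_rmsd, l_rmsd=l_rmsd,
                           dockq=dq, n_native_contacts=len(native),
                           n_model_contacts=len(model_pairs_raw),
                           receptor=rec_id, ligand=lig_id)


def dockq_aggregate(per_interface: list[DockQComponents]) -> dict[str, Optional[float]]:
    """DockQ-ave (plain mean) and DockQ-wave (native-contact-weighted mean)
    over scored interfaces; None when nothing could be scored."""
    scored = [c for c in per_interface if c.dockq is not None]
    if not scored:
        return {"dockq_ave": None, "dockq_wave": None}
    values = np.array([c.dockq for c in scored])
    weights = np.array([c.n_native_contacts for c in scored], dtype=float)
    ave = float(values.mean())
    wave = float((values * weights).sum() / weights.sum()) if weights.sum() > 0 else ave
    return {"dockq_ave": ave, "dockq_wave": wave}
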