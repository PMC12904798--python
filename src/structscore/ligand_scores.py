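"""Ligand pose scores: BiSyRMSD, RMSD-LP, LDDT-LP, LDDT-PLI and assignment.

* BiSyRMSD — symmetry-corrected RMSD of the model ligand after superposing
  the model binding site onto the reference binding site.  The binding site
  is every reference polymer residue with a heavy atom within 4 Å of the
  reference ligand.  With several polymer chains, all group-respecting
  mappings of candidate model chains (heavy atom within 25 Å of the model
  ligand) onto the binding-site chains are enumerated and the best RMSD is
  reported.  The superposition uses Cα (C3′) positions, or all backbone
  atoms when the site has two or fewer residues.
* RMSD-LP / LDDT-LP — backbone RMSD and all-atom LDDT of the binding-site
  residues under the mapping chosen by BiSyRMSD (LDDT-LP is 0 by definition
  for a single-residue site).
* LDDT-PLI — symmetry-corrected LDDT over polymer/ligand atom pairs with a
  6 Å inclusion radius.  Unlike classical LDDT it also adds atom pairs that
  are within the radius in the *model* (when both atoms can be mapped to
  the reference), so contact overprediction is penalized.  The score is
  maximized over chain mappings, ligand symmetries and polymer residue
  symmetries.
* Assignment — greedy one-to-one matching of reference and model ligands,
  best score first, done separately for BiSyRMSD and LDDT-PLI; candidate
  pairs in each round are restricted to coverages within ``coverage_delta``
  of the current maximum, discouraging solvent-to-cofactor matches.

Unscoreable pairs yield an explicit reason, never a sentinel number.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata
from .grouping import (AlignmentParams, ChainGroup, GroupingResult, align_chains,
                       assign_model_chains, group_reference_chains)
from .ligands import Ligand, LigandMatch
from .mapping import _enumerate_mappings
from .model import NUCLEOTIDE, Structure
from .superpose import apply_transform, kabsch, rmsd

logger = logging.getLogger(__name__)

DEFAULT_SITE_RADIUS = 4.0
DEFAULT_PLI_RADIUS = 6.0
PLI_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
MODEL_CHAIN_RADIUS = 25.0


@dataclass
class BindingSite:
    """Reference binding-site residues: (chain id, residue index) pairs."""

    residues: list[tuple[str, int]]
    radius: float

    @property
    def chain_ids(self) -> list[str]:
        return sorted({cid for cid, _ in self.residues})

    def __len__(self) -> int:
        return len(self.residues)


def _polymer_atom_index(structure: Structure, chain_ids: Optional[set[str]] = None):
    keys, coords = [], []
    for chain in structure.polymer_chains:
        if chain_ids is not None and chain.id not in chain_ids:
            continue
        for ri, res in enumerate(chain.residues):
            for a in res.atoms:
                if not a.is_hydrogen:
                    keys.append((chain.id, ri, a.name))
                    coords.append(a.pos)
    return keys, np.asarray(coords, dtype=float) if coords else np.zeros((0, 3))


def detect_binding_site(reference: Structure, reference_ligand: Ligand,
                        radius: float = DEFAULT_SITE_RADIUS) -> BindingSite:
    """Reference polymer residues with any heavy atom within ``radius`` of
    any heavy ligand atom.  May be empty (ligand not scoreable with the
    current radius)."""
    keys, coords = _polymer_atom_index(reference)
    if len(coords) == 0:
        return BindingSite([], radius)
    tree = cKDTree(coords)
    residues: set[tuple[str, int]] = set()
    for a in reference_ligand.atoms:
        for idx in tree.query_ball_point(np.asarray(a.pos, dtype=float), radius):
            residues.add(keys[idx][:2])
    return BindingSite(sorted(residues), radius)


def _chains_near_ligand(structure: Structure, ligand: Ligand, radius: float) -> list[str]:
    out = []
    lig_pts = ligand.coords()
    for chain in structure.polymer_chains:
        pts = np.array([a.pos for r in chain.residues for a in r.atoms
                        if not a.is_hydrogen])
        if len(pts) == 0:
            continue
        d = cKDTree(pts).query(lig_pts, k=1)[0]
        if np.min(d) <= radius:
            out.append(chain.id)
    return out


def _sub_grouping(reference: Structure, model: Structure,
                  ref_chain_ids: list[str], mdl_chain_ids: list[str],
                  alignment_params: AlignmentParams) -> GroupingResult:
    """Grouping restricted to the given chain sets (binding-site mapping)."""
    sub_ref = Structure(chains=[c for c in reference.chains if c.id in ref_chain_ids])
    groups = group_reference_chains(sub_ref, alignment_params)
    sub_mdl = Structure(chains=[c for c in model.chains if c.id in mdl_chain_ids])
    return assign_model_chains(sub_mdl, groups, alignment_params,
                               identity_threshold=None)


@dataclass
class LigandScoreResult:
    """Scores for one (reference ligand, model ligand) pair; ``None`` plus a
    reason whenever a score could not be computed."""

    reference_ligand: str
    model_ligand: str
    coverage: float
    bisy_rmsd: Optional[float] = None
    rmsd_lp: Optional[float] = None
    lddt_lp: Optional[float] = None
    lddt_pli: Optional[float] = None
    site: Optional[BindingSite] = None
    chain_mapping: dict[str, str] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)


def _site_backbone(reference: Structure, model: Structure, site: BindingSite,
                   mapping: dict[str, str],
                   alignment_params: AlignmentParams) -> Optional[tuple[np.ndarray, np.ndarray, dict]]:
    """Paired reference/model binding-site backbone coordinates.

    Representative atoms (Cα/C3′) by default; all backbone atoms when the
    site has <= 2 residues.  Returns None when fewer than 3 atom pairs (or
    unmapped chains) make a superposition impossible.
    """
    use_full_backbone = len(site) <= 2
    ref_pts, mdl_pts = [], []
    residue_pairs: dict[tuple[str, int], tuple[str, int]] = {}
    for cid, ri in site.residues:
        if cid not in mapping:
            continue
        ref_chain = reference.chain(cid)
        mdl_chain = model.chain(mapping[cid])
        aln = dict(align_chains(ref_chain, mdl_chain, alignment_params).pairs)
        if ri not in aln:
            continue
        res = ref_chain.residues[ri]
        mres = mdl_chain.residues[aln[ri]]
        residue_pairs[(cid, ri)] = (mdl_chain.id, aln[ri])
        if use_full_backbone:
            from .dockq import BACKBONE_NUCLEOTIDE, BACKBONE_PEPTIDE
            names = BACKBONE_PEPTIDE if ref_chain.chain_type != NUCLEOTIDE \
                else BACKBONE_NUCLEOTIDE
        else:
            names = ("CA",) if ref_chain.chain_type != NUCLEOTIDE else ("C3'",)
        for name in names:
            a, b = res.atom(name), mres.atom(name)
            if a is not None and b is not None:
                ref_pts.append(a.pos)
                mdl_pts.append(b.pos)
    if len(ref_pts) < 3:
        return None
    return np.asarray(ref_pts), np.asarray(mdl_pts), residue_pairs


def _symmetry_min_rmsd(ref_ligand: Ligand, mdl_coords: np.ndarray,
                       match: LigandMatch) -> float:
    """Minimal RMSD over all symmetry-equivalent atom correspondences."""
    ref_coords = ref_ligand.coords()
    best = np.inf
    for corr in match.correspondences:
        ridx = np.array(sorted(corr), dtype=int)
        midx = np.array([corr[i] for i in ridx], dtype=int)
        best = min(best, rmsd(ref_coords[ridx], mdl_coords[midx]))
    return float(best)


def bisy_rmsd(
    reference: Structure,
    model: Structure,
    reference_ligand: Ligand,
    model_ligand: Ligand,
    match: LigandMatch,
    site_radius: float = DEFAULT_SITE_RADIUS,
    alignment_params: Optional[AlignmentParams] = None,
) -> LigandScoreResult:
    """Binding-site superposed, symmetry-corrected ligand RMSD (plus
    RMSD-LP and LDDT-LP of the binding site under the same mapping)."""
    alignment_params = alignment_params or AlignmentParams()
    result = LigandScoreResult(reference_ligand.id, model_ligand.id, match.coverage)
    site = detect_binding_site(reference, reference_ligand, site_radius)
    result.site = site
    if len(site) == 0:
        result.reasons["bisy_rmsd"] = "empty binding site at radius %.1f" % site_radius
        return result
    mdl_chain_ids = _chains_near_ligand(model, model_ligand, MODEL_CHAIN_RADIUS)
    if not mdl_chain_ids:
        result.reasons["bisy_rmsd"] = \
            "no model chain within %.0f Å of the model ligand" % MODEL_CHAIN_RADIUS
        return result
    grouping = _sub_grouping(reference, model, site.chain_ids, mdl_chain_ids,
                             alignment_params)
    best: Optional[tuple[float, float, dict, dict]] = None
    for mapping in _enumerate_mappings(grouping):
        packed = _site_backbone(reference, model, site, mapping, alignment_params)
        if packed is None:
            continue
        ref_bb, mdl_bb, residue_pairs = packed
        rot, t = kabsch(mdl_bb, ref_bb)
        site_rmsd = rmsd(apply_transform(mdl_bb, rot, t), ref_bb)
        lig_moved = apply_transform(model_ligand.coords(), rot, t)
        value = _symmetry_min_rmsd(reference_ligand, lig_moved, match)
        if best is None or value < best[0]:
            best = (value, site_rmsd, mapping, residue_pairs)
    if best is None:
        result.reasons["bisy_rmsd"] = "binding site could not be superposed"
        return result
    result.bisy_rmsd, result.rmsd_lp, result.chain_mapping, residue_pairs = best
    result.lddt_lp = _lddt_lp(reference, model, site, residue_pairs)
    return result


def _lddt_lp(reference: Structure, model: Structure, site: BindingSite,
             residue_pairs: dict[tuple[str, int], tuple[str, int]]) -> float:
    """All-atom LDDT restricted to binding-site residues (0 by definition
    for a single-residue site)."""
    if len(site) <= 1:
        return 0.0
    from .grouping import PairAlignment
    from .lddt import LddtParams, build_contact_table, lddt
    from .model import Chain
    sub_ref = Structure(name="site")
    sub_mdl = Structure(name="site_mdl")
    per_chain: dict[str, list[int]] = {}
    for cid, ri in site.residues:
        per_chain.setdefault(cid, []).append(ri)
    alignments: dict[str, PairAlignment] = {}
    mapping: dict[str, str] = {}
    for cid, ris in per_chain.items():
        ref_chain = reference.chain(cid)
        sub_chain = Chain(id=cid, chain_type=ref_chain.chain_type)
        mdl_sub: list = []
        pairs = []
        for ri in sorted(ris):
            if (cid, ri) not in residue_pairs:
                sub_chain.residues.append(ref_chain.residues[ri])
                continue
            mcid, mj = residue_pairs[(cid, ri)]
            pairs.append((len(sub_chain.residues), len(mdl_sub)))
            sub_chain.residues.append(ref_chain.residues[ri])
            mdl_sub.append(model.chain(mcid).residues[mj])
        sub_ref.chains.append(sub_chain)
        mchain = Chain(id=cid, chain_type=ref_chain.chain_type, residues=mdl_sub)
        sub_mdl.chains.append(mchain)
        mapping[cid] = cid
        alignments[cid] = PairAlignment(pairs=pairs, identity=1.0, n_aligned=len(pairs))
    params = LddtParams(inclusion_radius=15.0)
    table = build_contact_table(sub_ref, params)
    if table.n_contacts == 0:
        return 0.0
    res = lddt(sub_mdl, table, mapping, alignments, params)
    return res.score if res.score is not None else 0.0


# ---------------------------------------------------------------------------
# LDDT-PLI
# ---------------------------------------------------------------------------

def lddt_pli(
    reference: Structure,
    model: Structure,
    reference_ligand: Ligand,
    model_ligand: Ligand,
    match: LigandMatch,
    inclusion_radius: float = DEFAULT_PLI_RADIUS,
    thresholds: tuple[float, ...] = PLI_THRESHOLDS,
    alignment_params: Optional[AlignmentParams] = None,
) -> tuple[Optional[float], Optional[str]]:
    """Symmetry-corrected LDDT over polymer-ligand contacts.

    Returns (score, reason); the score is None with a reason when no
    contact exists in either structure.  Model-side contacts between
    mappable atoms are added to the contact set, penalizing contact
    overprediction.  The best score over chain mappings, ligand symmetries
    and residue symmetries is reported; no stereochemistry checks apply.
    """
    alignment_params = alignment_params or AlignmentParams()
    chain_radius = inclusion_radius + max(thresholds)
    ref_cids = _chains_near_ligand(reference, reference_ligand, chain_radius)
    mdl_cids = _chains_near_ligand(model, model_ligand, chain_radius)
    if not ref_cids and not mdl_cids:
        return None, "no polymer chain within %.0f Å of the ligand" % chain_radius
    # chemically equivalent groups over all chains; model chains that touch
    # the ligand may borrow the closest equivalent reference chain even if
    # it is outside the relevant reference set
    all_groups = group_reference_chains(reference, alignment_params)
    grouping = assign_model_chains(
        Structure(chains=[c for c in model.chains if c.id in mdl_cids]),
        all_groups, alignment_params, identity_threshold=None)
    lig_centroid = np.mean(reference_ligand.coords(), axis=0)
    pruned: list[ChainGroup] = []
    for g in grouping.groups:
        if not g.model_chain_ids and not (set(g.reference_chain_ids) & set(ref_cids)):
            continue
        refs_in = [c for c in g.reference_chain_ids if c in ref_cids]
        extra_needed = max(len(g.model_chain_ids), 1 if refs_in else 0) - len(refs_in)
        if extra_needed > 0:
            others = [c for c in g.reference_chain_ids if c not in ref_cids]
            others.sort(key=lambda cid: np.linalg.norm(
                np.mean([a.pos for r in reference.chain(cid).residues
                         for a in r.atoms], axis=0) - lig_centroid))
            refs_in = refs_in + others[:extra_needed]
        if refs_in:
            pruned.append(ChainGroup(g.representative_sequence, g.chain_type,
                                     sorted(refs_in), list(g.model_chain_ids)))
    grouping = GroupingResult(groups=pruned)

    ref_keys, ref_coords = _polymer_atom_index(reference, set(
        cid for g in pruned for cid in g.reference_chain_ids))
    if len(ref_coords) == 0:
        return None, "no reference polymer atoms near the ligand"
    ref_tree = cKDTree(ref_coords)
    ref_lig_coords = reference_ligand.coords()
    # reference contacts: (ligand atom index, polymer atom key)
    ref_contacts: dict[tuple[int, tuple], float] = {}
    for li, pos in enumerate(ref_lig_coords):
        for idx in ref_tree.query_ball_point(pos, inclusion_radius):
            ref_contacts[(li, ref_keys[idx])] = float(
                np.linalg.norm(pos - ref_coords[idx]))
    ref_atom_pos = {k: ref_coords[i] for i, k in enumerate(ref_keys)}

    best_score: Optional[float] = None
    for mapping in _enumerate_mappings(grouping):
        inv = {m: r for r, m in mapping.items()}
        # model polymer atom -> reference polymer atom key
        alns = {r: dict(align_chains(reference.chain(r), model.chain(m),
                                     alignment_params).pairs)
                for r, m in mapping.items()}
        mdl_keys, mdl_coords = _polymer_atom_index(model, set(mapping.values()))
        atom_map: dict[tuple, tuple] = {}
        sym_groups: dict[tuple[str, int], list[dict[str, str]]] = {}
        for k in mdl_keys:
            mcid, mri, aname = k
            rcid = inv[mcid]
            col = {mj: ri for ri, mj in alns[rcid].items()}
            if mri not in col:
                continue
            rkey = (rcid, col[mri], aname)
            if rkey in ref_atom_pos:
                atom_map[k] = rkey
                res_name = reference.chain(rcid).residues[col[mri]].name
                if res_name in chemdata.RESIDUE_SYMMETRIES:
                    sym_groups[(rcid, col[mri])] = chemdata.RESIDUE_SYMMETRIES[res_name]
        mdl_atom_pos = {k: mdl_coords[i] for i, k in enumerate(mdl_keys)}
        mdl_tree = cKDTree(mdl_coords) if len(mdl_coords) else None

        for corr in match.correspondences:
            # contact set: reference contacts + mappable model-only contacts
            contacts: dict[tuple[int, tuple], tuple[float, Optional[float]]] = {}
            inv_corr = {m: r for r, m in corr.items()}
            mdl_lig_coords = model_ligand.coords()
            for (li, rkey), dref in ref_contacts.items():
                contacts[(li, rkey)] = (dref, None)
            if mdl_tree is not None:
                for mli, pos in enumerate(mdl_lig_coords):
                    if mli not in inv_corr:
                        continue  # no experimental evidence for this atom
                    li = inv_corr[mli]
                    for idx in mdl_tree.query_ball_point(pos, inclusion_radius):
                        k = mdl_keys[idx]
                        if k not in atom_map:
                            continue
                        rkey = atom_map[k]
                        dref = float(np.linalg.norm(
                            ref_lig_coords[li] - ref_atom_pos[rkey]))
                        contacts.setdefault((li, rkey), (dref, None))
            if not contacts:
                continue
            # model distances under this correspondence
            inv_atom_map = {v: k for k, v in atom_map.items()}
            base: dict[tuple[int, tuple], tuple[float, Optional[float]]] = {}
            for (li, rkey), (dref, _) in contacts.items():
                dm = None
                if li in corr and rkey in inv_atom_map:
                    dm = float(np.linalg.norm(
                        mdl_lig_coords[corr[li]] - mdl_atom_pos[inv_atom_map[rkey]]))
                base[(li, rkey)] = (dref, dm)
            score = _pli_score_with_symmetries(base, sym_groups, thresholds,
                                               inv_atom_map, mdl_atom_pos,
                                               mdl_lig_coords, corr)
            if best_score is None or score > best_score:
                best_score = score
    if best_score is None:
        if not ref_contacts:
            return None, "no polymer-ligand contacts within %.1f Å" % inclusion_radius
        return 0.0, None
    return best_score, None


def _pli_score_with_symmetries(contacts, sym_groups, thresholds,
                               inv_atom_map, mdl_atom_pos, mdl_lig_coords, corr):
    """Mean preserved fraction over thresholds, after greedily resolving
    each residue's atom-name symmetry to maximize its own preserved
    contacts."""
    # greedy per-residue relabeling: recompute model distances for contacts
    # touching a symmetric residue under each alternative naming
    adjusted = dict(contacts)
    by_res: dict[tuple[str, int], list] = {}
    for key in contacts:
        _, (rcid, rri, _) = key
        if (rcid, rri) in sym_groups:
            by_res.setdefault((rcid, rri), []).append(key)
    for res_key, keys in by_res.items():
        def preserved_count(entries) -> int:
            n = 0
            for key in keys:
                dref, dm = entries[key]
                if dm is None:
                    continue
                n += sum(1 for t in thresholds if abs(dm - dref) <= t)
            return n
        best_entries = {k: adjusted[k] for k in keys}
        best_n = preserved_count(best_entries)
        for perm in sym_groups[res_key]:
            trial = {}
            for key in keys:
                li, (rcid, rri, aname) = key
                swapped = perm.get(aname, aname)
                rkey_sw = (rcid, rri, swapped)
                dm = None
                if li in corr and rkey_sw in inv_atom_map:
                    dm = float(np.linalg.norm(
                        mdl_lig_coords[corr[li]] - mdl_atom_pos[inv_atom_map[rkey_sw]]))
                trial[key] = (adjusted[key][0], dm)
            n = preserved_count(trial)
            if n > best_n:
                best_entries, best_n = trial, n
        adjusted.update(best_entries)
    total = len(adjusted)
    fracs = []
    for t in thresholds:
        n = sum(1 for dref, dm in adjusted.values()
                if dm is not None and abs(dm - dref) <= t)
        fracs.append(n / total)
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# Ligand assignment
# ---------------------------------------------------------------------------

@dataclass
class LigandAssignment:
    """One-to-one reference/model ligand assignment for one score."""

    score_name: str
    pairs: list[tuple[str, str, float]]      # (ref ligand id, mdl ligand id, score)
    unassigned_reference: list[str] = field(default_factory=list)
    unassigned_model: list[str] = field(default_factory=list)


def assign_ligands(
    scored_pairs: list[tuple[str, str, float, float]],
    reference_ids: list[str],
    model_ids: list[str],
    score_name: str,
    higher_is_better: bool,
    coverage_delta: float = 0.2,
) -> LigandAssignment:
    """Greedy one-to-one assignment from (ref id, mdl id, coverage, score)
    candidates.  Each round restricts candidates to coverage within
    ``coverage_delta`` of the maximum remaining coverage, then picks the
    best score (ties: higher coverage, then lexicographic ids)."""
    remaining = list(scored_pairs)
    free_ref = set(reference_ids)
    free_mdl = set(model_ids)
    pairs: list[tuple[str, str, float]] = []
    while True:
        pool = [p for p in remaining if p[0] in free_ref and p[1] in free_mdl]
        if not pool:
            break
        max_cov = max(p[2] for p in pool)
        window = [p for p in pool if p[2] > max_cov - coverage_delta]
        sign = -1.0 if higher_is_better else 1.0

        def rank(p):
            return (sign * p[3], -p[2], p[0], p[1])
        best = min(window, key=rank)
        pairs.append((best[0], best[1], best[3]))
        free_ref.discard(best[0])
        free_mdl.discard(best[1])
    return LigandAssignment(score_name, pairs,
                            unassigned_reference=sorted(free_ref),
                            unassigned_model=sorted(free_mdl))
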