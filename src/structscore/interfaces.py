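"""Interface contact similarity (ICS) and interface patch similarity (IPS).

Interface contacts are residue pairs from different chains with any
heavy-atom pair within 5 Å (the CASP convention; configurable).  ICS is the
F1 measure of the model contact set against the reference contact set; IPS
is the Jaccard coefficient of the interface residue sets.  Contacts from
the complete complexes are pooled for the full-complex score and also
reported per chain-pair interface.  The ``trimmed`` variants remove model
residues with no reference counterpart before contact collection, so that
regions not covered by experiment cannot penalize the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .grouping import PairAlignment
from .model import Structure

CONTACT_DIST = 5.0

ResKey = tuple[str, int]             # (chain id, residue index)
Contact = tuple[ResKey, ResKey]


def residue_contacts(structure: Structure, dist: float = CONTACT_DIST) -> set[Contact]:
    """Inter-chain residue-pair contacts (any heavy-atom pair within dist)."""
    keys: list[ResKey] = []
    coords: list = []
    for chain in structure.polymer_chains:
        for ri, res in enumerate(chain.residues):
            for a in res.atoms:
                if not a.is_hydrogen:
                    keys.append((chain.id, ri))
                    coords.append(a.pos)
    if not coords:
        return set()
    tree = cKDTree(np.asarray(coords, dtype=float))
    contacts: set[Contact] = set()
    for i, j in tree.query_pairs(dist):
        ki, kj = keys[i], keys[j]
        if ki[0] == kj[0]:
            continue
        contacts.add((ki, kj) if ki < kj else (kj, ki))
    return contacts


def _map_model_contacts(
    contacts: set[Contact],
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
) -> tuple[set[Contact], int]:
    """Express model contacts in reference residue keys.

    Returns the mappable contacts (both residues aligned to the reference)
    and the number of unmappable ones, which count against precision.
    """
    inverse = {m: r for r, m in mapping.items()}
    res_lut: dict[str, dict[int, int]] = {}
    for ref_cid, aln in alignments.items():
        res_lut[ref_cid] = {mj: ri for ri, mj in aln.pairs}
    mapped: set[Contact] = set()
    unmappable = 0
    for (c1, r1), (c2, r2) in contacts:
        rc1, rc2 = inverse.get(c1), inverse.get(c2)
        if rc1 is None or rc2 is None or r1 not in res_lut.get(rc1, {}) \
                or r2 not in res_lut.get(rc2, {}):
            unmappable += 1
            continue
        k1 = (rc1, res_lut[rc1][r1])
        k2 = (rc2, res_lut[rc2][r2])
        mapped.add((k1, k2) if k1 < k2 else (k2, k1))
    return mapped, unmappable


def trim_model(model: Structure, mapping: dict[str, str],
               alignments: dict[str, PairAlignment]) -> Structure:
    """Remove model chains/residues that have no reference counterpart."""
    out = model.copy()
    inverse = {m: r for r, m in mapping.items()}
    kept = []
    for chain in out.chains:
        ref_cid = inverse.get(chain.id)
        if ref_cid is None or ref_cid not in alignments:
            continue
        aligned_mdl = {mj for _, mj in alignments[ref_cid].pairs}
        chain.residues = [r for j, r in enumerate(chain.residues) if j in aligned_mdl]
        if chain.residues:
            kept.append(chain)
    out.chains = kept
    return out


@dataclass
class IcsIpsResult:
    ics: Optional[float]
    ips: Optional[float]
    precision: Optional[float] = None
    recall: Optional[float] = None
    per_interface: dict[tuple[str, str], dict] = field(default_factory=dict)
    n_ref_contacts: int = 0
    n_mdl_contacts: int = 0
    reason: Optional[str] = None


def _f1(n_shared: int, n_mdl: int, n_ref: int) -> tuple[Optional[float], float, float]:
    precision = n_shared / n_mdl if n_mdl else 0.0
    recall = n_shared / n_ref if n_ref else 0.0
    if precision + recall == 0:
        return 0.0, precision, recall
    return 2 * precision * recall / (precision + recall), precision, recall


def _patch_jaccard(ref_contacts: set[Contact], mdl_contacts: set[Contact]) -> Optional[float]:
    ref_res = {k for c in ref_contacts for k in c}
    mdl_res = {k for c in mdl_contacts for k in c}
    union = ref_res | mdl_res
    if not union:
        return None
    return len(ref_res & mdl_res) / len(union)


def ics_ips(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
    trimmed: bool = False,
    contact_dist: float = CONTACT_DIST,
) -> IcsIpsResult:
    """Pooled and per-interface ICS/IPS for a given chain mapping."""
    work = trim_model(model, mapping, alignments) if trimmed else model
    ref_contacts = residue_contacts(reference, contact_dist)
    mdl_raw = residue_contacts(work, contact_dist)
    mdl_contacts, unmappable = _map_model_contacts(mdl_raw, mapping, alignments)
    n_mdl = len(mdl_contacts) + unmappable
    n_ref = len(ref_contacts)
    if n_ref == 0 and n_mdl == 0:
        return IcsIpsResult(None, None, reason="no interface contacts in either structure")
    shared = ref_contacts & mdl_contacts
    ics, precision, recall = _f1(len(shared), n_mdl, n_ref)
    ips = _patch_jaccard(ref_contacts, mdl_contacts)

    per_interface: dict[tuple[str, str], dict] = {}
    pair_of = lambda c: tuple(sorted((c[0][0], c[1][0])))
    pairs = {pair_of(c) for c in ref_contacts} | {pair_of(c) for c in mdl_contacts}
    for pair in sorted(pairs):
        rc = {c for c in ref_contacts if pair_of(c) == pair}
        mc = {c for c in mdl_contacts if pair_of(c) == pair}
        f1, p, r = _f1(len(rc & mc), len(mc), len(rc))
        per_interface[pair] = {"ics": f1, "ips": _patch_jaccard(rc, mc),
                               "n_ref_contacts": len(rc), "n_mdl_contacts": len(mc)}
    return IcsIpsResult(ics, ips, precision, recall, per_interface, n_ref, n_mdl)
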