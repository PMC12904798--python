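"""Quaternary-structure score (QS-score) on interface residue contacts.

A contact is a pair of residues from different chains whose representative
positions (Cβ, Cα for glycine) are within 12 Å.  Contacts shared by model
and reference contribute a weight that decays with the difference of the
two distances; contacts seen in only one structure contribute their weight
to the denominator.  Two flavours are reported:

* ``qs_global`` — symmetric; contacts present in only one structure (e.g.
  chains with no counterpart, extra stoichiometry) penalize the score.
* ``qs_best`` — restricted to residues resolved in both structures, so
  incomplete models or wrong stoichiometry are not penalized.

Weights follow the conventional QS-score form: w(d) = 1 for d <= 5 Å and a
Gaussian fall-off exp(-2 ((d-5)/4.28)^2) beyond; a shared contact with
reference distance d1 and model distance d2 scores
w((d1+d2)/2) * (1 - min(|d1-d2|, 12)/12).  These choices are pinned by
golden tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grouping import PairAlignment
from .model import Chain, Structure

CONTACT_DIST = 12.0


def weight(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    w = np.exp(-2.0 * ((d - 5.0) / 4.28) ** 2)
    return np.where(d <= 5.0, 1.0, w)


def rep_coords(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue representative coordinates (Cβ, Cα fallback) and a
    validity mask."""
    n = len(chain.residues)
    pos = np.zeros((n, 3))
    mask = np.zeros(n, dtype=bool)
    for i, res in enumerate(chain.residues):
        a = res.sidechain_rep()
        if a is not None:
            pos[i] = a.pos
            mask[i] = True
    return pos, mask


def _pair_dist(pos_a, mask_a, pos_b, mask_b) -> np.ndarray:
    """Residue-pair distance matrix; NaN where a representative is missing."""
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=2)
    d[~mask_a, :] = np.nan
    d[:, ~mask_b] = np.nan
    return d


@dataclass
class QsPairTerms:
    """Additive QS-score terms for one (reference chain pair, model chain
    pair) assignment; see module docstring for the decomposition."""

    numerator: float = 0.0
    den_mutual: float = 0.0     # shared + mutually-resolved one-sided contacts
    den_ref_extra: float = 0.0  # reference-only contacts (global denominator)
    den_mdl_extra: float = 0.0  # model-only contacts (global denominator)


def chain_pair_weight(pos_a, mask_a, pos_b, mask_b) -> float:
    """Total contact weight of one chain pair in a single structure."""
    d = _pair_dist(pos_a, mask_a, pos_b, mask_b)
    with np.errstate(invalid="ignore"):
        sel = d <= CONTACT_DIST
    return float(weight(d[sel]).sum())


def qs_pair_terms(
    d_ref: np.ndarray,
    d_mdl: np.ndarray,
    row_map: dict[int, int],
    col_map: dict[int, int],
) -> QsPairTerms:
    """Terms for a mapped chain pair.

    ``d_ref`` is the reference residue-pair distance matrix for chains
    (A, B); ``d_mdl`` the model matrix for the assigned chains (A', B');
    ``row_map``/``col_map`` are residue alignments A->A', B->B'.
    """
    terms = QsPairTerms()
    rows = np.array(sorted(row_map), dtype=int) if row_map else np.zeros(0, dtype=int)
    cols = np.array(sorted(col_map), dtype=int) if col_map else np.zeros(0, dtype=int)
    mrows = np.array([row_map[r] for r in rows], dtype=int)
    mcols = np.array([col_map[c] for c in cols], dtype=int)
    with np.errstate(invalid="ignore"):
        ref_contact = d_ref <= CONTACT_DIST
        # aligned submatrices
        if len(rows) and len(cols):
            sub_ref = d_ref[np.ix_(rows, cols)]
            sub_mdl = d_mdl[np.ix_(mrows, mcols)]
            both = (sub_ref <= CONTACT_DIST) & (sub_mdl <= CONTACT_DIST)
            ref_only_m = (sub_ref <= CONTACT_DIST) & ~(sub_mdl <= CONTACT_DIST) \
                & np.isfinite(sub_mdl)
            mdl_only_m = (sub_mdl <= CONTACT_DIST) & ~(sub_ref <= CONTACT_DIST) \
                & np.isfinite(sub_ref)
            davg = 0.5 * (sub_ref[both] + sub_mdl[both])
            diff = np.abs(sub_ref[both] - sub_mdl[both])
            terms.numerator = float((weight(davg) * (1.0 - np.minimum(diff, CONTACT_DIST)
                                                     / CONTACT_DIST)).sum())
            terms.den_mutual = float(weight(davg).sum()
                                     + weight(sub_ref[ref_only_m]).sum()
                                     + weight(sub_mdl[mdl_only_m]).sum())
            # contacts whose counterpart residues are unresolved in the model
            mask = np.ones_like(ref_contact)
            mask[np.ix_(rows, cols)] = ~np.isfinite(sub_mdl)
            ref_extra = ref_contact & mask
            terms.den_ref_extra = float(weight(d_ref[ref_extra]).sum())
            mdl_contact = d_mdl <= CONTACT_DIST
            mask_m = np.ones_like(mdl_contact)
            mask_m[np.ix_(mrows, mcols)] = ~np.isfinite(sub_ref)
            mdl_extra = mdl_contact & mask_m
            terms.den_mdl_extra = float(weight(d_mdl[mdl_extra]).sum())
        else:
            terms.den_ref_extra = float(weight(d_ref[ref_contact]).sum())
            with np.errstate(invalid="ignore"):
                mdl_contact = d_mdl <= CONTACT_DIST
            terms.den_mdl_extra = float(weight(d_mdl[mdl_contact]).sum())
    return terms


@dataclass
class QsResult:
    qs_global: Optional[float]
    qs_best: Optional[float]
    reason: Optional[str] = None


def qs_score(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
) -> QsResult:
    """QS-global and QS-best for a given chain mapping.

    Unmapped chains on either side contribute their interface contacts to
    the global denominator only.  Returns a not-computable result when
    neither structure has any interface contact.
    """
    ref_chains = [c for c in reference.polymer_chains]
    mdl_chains = [c for c in model.polymer_chains]
    ref_rep = {c.id: rep_coords(c) for c in ref_chains}
    mdl_rep = {c.id: rep_coords(c) for c in mdl_chains}
    mapped_ref = [c.id for c in ref_chains if c.id in mapping]
    mapped_mdl = {mapping[r] for r in mapped_ref}

    num = den_mutual = den_extra = 0.0
    # reference chain pairs
    for i, ci in enumerate(ref_chains):
        for cj in ref_chains[i + 1:]:
            if ci.id in mapping and cj.id in mapping:
                d_ref = _pair_dist(*ref_rep[ci.id], *ref_rep[cj.id])
                d_mdl = _pair_dist(*mdl_rep[mapping[ci.id]], *mdl_rep[mapping[cj.id]])
                terms = qs_pair_terms(d_ref, d_mdl,
                                      dict(alignments[ci.id].pairs),
                                      dict(alignments[cj.id].pairs))
                num += terms.numerator
                den_mutual += terms.den_mutual
                den_extra += terms.den_ref_extra + terms.den_mdl_extra
            else:
                d_ref = _pair_dist(*ref_rep[ci.id], *ref_rep[cj.id])
                with np.errstate(invalid="ignore"):
                    sel = d_ref <= CONTACT_DIST
                den_extra += float(weight(d_ref[sel]).sum())
    # model chain pairs with at least one unmapped chain
    for i, cu in enumerate(mdl_chains):
        for cv in mdl_chains[i + 1:]:
            if cu.id in mapped_mdl and cv.id in mapped_mdl:
                continue
            d_mdl = _pair_dist(*mdl_rep[cu.id], *mdl_rep[cv.id])
            with np.errstate(invalid="ignore"):
                sel = d_mdl <= CONTACT_DIST
            den_extra += float(weight(d_mdl[sel]).sum())

    if den_mutual + den_extra == 0.0:
        return QsResult(None, None, reason="no interface contacts in either structure")
    qs_global = num / (den_mutual + den_extra)
    qs_best = num / den_mutual if den_mutual > 0 else None
    return QsResult(qs_global, qs_best)
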