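"""Chain mapping: QSMap (QS-score / backbone LDDT) and QSMapR (backbone RMSD).

Both algorithms assign model chains one-to-one to reference chains within
the chemically equivalent groups from :mod:`structscore.grouping`.  Small
problems are solved by exhaustive enumeration of all group-respecting
mappings; larger ones by a greedy extension heuristic that is seeded from
every possible reference/model chain pair, grows the mapping by the pair
giving the best objective, and re-seeds stalled (disconnected) mappings so
that the returned mapping is always complete.

QSMap optimizes the QS-score, switching to backbone LDDT with a 30 Å
inclusion radius as soon as nucleotide chains are involved (the QS-score
contact weighting is protein-specific).  Both objectives are pairwise
decomposable, so per-(chain-pair, chain-pair) contributions are cached and
each candidate mapping is scored from cached blocks.  QSMapR optimizes the
backbone RMSD over per-group alignment columns covered in every member
chain, subsampled to 50 equidistant columns, with one Kabsch superposition
per candidate mapping.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import qs as qsmod
from .grouping import AlignmentParams, GroupingResult, PairAlignment, align_chains
from .model import NUCLEOTIDE, Chain, Structure
from .superpose import apply_transform, kabsch, rmsd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MappingSearchParams:
    """Search-control knobs for QSMap/QSMapR."""

    exhaustive_limit_qsmap: int = 8     # enumerate when #mappings <= 8!
    exhaustive_limit_qsmapr: int = 5    # enumerate when #mappings <= 5!
    qs_accessibility_dist: float = 12.0  # Cβ proximity for accessible chains
    qs_contact_dist: float = 8.0         # contact definition for accessibility
    min_interface_contacts: int = 3
    lddt_inclusion_radius: float = 30.0
    lddt_max_deviation: float = 4.0
    lddt_thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    msa_subsample_columns: int = 50
    force_greedy: bool = False
    force_exhaustive: bool = False


@dataclass
class ChainMapping:
    """One-to-one reference -> model chain assignment with its objective."""

    pairs: dict[str, str]
    objective: str               # qs_score | bb_lddt | rmsd
    objective_value: Optional[float]
    complete: bool
    search_mode: str             # exhaustive | greedy | trivial
    seeds_evaluated: int = 0
    alignments: dict[tuple[str, str], PairAlignment] = field(default_factory=dict)


def _group_pairs(grouping: GroupingResult) -> list[tuple[list[str], list[str]]]:
    return [(list(g.reference_chain_ids), list(g.model_chain_ids))
            for g in grouping.groups]


def problem_size(grouping: GroupingResult) -> int:
    """Number of complete group-respecting mappings (capped at 10**9)."""
    total = 1
    for refs, mdls in _group_pairs(grouping):
        r, m = len(refs), len(mdls)
        k = min(r, m)
        count = math.comb(r, k) * math.comb(m, k) * math.factorial(k)
        total *= max(count, 1)
        if total > 10 ** 9:
            return 10 ** 9
    return total


def _enumerate_mappings(grouping: GroupingResult):
    """Yield complete mappings as dict ref_chain -> model_chain."""
    per_group = []
    for refs, mdls in _group_pairs(grouping):
        k = min(len(refs), len(mdls))
        options = []
        for ref_sub in itertools.combinations(refs, k):
            for mdl_perm in itertools.permutations(mdls, k):
                options.append(dict(zip(ref_sub, mdl_perm)))
        per_group.append(options)
    for combo in itertools.product(*per_group):
        merged: dict[str, str] = {}
        for part in combo:
            merged.update(part)
        yield merged


class _AlignmentCache:
    def __init__(self, reference: Structure, model: Structure,
                 params: AlignmentParams) -> None:
        self.reference = reference
        self.model = model
        self.params = params
        self._cache: dict[tuple[str, str], PairAlignment] = {}

    def get(self, ref_cid: str, mdl_cid: str) -> PairAlignment:
        key = (ref_cid, mdl_cid)
        if key not in self._cache:
            self._cache[key] = align_chains(self.reference.chain(ref_cid),
                                            self.model.chain(mdl_cid), self.params)
        return self._cache[key]


# ---------------------------------------------------------------------------
# QS-score objective
# ---------------------------------------------------------------------------

class _QsObjective:
    """Cached pairwise decomposition of QS-global over chain pairs."""

    name = "qs_score"

    def __init__(self, reference: Structure, model: Structure,
                 alignments: _AlignmentCache, params: MappingSearchParams) -> None:
        self.alignments = alignments
        self.params = params
        self.ref_rep = {c.id: qsmod.rep_coords(c) for c in reference.polymer_chains}
        self.mdl_rep = {c.id: qsmod.rep_coords(c) for c in model.polymer_chains}
        self.ref_ids = [c.id for c in reference.polymer_chains]
        self.mdl_ids = [c.id for c in model.polymer_chains]
        self._dref: dict[tuple[str, str], np.ndarray] = {}
        self._dmdl: dict[tuple[str, str], np.ndarray] = {}
        self._wref: dict[tuple[str, str], float] = {}
        self._wmdl: dict[tuple[str, str], float] = {}
        self._blocks: dict[tuple[str, str, str, str], qsmod.QsPairTerms] = {}
        self.total_unmapped_weight = 0.0
        for ids, reps, dmat, wmat in ((self.ref_ids, self.ref_rep, self._dref, self._wref),
                                      (self.mdl_ids, self.mdl_rep, self._dmdl, self._wmdl)):
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    d = qsmod._pair_dist(*reps[a], *reps[b])
                    dmat[(a, b)] = d
                    with np.errstate(invalid="ignore"):
                        sel = d <= qsmod.CONTACT_DIST
                    w = float(qsmod.weight(d[sel]).sum())
                    wmat[(a, b)] = w
                    self.total_unmapped_weight += w

    def _dmat_ref(self, a: str, b: str) -> np.ndarray:
        return self._dref[(a, b)] if (a, b) in self._dref else self._dref[(b, a)].T

    def _dmat_mdl(self, a: str, b: str) -> np.ndarray:
        return self._dmdl[(a, b)] if (a, b) in self._dmdl else self._dmdl[(b, a)].T

    def wref(self, a: str, b: str) -> float:
        return self._wref.get((a, b), self._wref.get((b, a), 0.0))

    def wmdl(self, a: str, b: str) -> float:
        return self._wmdl.get((a, b), self._wmdl.get((b, a), 0.0))

    def block(self, ri: str, rj: str, mi: str, mj: str) -> qsmod.QsPairTerms:
        """Terms for reference pair (ri, rj) assigned to model (mi, mj)."""
        if (rj, ri) < (ri, rj):
            ri, rj, mi, mj = rj, ri, mj, mi
        key = (ri, rj, mi, mj)
        hit = self._blocks.get(key)
        if hit is None:
            hit = qsmod.qs_pair_terms(
                self._dmat_ref(ri, rj), self._dmat_mdl(mi, mj),
                dict(self.alignments.get(ri, mi).pairs),
                dict(self.alignments.get(rj, mj).pairs))
            self._blocks[key] = hit
        return hit

    def score(self, mapping: dict[str, str]) -> float:
        num = den = 0.0
        items = sorted(mapping.items())
        covered_w = 0.0
        for (ri, mi), (rj, mj) in itertools.combinations(items, 2):
            terms = self.block(ri, rj, mi, mj)
            num += terms.numerator
            den += terms.den_mutual + terms.den_ref_extra + terms.den_mdl_extra
            covered_w += self.wref(ri, rj) + self.wmdl(mi, mj)
        den += self.total_unmapped_weight - covered_w
        return num / den if den > 0 else 0.0

    # additive-gain API used by the incremental greedy search:
    # state vector = (numerator, mapped denominator, covered unmapped weight)
    def zero(self) -> np.ndarray:
        return np.zeros(3)

    def seed_gain(self, r: str, m: str) -> np.ndarray:
        return np.zeros(3)  # QS-score has no single-chain contribution

    def pair_gain(self, r: str, m: str, q: str, mq: str) -> np.ndarray:
        terms = self.block(r, q, m, mq)
        return np.array([
            terms.numerator,
            terms.den_mutual + terms.den_ref_extra + terms.den_mdl_extra,
            self.wref(r, q) + self.wmdl(m, mq)])

    def score_vec(self, state: np.ndarray) -> float:
        den = state[1] + self.total_unmapped_weight - state[2]
        return float(state[0] / den) if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Backbone-LDDT objective
# ---------------------------------------------------------------------------

class _BbLddtObjective:
    """Pairwise decomposition of backbone LDDT preserved-contact counts."""

    name = "bb_lddt"

    def __init__(self, reference: Structure, model: Structure,
                 alignments: _AlignmentCache, params: MappingSearchParams) -> None:
        self.alignments = alignments
        self.params = params
        self.thresholds = params.lddt_thresholds
        self.radius = params.lddt_inclusion_radius
        self.ref_bb = {c.id: self._bb_coords(c) for c in reference.polymer_chains}
        self.mdl_bb = {c.id: self._bb_coords(c) for c in model.polymer_chains}
        self.ref_ids = list(self.ref_bb)
        self.mdl_ids = list(self.mdl_bb)
        # intra-chain contact lists: (i, j, d)
        self._intra: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.total_contacts = 0
        for cid, (pos, mask) in self.ref_bb.items():
            d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            d[~mask, :] = np.nan
            d[:, ~mask] = np.nan
            iu, ju = np.triu_indices(len(pos), k=1)
            with np.errstate(invalid="ignore"):
                sel = d[iu, ju] <= self.radius
            self._intra[cid] = (iu[sel], ju[sel], d[iu, ju][sel])
            self.total_contacts += int(sel.sum())
        self._inter: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for i, a in enumerate(self.ref_ids):
            for b in self.ref_ids[i + 1:]:
                pa, ma = self.ref_bb[a]
                pb, mb = self.ref_bb[b]
                d = np.linalg.norm(pa[:, None] - pb[None, :], axis=2)
                d[~ma, :] = np.nan
                d[:, ~mb] = np.nan
                with np.errstate(invalid="ignore"):
                    ii, jj = np.nonzero(d <= self.radius)
                self._inter[(a, b)] = (ii, jj, d[ii, jj])
                self.total_contacts += len(ii)
        self._single_cache: dict[tuple[str, str], int] = {}
        self._pair_cache: dict[tuple[str, str, str, str], int] = {}

    @staticmethod
    def _bb_coords(chain: Chain) -> tuple[np.ndarray, np.ndarray]:
        n = len(chain.residues)
        pos = np.zeros((n, 3))
        mask = np.zeros(n, dtype=bool)
        for i, res in enumerate(chain.residues):
            a = res.backbone_rep(chain.chain_type)
            if a is not None:
                pos[i] = a.pos
                mask[i] = True
        return pos, mask

    def _model_pos_for(self, ref_cid: str, mdl_cid: str) -> np.ndarray:
        """Model backbone positions indexed by reference residue (NaN gaps)."""
        n = len(self.ref_bb[ref_cid][0])
        out = np.full((n, 3), np.nan)
        mpos, mmask = self.mdl_bb[mdl_cid]
        for ri, mi in self.alignments.get(ref_cid, mdl_cid).pairs:
            if mmask[mi]:
                out[ri] = mpos[mi]
        return out

    def _preserved(self, ii, jj, dref, pos_i, pos_j) -> int:
        dm = np.linalg.norm(pos_i[ii] - pos_j[jj], axis=1)
        delta = np.abs(dm - dref)
        return int(sum((delta <= t).sum() for t in self.thresholds))

    def single(self, ref_cid: str, mdl_cid: str) -> int:
        key = (ref_cid, mdl_cid)
        if key not in self._single_cache:
            ii, jj, dref = self._intra[ref_cid]
            pos = self._model_pos_for(ref_cid, mdl_cid)
            self._single_cache[key] = self._preserved(ii, jj, dref, pos, pos)
        return self._single_cache[key]

    def block(self, ri: str, rj: str, mi: str, mj: str) -> int:
        if (rj, ri) < (ri, rj):
            ri, rj, mi, mj = rj, ri, mj, mi
        key = (ri, rj, mi, mj)
        if key not in self._pair_cache:
            ii, jj, dref = self._inter[(ri, rj)]
            pos_i = self._model_pos_for(ri, mi)
            pos_j = self._model_pos_for(rj, mj)
            self._pair_cache[key] = self._preserved(ii, jj, dref, pos_i, pos_j)
        return self._pair_cache[key]

    def score(self, mapping: dict[str, str]) -> float:
        if self.total_contacts == 0:
            return 0.0
        preserved = sum(self.single(r, m) for r, m in mapping.items())
        for (ri, mi), (rj, mj) in itertools.combinations(sorted(mapping.items()), 2):
            preserved += self.block(ri, rj, mi, mj)
        return preserved / (self.total_contacts * len(self.thresholds))

    # additive-gain API: state = (preserved contact count summed over thresholds,)
    def zero(self) -> np.ndarray:
        return np.zeros(1)

    def seed_gain(self, r: str, m: str) -> np.ndarray:
        return np.array([float(self.single(r, m))])

    def pair_gain(self, r: str, m: str, q: str, mq: str) -> np.ndarray:
        return np.array([float(self.block(r, q, m, mq))])

    def score_vec(self, state: np.ndarray) -> float:
        if self.total_contacts == 0:
            return 0.0
        return float(state[0] / (self.total_contacts * len(self.thresholds)))


# ---------------------------------------------------------------------------
# Accessibility (greedy search space restriction)
# ---------------------------------------------------------------------------

class _Accessibility:
    """Chain-level adjacency used to confine greedy extension candidates."""

    def __init__(self, objective, params: MappingSearchParams, mode: str) -> None:
        self.mode = mode
        self.params = params
        if mode == "qs_score":
            ref_rep, mdl_rep = objective.ref_rep, objective.mdl_rep
        else:
            ref_rep, mdl_rep = objective.ref_bb, objective.mdl_bb
        self.ref_adj = self._adjacency(ref_rep, is_model=False)
        self.mdl_adj = self._adjacency(mdl_rep, is_model=True)

    def _adjacency(self, reps: dict, is_model: bool) -> dict[str, set[str]]:
        p = self.params
        if self.mode == "qs_score":
            dist = p.qs_accessibility_dist
            contact_dist = p.qs_contact_dist
            min_contacts = p.min_interface_contacts
        else:
            dist = p.lddt_inclusion_radius + (p.lddt_max_deviation if is_model else 0.0)
            contact_dist = None
            min_contacts = 0
        ids = list(reps)
        adj: dict[str, set[str]] = {cid: set() for cid in ids}
        for i, a in enumerate(ids):
            pa, ma = reps[a]
            for b in ids[i + 1:]:
                pb, mb = reps[b]
                if not ma.any() or not mb.any():
                    continue
                d = np.linalg.norm(pa[ma][:, None] - pb[mb][None, :], axis=2)
                if d.min() > dist:
                    continue
                if contact_dist is not None and (d <= contact_dist).sum() < min_contacts:
                    continue
                adj[a].add(b)
                adj[b].add(a)
        return adj

    def accessible(self, ref_cid: str, mdl_cid: str,
                   mapping: dict[str, str]) -> bool:
        if not mapping:
            return True
        ok_ref = any(q in self.ref_adj[ref_cid] for q in mapping)
        ok_mdl = any(mv in self.mdl_adj[mdl_cid] for mv in mapping.values())
        return ok_ref and ok_mdl


# ---------------------------------------------------------------------------
# QSMap
# ---------------------------------------------------------------------------

def _target_size(grouping: GroupingResult) -> int:
    return sum(min(len(g.reference_chain_ids), len(g.model_chain_ids))
               for g in grouping.groups)


def _candidate_pairs(grouping: GroupingResult, mapping: dict[str, str]):
    used_mdl = set(mapping.values())
    for g in grouping.groups:
        for r in g.reference_chain_ids:
            if r in mapping:
                continue
            for m in g.model_chain_ids:
                if m not in used_mdl:
                    yield r, m


def _greedy_extend(mapping0: dict[str, str], grouping: GroupingResult,
                   objective, access: Optional[_Accessibility]):
    """Incremental greedy extension: candidate gains are additive vectors
    updated as pairs are added, so each step costs O(#candidates)."""
    target = _target_size(grouping)
    mapping = dict(mapping0)
    state = objective.zero()
    items = sorted(mapping.items())
    for r, m in items:
        state = state + objective.seed_gain(r, m)
    for (r, m), (q, mq) in itertools.combinations(items, 2):
        state = state + objective.pair_gain(r, m, q, mq)
    gains: dict[tuple[str, str], np.ndarray] = {}
    for r, m in _candidate_pairs(grouping, mapping):
        g = objective.seed_gain(r, m)
        for q, mq in mapping.items():
            g = g + objective.pair_gain(r, m, q, mq)
        gains[(r, m)] = g
    while len(mapping) < target and gains:
        best_pair, best_score = None, -np.inf
        for (r, m) in sorted(gains):
            if access is not None and not access.accessible(r, m, mapping):
                continue
            s = objective.score_vec(state + gains[(r, m)])
            if s > best_score:
                best_pair, best_score = (r, m), s
        if best_pair is None:
            break  # stalled: no accessible extension
        r0, m0 = best_pair
        state = state + gains[best_pair]
        mapping[r0] = m0
        gains = {(r, m): g for (r, m), g in gains.items() if r != r0 and m != m0}
        for (r, m) in gains:
            gains[(r, m)] = gains[(r, m)] + objective.pair_gain(r, m, r0, m0)
    return mapping, objective.score_vec(state)


def _greedy_from_seed(seed: tuple[str, str], grouping: GroupingResult,
                      objective, access: Optional[_Accessibility]):
    """Greedy extension per the published scheme; stalled (disconnected)
    mappings are re-seeded with every possible unmapped pair and the best
    continuation is kept, enforcing a full mapping."""
    target = _target_size(grouping)
    mapping, score = _greedy_extend({seed[0]: seed[1]}, grouping, objective, access)
    while len(mapping) < target:
        best_cont, best_score = None, -np.inf
        for r, m in _candidate_pairs(grouping, mapping):
            trial, s = _greedy_extend({**mapping, r: m}, grouping, objective, access)
            if s > best_score:
                best_cont, best_score = trial, s
        if best_cont is None or len(best_cont) == len(mapping):
            break
        mapping, score = best_cont, best_score
    return mapping, score


def _search(grouping: GroupingResult, objective, access, exhaustive: bool):
    if exhaustive:
        best_mapping, best_score = None, -np.inf
        n = 0
        for mapping in _enumerate_mappings(grouping):
            n += 1
            s = objective.score(mapping)
            if s > best_score:
                best_mapping, best_score = mapping, s
        return best_mapping or {}, best_score, "exhaustive", n
    best_mapping, best_score = None, -np.inf
    seeds = 0
    for g in grouping.groups:
        for r in g.reference_chain_ids:
            for m in g.model_chain_ids:
                seeds += 1
                mapping, s = _greedy_from_seed((r, m), grouping, objective, access)
                if len(mapping) == _target_size(grouping) and s > best_score:
                    best_mapping, best_score = mapping, s
    if best_mapping is None:  # disconnected beyond repair; best partial wins
        for g in grouping.groups:
            for r in g.reference_chain_ids:
                for m in g.model_chain_ids:
                    mapping, s = _greedy_from_seed((r, m), grouping, objective, None)
                    if s > best_score:
                        best_mapping, best_score = mapping, s
    return best_mapping or {}, best_score, "greedy", seeds


def qsmap(
    reference: Structure,
    model: Structure,
    grouping: GroupingResult,
    params: Optional[MappingSearchParams] = None,
    alignment_params: Optional[AlignmentParams] = None,
) -> ChainMapping:
    """QSMap chain mapping: global QS-score optimum for small problems,
    greedy best-of-all-seeds otherwise; backbone LDDT objective whenever
    nucleotide chains are present."""
    params = params or MappingSearchParams()
    has_nuc = any(c.chain_type == NUCLEOTIDE for c in
                  list(reference.polymer_chains) + list(model.polymer_chains))
    aln_cache = _AlignmentCache(reference, model, alignment_params or AlignmentParams())
    if has_nuc:
        objective = _BbLddtObjective(reference, model, aln_cache, params)
    else:
        objective = _QsObjective(reference, model, aln_cache, params)
    return _run_mapping(objective, grouping, params, aln_cache,
                        exhaustive_limit=params.exhaustive_limit_qsmap)


def _run_mapping(objective, grouping, params, aln_cache, exhaustive_limit):
    if _target_size(grouping) == 0:
        logger.warning("no mappable chains; returning empty mapping")
        return ChainMapping({}, objective.name, None, complete=False,
                            search_mode="trivial")
    size = problem_size(grouping)
    exhaustive = size <= math.factorial(exhaustive_limit)
    if params.force_greedy:
        exhaustive = False
    if params.force_exhaustive:
        exhaustive = True
    access = None if exhaustive else _Accessibility(objective, params, objective.name)
    mapping, score, mode, seeds = _search(grouping, objective, access, exhaustive)
    alignments = {(r, m): aln_cache.get(r, m) for r, m in mapping.items()}
    return ChainMapping(mapping, objective.name, score,
                        complete=len(mapping) == _target_size(grouping),
                        search_mode=mode, seeds_evaluated=seeds,
                        alignments=alignments)


# ---------------------------------------------------------------------------
# QSMapR
# ---------------------------------------------------------------------------

class _RmsdObjective:
    """Backbone RMSD over subsampled per-group alignment columns."""

    name = "rmsd"

    def __init__(self, reference: Structure, model: Structure,
                 grouping: GroupingResult, alignments: _AlignmentCache,
                 params: MappingSearchParams,
                 alignment_params: AlignmentParams) -> None:
        self.alignments = alignments
        self.coords: dict[str, np.ndarray] = {}
        from .grouping import align_pair
        for g in grouping.groups:
            rep_seq = g.representative_sequence
            members: list[tuple[str, Chain, bool]] = \
                [(cid, reference.chain(cid), True) for cid in g.reference_chain_ids] + \
                [(cid, model.chain(cid), False) for cid in g.model_chain_ids]
            # representative columns covered in every member sequence with a
            # backbone representative present
            covered = np.ones(len(rep_seq), dtype=bool)
            col_maps: dict[tuple[str, bool], dict[int, int]] = {}
            for cid, chain, is_ref in members:
                if alignment_params.mode == "residue_number":
                    lut = {}
                    rep_numbers = {i: i + 1 for i in range(len(rep_seq))}
                    by_num = {r.number: j for j, r in enumerate(chain.residues)}
                    for col, num in rep_numbers.items():
                        if num in by_num:
                            lut[col] = by_num[num]
                else:
                    from .model import extract_sequence
                    aln = align_pair(rep_seq, extract_sequence(chain),
                                     g.chain_type, alignment_params)
                    lut = dict(aln.pairs)
                mask = np.zeros(len(rep_seq), dtype=bool)
                for col, j in lut.items():
                    res = chain.residues[j]
                    if res.backbone_rep(chain.chain_type) is not None:
                        mask[col] = True
                covered &= mask
                col_maps[(cid, is_ref)] = lut
            cols = np.flatnonzero(covered)
            n = params.msa_subsample_columns
            if len(cols) > n:
                cols = cols[np.unique(np.linspace(0, len(cols) - 1, n).astype(int))]
            for cid, chain, is_ref in members:
                lut = col_maps[(cid, is_ref)]
                pts = np.array([chain.residues[lut[c]].backbone_rep(chain.chain_type).pos
                                for c in cols]) if len(cols) else np.zeros((0, 3))
                self.coords[("R" if is_ref else "M") + cid] = pts

    def stacked(self, mapping: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
        items = sorted(mapping.items())
        ref = np.vstack([self.coords["R" + r] for r, _ in items]) if items else np.zeros((0, 3))
        mdl = np.vstack([self.coords["M" + m] for _, m in items]) if items else np.zeros((0, 3))
        return ref, mdl

    def rmsd_of(self, mapping: dict[str, str]) -> float:
        ref, mdl = self.stacked(mapping)
        if len(ref) < 3:
            return float("inf")
        rot, t = kabsch(mdl, ref)
        return rmsd(apply_transform(mdl, rot, t), ref)

    # greedy API: maximize score == minimize RMSD
    def score(self, mapping: dict[str, str]) -> float:
        return -self.rmsd_of(mapping)


def _qsmapr_greedy(grouping: GroupingResult, objective: _RmsdObjective):
    """Greedy extension with one Kabsch per step: candidates are ranked by
    their RMSD under the current superposition, then the transform is
    refitted after each addition."""
    target = _target_size(grouping)
    best_mapping, best_rmsd = None, np.inf
    seeds = 0
    for g in grouping.groups:
        for r0 in g.reference_chain_ids:
            for m0 in g.model_chain_ids:
                seeds += 1
                mapping = {r0: m0}
                while len(mapping) < target:
                    ref, mdl = objective.stacked(mapping)
                    if len(ref) >= 3:
                        rot, t = kabsch(mdl, ref)
                    else:
                        rot, t = np.eye(3), np.zeros(3)
                    best_pair, best_val = None, np.inf
                    for r, m in _candidate_pairs(grouping, mapping):
                        moved = apply_transform(objective.coords["M" + m], rot, t)
                        val = rmsd(moved, objective.coords["R" + r]) \
                            if len(moved) else np.inf
                        if val < best_val or (val == best_val and best_pair is not None
                                              and (r, m) < best_pair):
                            best_pair, best_val = (r, m), val
                    if best_pair is None:
                        break
                    mapping[best_pair[0]] = best_pair[1]
                if len(mapping) == target:
                    final = objective.rmsd_of(mapping)
                    if final < best_rmsd:
                        best_mapping, best_rmsd = mapping, final
    return best_mapping or {}, best_rmsd, seeds


def qsmapr(
    reference: Structure,
    model: Structure,
    grouping: GroupingResult,
    params: Optional[MappingSearchParams] = None,
    alignment_params: Optional[AlignmentParams] = None,
) -> ChainMapping:
    """QSMapR chain mapping: minimal backbone RMSD over group-respecting
    mappings; exhaustive enumeration for small problems, greedy otherwise."""
    params = params or MappingSearchParams()
    alignment_params = alignment_params or AlignmentParams()
    aln_cache = _AlignmentCache(reference, model, alignment_params)
    if _target_size(grouping) == 0:
        logger.warning("no mappable chains; returning empty mapping")
        return ChainMapping({}, "rmsd", None, complete=False, search_mode="trivial")
    objective = _RmsdObjective(reference, model, grouping, aln_cache,
                               params, alignment_params)
    size = problem_size(grouping)
    exhaustive = size <= math.factorial(params.exhaustive_limit_qsmapr)
    if params.force_greedy:
        exhaustive = False
    if params.force_exhaustive:
        exhaustive = True
    if exhaustive:
        best_mapping, best_rmsd = None, np.inf
        n = 0
        for mapping in _enumerate_mappings(grouping):
            n += 1
            val = objective.rmsd_of(mapping)
            if val < best_rmsd:
                best_mapping, best_rmsd = mapping, val
        mapping, value, mode, seeds = best_mapping or {}, best_rmsd, "exhaustive", n
    else:
        mapping, value, seeds = _qsmapr_greedy(grouping, objective)
        mode = "greedy"
    alignments = {(r, m): aln_cache.get(r, m) for r, m in mapping.items()}
    return ChainMapping(mapping, "rmsd", float(value) if np.isfinite(value) else None,
                        complete=len(mapping) == _target_size(grouping),
                        search_mode=mode, seeds_evaluated=seeds,
                        alignments=alignments)
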