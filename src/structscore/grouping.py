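"""Sequence-based grouping of polymer chains.

Chains are compared by global Needleman–Wunsch alignment (BLOSUM62 for
proteins, NUC44 for nucleotides) and grouped into sets of chemically
equivalent chains: reference chains by single-linkage clustering at 95%
sequence identity (or directly by mmCIF entity records when present), model
chains by best-identity assignment to a reference group at a relaxed 70%
threshold.  Alternatively, alignments can be built purely from residue
numbers, the recommended mode when models are numbered according to the
target sequence.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .model import NONPOLYMER, NUCLEOTIDE, PEPTIDE, Chain, Structure, extract_sequence
from .model import MIN_LEN_NUCLEOTIDE, MIN_LEN_PEPTIDE

logger = logging.getLogger(__name__)

SEQUENCE_MODE = "sequence"
RESIDUE_NUMBER_MODE = "residue_number"


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment configuration shared by grouping and residue mapping."""

    mode: str = SEQUENCE_MODE
    protein_gap_open: float = -11.0
    protein_gap_extend: float = -1.0
    nucleotide_gap_open: float = -5.0
    nucleotide_gap_extend: float = -2.0
    cluster_threshold: float = 0.95
    assign_threshold: Optional[float] = 0.70


@dataclass
class PairAlignment:
    """Residue-index correspondence between two chains/sequences."""

    pairs: list[tuple[int, int]]
    identity: float
    n_aligned: int


@functools.lru_cache(maxsize=4)
def _aligner(chain_type: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(
        "BLOSUM62" if chain_type == PEPTIDE else "NUC.4.4")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _prepare(seq: str, chain_type: str) -> str:
    if chain_type == PEPTIDE:
        return "".join(c if c in "ARNDCQEGHILKMFPSTWYVBZX" else "X" for c in seq)
    # NUC44 has no U column; RNA is aligned on the DNA alphabet
    seq = seq.replace("U", "T")
    return "".join(c if c in "ATGCSWRYKMBVHDN" else "N" for c in seq)


_CACHE: dict[tuple, PairAlignment] = {}


def align_pair(a: str, b: str, chain_type: str = PEPTIDE,
               params: Optional[AlignmentParams] = None) -> PairAlignment:
    """Global pairwise alignment and sequence identity of two sequences.

    Identity is the fraction of identical columns among aligned (non-gap)
    column pairs.
    """
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if chain_type == PEPTIDE:
        go, ge = params.protein_gap_open, params.protein_gap_extend
    else:
        go, ge = params.nucleotide_gap_open, params.nucleotide_gap_extend
    key = (a, b, chain_type, go, ge)
    hit = _CACHE.get(key)
    if hit is not None:
        return hit
    aligner = _aligner(chain_type, go, ge)
    aln = aligner.align(_prepare(a, chain_type), _prepare(b, chain_type))[0]
    pairs: list[tuple[int, int]] = []
    identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if a[i] == b[j]:
                identical += 1
    identity = identical / len(pairs) if pairs else 0.0
    result = PairAlignment(pairs=pairs, identity=identity, n_aligned=len(pairs))
    if len(_CACHE) > 100000:
        _CACHE.clear()
    _CACHE[key] = result
    return result


def align_chains(ref_chain: Chain, mdl_chain: Chain,
                 params: Optional[AlignmentParams] = None) -> PairAlignment:
    """Residue-index correspondence between a reference and a model chain.

    ``sequence`` mode aligns one-letter sequences; ``residue_number`` mode
    pairs residues with equal (number, insertion code).
    """
    params = params or AlignmentParams()
    if ref_chain.chain_type == NONPOLYMER or mdl_chain.chain_type == NONPOLYMER:
        raise ValueError("polymer chains required")
    if ref_chain.chain_type != mdl_chain.chain_type:
        raise ValueError(
            f"cannot align {ref_chain.chain_type} chain {ref_chain.id} "
            f"with {mdl_chain.chain_type} chain {mdl_chain.id}")
    if params.mode == RESIDUE_NUMBER_MODE:
        by_id = {r.id: j for j, r in enumerate(mdl_chain.residues)}
        pairs = [(i, by_id[r.id]) for i, r in enumerate(ref_chain.residues)
                 if r.id in by_id]
        identical = sum(1 for i, j in pairs
                        if ref_chain.residues[i].one_letter == mdl_chain.residues[j].one_letter)
        identity = identical / len(pairs) if pairs else 0.0
        return PairAlignment(pairs=pairs, identity=identity, n_aligned=len(pairs))
    return align_pair(extract_sequence(ref_chain), extract_sequence(mdl_chain),
                      ref_chain.chain_type, params)


@dataclass
class ChainGroup:
    """Chemically equivalent chains sharing a representative sequence."""

    representative_sequence: str
    chain_type: str
    reference_chain_ids: list[str] = field(default_factory=list)
    model_chain_ids: list[str] = field(default_factory=list)


@dataclass
class GroupingResult:
    groups: list[ChainGroup]
    unmapped_model_chains: list[str] = field(default_factory=list)

    def group_of_reference(self, chain_id: str) -> Optional[ChainGroup]:
        for g in self.groups:
            if chain_id in g.reference_chain_ids:
                return g
        return None

    def group_of_model(self, chain_id: str) -> Optional[ChainGroup]:
        for g in self.groups:
            if chain_id in g.model_chain_ids:
                return g
        return None


def _eligible(chain: Chain) -> bool:
    if chain.chain_type == NONPOLYMER:
        return False
    min_len = MIN_LEN_PEPTIDE if chain.chain_type == PEPTIDE else MIN_LEN_NUCLEOTIDE
    return len(chain.residues) >= min_len


def group_reference_chains(reference: Structure,
                           params: Optional[AlignmentParams] = None) -> list[ChainGroup]:
    """Group reference chains into sets of chemically identical chains.

    mmCIF entity records define groups directly when every polymer chain
    carries one; otherwise single-linkage clustering over the >= 95%
    sequence-identity graph is used, separately for proteins and
    nucleotides.  The longest chain of a cluster is its representative
    (ties: lexicographically smallest chain id).
    """
    params = params or AlignmentParams()
    chains = sorted((c for c in reference.polymer_chains if _eligible(c)),
                    key=lambda c: c.id)
    if not chains:
        return []
    if all(c.entity_id is not None for c in chains):
        clusters: dict[tuple[str, str], list[Chain]] = {}
        for c in chains:
            clusters.setdefault((c.chain_type, c.entity_id), []).append(c)
        cluster_list = list(clusters.values())
    else:
        import networkx as nx
        cluster_list = []
        for ctype in (PEPTIDE, NUCLEOTIDE):
            members = [c for c in chains if c.chain_type == ctype]
            g = nx.Graph()
            g.add_nodes_from(c.id for c in members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    aln = align_pair(extract_sequence(a), extract_sequence(b),
                                     ctype, params)
                    if aln.identity >= params.cluster_threshold:
                        g.add_edge(a.id, b.id)
            by_id = {c.id: c for c in members}
            for comp in sorted(nx.connected_components(g), key=min):
                cluster_list.append([by_id[cid] for cid in sorted(comp)])
    groups = []
    for cluster in cluster_list:
        rep = max(cluster, key=lambda c: (len(c.residues), [-ord(x) for x in c.id]))
        groups.append(ChainGroup(
            representative_sequence=extract_sequence(rep),
            chain_type=cluster[0].chain_type,
            reference_chain_ids=sorted(c.id for c in cluster)))
    groups.sort(key=lambda g: g.reference_chain_ids[0])
    return groups


def assign_model_chains(model: Structure, groups: list[ChainGroup],
                        params: Optional[AlignmentParams] = None,
                        identity_threshold: Optional[float] = 0.70) -> GroupingResult:
    """Assign each model chain to the reference group of maximal sequence
    identity with the group representative; chains below the threshold (or
    of a type with no groups) are reported unmapped.  Pass
    ``identity_threshold=None`` to force assignment of every chain."""
    params = params or AlignmentParams()
    result = GroupingResult(groups=[ChainGroup(
        representative_sequence=g.representative_sequence,
        chain_type=g.chain_type,
        reference_chain_ids=list(g.reference_chain_ids)) for g in groups])
    for chain in sorted(model.polymer_chains, key=lambda c: c.id):
        if not _eligible(chain):
            result.unmapped_model_chains.append(chain.id)
            continue
        best: Optional[tuple[float, ChainGroup]] = None
        seq = extract_sequence(chain)
        for g in result.groups:
            if g.chain_type != chain.chain_type:
                continue
            aln = align_pair(seq, g.representative_sequence, chain.chain_type, params)
            if best is None or aln.identity > best[0]:
                best = (aln.identity, g)
        if best is None:
            result.unmapped_model_chains.append(chain.id)
            continue
        identity, group = best
        if identity_threshold is not None and identity < identity_threshold:
            logger.info("model chain %s unmapped (best identity %.2f < %.2f)",
                        chain.id, identity, identity_threshold)
            result.unmapped_model_chains.append(chain.id)
        else:
            group.model_chain_ids.append(chain.id)
    return result
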