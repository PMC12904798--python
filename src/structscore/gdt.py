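"""Global distance test (GDT) and backbone RMSD.

GDT reports, per distance threshold, the largest fraction of reference
representative positions (Cα for peptides, C3′ for nucleotides) that can be
brought within the threshold of their model counterparts by one rigid
superposition.  Search strategy: sliding windows of sizes 7, 9, 12, 24 and
48 over the mapped positions seed an iterative refinement — superpose on
the current set, then replace it with all pairs within the threshold —
until the set stops changing; the largest set ever observed wins.  Each
window size is placed at most 1000 times, at equidistant offsets.

GDT_TS averages the fractions at 1, 2, 4 and 8 Å; GDT_HA at 0.5, 1, 2 and
4 Å.  Both are reported on a 0–1 scale.  Incomplete models are penalized:
the denominator is the number of reference positions, mapped or not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .grouping import PairAlignment
from .model import Structure
from .superpose import apply_transform, kabsch, rmsd

TS_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class GdtParams:
    window_sizes: tuple[int, ...] = (7, 9, 12, 24, 48)
    max_windows_per_size: int = 1000
    max_iterations: int = 10


@dataclass
class GdtResult:
    gdt_ts: Optional[float]
    gdt_ha: Optional[float]
    fractions: dict[float, float]
    n_reference_positions: int
    reason: Optional[str] = None


def mapped_positions(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired representative coordinates and the total count of reference
    representative positions (the GDT denominator)."""
    ref_pts, mdl_pts = [], []
    n_reference = 0
    mdl_chains = {c.id: c for c in model.polymer_chains}
    for chain in reference.polymer_chains:
        reps = [(ri, res.backbone_rep(chain.chain_type)) for ri, res in enumerate(chain.residues)]
        reps = [(ri, a) for ri, a in reps if a is not None]
        n_reference += len(reps)
        if chain.id not in mapping or mapping[chain.id] not in mdl_chains:
            continue
        lut = dict(alignments[chain.id].pairs)
        mdl_chain = mdl_chains[mapping[chain.id]]
        for ri, atom in reps:
            if ri not in lut:
                continue
            matom = mdl_chain.residues[lut[ri]].backbone_rep(mdl_chain.chain_type)
            if matom is not None:
                ref_pts.append(atom.pos)
                mdl_pts.append(matom.pos)
    if not ref_pts:
        return np.zeros((0, 3)), np.zeros((0, 3)), n_reference
    return np.asarray(ref_pts), np.asarray(mdl_pts), n_reference


def _largest_set(ref: np.ndarray, mdl: np.ndarray, threshold: float,
                 params: GdtParams) -> int:
    n = len(ref)
    best = 0
    seeds: list[np.ndarray] = []
    for w in params.window_sizes:
        w = min(w, n)
        n_starts = n - w + 1
        if n_starts <= params.max_windows_per_size:
            starts = range(n_starts)
        else:
            starts = np.unique(np.linspace(0, n_starts - 1,
                                           params.max_windows_per_size).astype(int))
        for s in starts:
            seeds.append(np.arange(s, s + w))
    for seed in seeds:
        current = seed
        seen: set[bytes] = set()
        for _ in range(params.max_iterations):
            if len(current) < 3:
                break
            rot, t = kabsch(mdl[current], ref[current])
            moved = apply_transform(mdl, rot, t)
            dist = np.linalg.norm(moved - ref, axis=1)
            nxt = np.flatnonzero(dist <= threshold)
            best = max(best, len(nxt))
            key = nxt.tobytes()
            if key in seen or len(nxt) == 0:
                break
            seen.add(key)
            current = nxt
    return best


def gdt(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
    params: Optional[GdtParams] = None,
) -> GdtResult:
    """GDT_TS / GDT_HA over the union of TS and HA thresholds."""
    params = params or GdtParams()
    ref, mdl, n_reference = mapped_positions(reference, model, mapping, alignments)
    if len(ref) < 3:
        return GdtResult(None, None, {}, n_reference,
                         reason="fewer than 3 mapped representative positions")
    thresholds = sorted(set(TS_THRESHOLDS) | set(HA_THRESHOLDS))
    fractions = {t: _largest_set(ref, mdl, t, params) / n_reference for t in thresholds}
    gdt_ts = float(np.mean([fractions[t] for t in TS_THRESHOLDS]))
    gdt_ha = float(np.mean([fractions[t] for t in HA_THRESHOLDS]))
    return GdtResult(gdt_ts, gdt_ha, fractions, n_reference)


def backbone_rmsd(
    reference: Structure,
    model: Structure,
    mapping: dict[str, str],
    alignments: dict[str, PairAlignment],
) -> Optional[float]:
    """Minimal RMSD over all mapped representative positions after one
    Kabsch superposition; None with fewer than 3 mapped positions."""
    ref, mdl, _ = mapped_positions(reference, model, mapping, alignments)
    if len(ref) < 3:
        return None
    rot, t = kabsch(mdl, ref)
    return rmsd(apply_transform(mdl, rot, t), ref)
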