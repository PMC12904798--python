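"""End-to-end comparison pipelines and machine-readable reports.

``compare_structures`` covers polymer scores (LDDT family, QS-score,
ICS/IPS, DockQ family, GDT, RMSD) on top of automatic chain mapping;
``compare_ligand_structures`` covers the ligand scores with matching and
assignment.  Every score is reported either as a number or as null plus a
reason; per-score failures never abort the run.  Reports embed the full
configuration and are deterministic for identical inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from . import __version__
from .dockq import dockq, dockq_aggregate
from .gdt import GdtParams, backbone_rmsd, gdt
from .grouping import (AlignmentParams, RESIDUE_NUMBER_MODE, SEQUENCE_MODE,
                       assign_model_chains, group_reference_chains)
from .interfaces import ics_ips
from .io import read_structure
from .lddt import LddtParams, default_params_for, lddt_score
from .ligand_scores import assign_ligands, bisy_rmsd, lddt_pli
from .ligands import match_ligands, read_ligand_sdf
from .mapping import MappingSearchParams, qsmap, qsmapr
from .model import Structure, cleanup_polymer

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one comparison run; embedded verbatim in reports."""

    reference: str = ""
    model: str = ""
    reference_ligands: list[str] = field(default_factory=list)
    model_ligands: list[str] = field(default_factory=list)
    residue_number_alignment: bool = False
    # polymer score selection
    lddt: bool = False
    bb_lddt: bool = False
    i_lddt: bool = False
    qs_score: bool = False
    ics_ips: bool = False
    dockq: bool = False
    dockq_capri_peptide: bool = False
    gdt: bool = False
    rmsd: bool = False
    stereo_checks: bool = False
    # ligand parameters
    radius: float = 4.0
    lddt_pli_radius: float = 6.0
    coverage_delta: float = 0.2
    substructure_match: bool = False
    # numeric knobs
    seqid_cluster_threshold: float = 0.95
    seqid_assign_threshold: Optional[float] = 0.70
    output: Optional[str] = None

    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(
            mode=RESIDUE_NUMBER_MODE if self.residue_number_alignment else SEQUENCE_MODE,
            cluster_threshold=self.seqid_cluster_threshold,
            assign_threshold=self.seqid_assign_threshold)


def _score_entry(value, reason: Optional[str] = None):
    if value is None:
        return {"value": None, "reason": reason or "not computable"}
    return {"value": value}


def _load_pair(config: RunConfig, replace_nonstandard: bool,
               extract_ligands: bool) -> tuple[Structure, Structure]:
    reference = read_structure(config.reference, extract_ligands=extract_ligands)
    model = read_structure(config.model, extract_ligands=extract_ligands)
    ref_clean = cleanup_polymer(reference, replace_nonstandard=replace_nonstandard)
    mdl_clean = cleanup_polymer(model, replace_nonstandard=replace_nonstandard)
    ref_clean.ligands = reference.ligands
    mdl_clean.ligands = model.ligands
    return ref_clean, mdl_clean


def compare_structures(config: RunConfig,
                       reference: Optional[Structure] = None,
                       model: Optional[Structure] = None) -> dict:
    """Run the polymer comparison pipeline and return the report dict.

    Structures may be passed directly (already cleaned) instead of paths.
    """
    if reference is None or model is None:
        reference, model = _load_pair(config, replace_nonstandard=True,
                                      extract_ligands=False)
    aln_params = config.alignment_params()
    groups = group_reference_chains(reference, aln_params)
    grouping = assign_model_chains(model, groups, aln_params,
                                   identity_threshold=config.seqid_assign_threshold)
    report: dict = {
        "tool": {"name": "structscore", "version": __version__},
        "config": dataclasses.asdict(config),
        "chain_groups": [{"reference_chains": g.reference_chain_ids,
                          "model_chains": g.model_chain_ids,
                          "chain_type": g.chain_type} for g in grouping.groups],
        "unmapped_model_chains": grouping.unmapped_model_chains,
        "scores": {},
    }
    scores = report["scores"]

    need_qsmap = any([config.lddt, config.bb_lddt, config.i_lddt, config.qs_score,
                      config.ics_ips, config.dockq])
    need_qsmapr = config.gdt or config.rmsd
    cmap = qsmap(reference, model, grouping,
                 alignment_params=aln_params) if need_qsmap else None
    cmap_r = qsmapr(reference, model, grouping,
                    alignment_params=aln_params) if need_qsmapr else None
    for name, cm in (("qsmap", cmap), ("qsmapr", cmap_r)):
        if cm is not None:
            report[name] = {"pairs": cm.pairs, "objective": cm.objective,
                            "objective_value": cm.objective_value,
                            "search_mode": cm.search_mode,
                            "seeds_evaluated": cm.seeds_evaluated,
                            "complete": cm.complete}

    def alignments_of(cm):
        return {r: cm.alignments[(r, m)] for r, m in cm.pairs.items()}

    if config.lddt or config.bb_lddt or config.i_lddt:
        alns = alignments_of(cmap)
        for flag, variant, key in ((config.lddt, "full", "lddt"),
                                   (config.bb_lddt, "backbone", "bb_lddt"),
                                   (config.i_lddt, "interface_only", "i_lddt")):
            if not flag:
                continue
            base = default_params_for(reference, variant)
            params = dataclasses.replace(base, stereo_checks=config.stereo_checks)
            res = lddt_score(reference, model, cmap.pairs, alns, params)
            scores[key] = _score_entry(res.score, res.reason)
            if res.score is not None and variant == "full":
                report["per_residue_lddt"] = {
                    f"{cid}.{ri}": (None if v is None else round(v, 4))
                    for (cid, ri), v in res.per_residue.items()}
    if config.qs_score:
        from .qs import qs_score as qs_fn
        res = qs_fn(reference, model, cmap.pairs, alignments_of(cmap))
        scores["qs_global"] = _score_entry(res.qs_global, res.reason)
        scores["qs_best"] = _score_entry(res.qs_best, res.reason)
    if config.ics_ips:
        alns = alignments_of(cmap)
        for trimmed, suffix in ((False, ""), (True, "_trimmed")):
            res = ics_ips(reference, model, cmap.pairs, alns, trimmed=trimmed)
            scores["ics" + suffix] = _score_entry(res.ics, res.reason)
            scores["ips" + suffix] = _score_entry(res.ips, res.reason)
            if not trimmed and res.per_interface:
                report["per_interface_ics_ips"] = {
                    f"{a}-{b}": v for (a, b), v in res.per_interface.items()}
    if config.dockq:
        alns = alignments_of(cmap)
        from .interfaces import residue_contacts
        ref_contacts = residue_contacts(reference)
        interfaces = sorted({tuple(sorted((c1[0], c2[0])))
                             for (c1, c2) in ref_contacts})
        components = []
        per_interface = {}
        for pair in interfaces:
            if pair[0] not in cmap.pairs or pair[1] not in cmap.pairs:
                per_interface["-".join(pair)] = {"value": None,
                                                 "reason": "interface chains unmapped"}
                continue
            comp = dockq(reference, model, cmap.pairs, alns, pair,
                         capri_peptide=config.dockq_capri_peptide)
            components.append(comp)
            per_interface["-".join(pair)] = {
                "fnat": comp.fnat, "fnonnat": comp.fnonnat,
                "i_rmsd": comp.i_rmsd, "l_rmsd": comp.l_rmsd,
                "dockq": comp.dockq, "receptor": comp.receptor,
                "n_native_contacts": comp.n_native_contacts}
        report["dockq_per_interface"] = per_interface
        agg = dockq_aggregate(components)
        scores["dockq_ave"] = _score_entry(agg["dockq_ave"],
                                           "no scoreable interface")
        scores["dockq_wave"] = _score_entry(agg["dockq_wave"],
                                            "no scoreable interface")
    if config.gdt:
        res = gdt(reference, model, cmap_r.pairs, alignments_of(cmap_r))
        scores["gdt_ts"] = _score_entry(res.gdt_ts, res.reason)
        scores["gdt_ha"] = _score_entry(res.gdt_ha, res.reason)
    if config.rmsd:
        value = backbone_rmsd(reference, model, cmap_r.pairs, alignments_of(cmap_r))
        scores["rmsd"] = _score_entry(value, "fewer than 3 mapped positions")
    return report


def compare_ligand_structures(config: RunConfig,
                              reference: Optional[Structure] = None,
                              model: Optional[Structure] = None) -> dict:
    """Run the ligand comparison pipeline and return the report dict.

    Ligands come from SDF files when given, otherwise from nonpolymer
    entities of the input structures.  Receptor cleanup keeps nonstandard
    residues.
    """
    if reference is None or model is None:
        reference, model = _load_pair(config, replace_nonstandard=False,
                                      extract_ligands=True)
    ref_ligands = list(reference.ligands)
    mdl_ligands = list(model.ligands)
    if config.reference_ligands:
        ref_ligands = [read_ligand_sdf(p) for p in config.reference_ligands]
    if config.model_ligands:
        mdl_ligands = [read_ligand_sdf(p) for p in config.model_ligands]
    aln_params = config.alignment_params()
    report: dict = {
        "tool": {"name": "structscore", "version": __version__},
        "config": dataclasses.asdict(config),
        "reference_ligands": [lig.id for lig in ref_ligands],
        "model_ligands": [lig.id for lig in mdl_ligands],
        "pairs": [],
    }
    bisy_candidates = []
    pli_candidates = []
    for rlig in ref_ligands:
        for mlig in mdl_ligands:
            match = match_ligands(rlig, mlig,
                                  allow_subgraph=config.substructure_match)
            if match is None:
                continue
            entry = {"reference_ligand": rlig.id, "model_ligand": mlig.id,
                     "coverage": match.coverage,
                     "n_symmetries": len(match.correspondences)}
            res = bisy_rmsd(reference, model, rlig, mlig, match,
                            site_radius=config.radius,
                            alignment_params=aln_params)
            entry["bisy_rmsd"] = _score_entry(res.bisy_rmsd,
                                              res.reasons.get("bisy_rmsd"))
            entry["rmsd_lp"] = _score_entry(res.rmsd_lp,
                                            res.reasons.get("bisy_rmsd"))
            entry["lddt_lp"] = _score_entry(res.lddt_lp,
                                            res.reasons.get("bisy_rmsd"))
            entry["site_residues"] = len(res.site) if res.site else 0
            entry["chain_mapping"] = res.chain_mapping
            pli, reason = lddt_pli(reference, model, rlig, mlig, match,
                                   inclusion_radius=config.lddt_pli_radius,
                                   alignment_params=aln_params)
            entry["lddt_pli"] = _score_entry(pli, reason)
            report["pairs"].append(entry)
            if res.bisy_rmsd is not None:
                bisy_candidates.append((rlig.id, mlig.id, match.coverage, res.bisy_rmsd))
            if pli is not None:
                pli_candidates.append((rlig.id, mlig.id, match.coverage, pli))
    ref_ids = [lig.id for lig in ref_ligands]
    mdl_ids = [lig.id for lig in mdl_ligands]
    for name, cands, higher in (("bisy_rmsd", bisy_candidates, False),
                                ("lddt_pli", pli_candidates, True)):
        asg = assign_ligands(cands, ref_ids, mdl_ids, name, higher,
                             coverage_delta=config.coverage_delta)
        report[f"assignment_{name}"] = {
            "pairs": [{"reference_ligand": r, "model_ligand": m, "score": s}
                      for r, m, s in asg.pairs],
            "unassigned_reference": asg.unassigned_reference,
            "unassigned_model": asg.unassigned_model,
        }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    import numpy as np
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def report_to_tsv(report: dict) -> str:
    """Flat two-column summary of the scalar scores."""
    lines = ["score\tvalue"]
    for key, entry in sorted(report.get("scores", {}).items()):
        value = entry.get("value")
        lines.append(f"{key}\t{'NA' if value is None else round(value, 6)}")
    return "\n".join(lines) + "\n"
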