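"""Reading and writing structures (PDBx/mmCIF, legacy PDB) via gemmi.

``read_structure`` converts a gemmi structure into the benchmarking data
model.  Chains are typed from mmCIF entity annotation when present and from
residue-name heuristics for legacy PDB.  Nonpolymer components can be
collected as ligands, with connectivity from the component dictionary when
known and from the van der Waals heuristic otherwise.

The writers are deliberately minimal fixture emitters (coordinates, chain
ids, residue numbering, entity grouping); they exist so that every test
input can be generated as plain text and round-tripped through the gemmi
readers.
"""

from __future__ import annotations

import logging
from typing import Optional

import gemmi

from . import chemdata
from .ligands import Ligand, heuristic_bonds
from .model import (
    NONPOLYMER, NUCLEOTIDE, PEPTIDE,
    Atom, Chain, ChemCompDictionary, Residue, Structure,
    DEFAULT_DICTIONARY, classify_chain_type, extract_sequence,
)

logger = logging.getLogger(__name__)


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


_WATER_NAMES = {"HOH", "DOD", "WAT"}


def _convert_residue(gres: gemmi.Residue) -> Residue:
    res = Residue(name=gres.name, number=gres.seqid.num,
                  icode=gres.seqid.icode.strip())
    for ga in gres:
        altloc = ga.altloc if ga.altloc not in ("\x00", " ") else ""
        elem = ga.element.name.upper() if ga.element.name else chemdata.element_of_atom_name(ga.name)
        res.atoms.append(Atom(name=ga.name, element=elem,
                              pos=(ga.pos.x, ga.pos.y, ga.pos.z),
                              occupancy=ga.occ, altloc=altloc))
    # altloc resolution: keep highest occupancy per atom name, tie -> first
    # altloc alphabetically
    best: dict[str, Atom] = {}
    for a in res.atoms:
        prev = best.get(a.name)
        if prev is None or a.occupancy > prev.occupancy or (
                a.occupancy == prev.occupancy and a.altloc < prev.altloc):
            best[a.name] = a
    res.atoms = [best[a.name] for a in res.atoms if best[a.name] is a]
    return res


def _ligand_from_residue(chain_id: str, res: Residue,
                         dictionary: ChemCompDictionary) -> Ligand:
    atoms = [a for a in res.atoms if not a.is_hydrogen]
    known = dictionary.bonds(res.name)
    if known is not None:
        index = {a.name: i for i, a in enumerate(atoms)}
        bonds = [(index[p], index[q]) for p, q in known if p in index and q in index]
        source = "ccd"
    else:
        bonds = heuristic_bonds(atoms)
        source = "heuristic"
    return Ligand(name=res.name, atoms=atoms, bonds=bonds, source=source,
                  chain_id=chain_id, residue_number=res.number)


def read_structure(
    path,
    format_hint: Optional[str] = None,
    extract_ligands: bool = False,
    dictionary: Optional[ChemCompDictionary] = None,
) -> Structure:
    """Read a structure from PDBx/mmCIF or legacy PDB.

    Only the first model of multi-model files is used (with a warning).
    With ``extract_ligands``, nonpolymer components (mmCIF nonpolymer
    entities, or HETATM residues outside the polymer sets for PDB) become
    :class:`~structscore.ligands.Ligand` objects; waters are always skipped.
    """
    dictionary = dictionary or DEFAULT_DICTIONARY
    fmt_map = {"mmcif": gemmi.CoorFormat.Mmcif, "cif": gemmi.CoorFormat.Mmcif,
               "pdb": gemmi.CoorFormat.Pdb}
    try:
        if format_hint:
            gst = gemmi.read_structure(str(path), format=fmt_map[format_hint.lower()])
        else:
            gst = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, KeyError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(gst) == 0:
        raise StructureFormatError(f"{path}: no coordinate models found")
    if len(gst) > 1:
        logger.warning("%s: %d models present, using the first", path, len(gst))
    source_format = "pdb" if gst.input_format == gemmi.CoorFormat.Pdb else "mmcif"
    has_entities = len(gst.entities) > 0

    structure = Structure(source_format=source_format, name=gst.name)
    for gchain in gst[0]:
        polymer_residues: list[Residue] = []
        entity_id: Optional[str] = None
        ligand_residues: list[Residue] = []
        for gres in gchain:
            if gres.name in _WATER_NAMES or gres.entity_type == gemmi.EntityType.Water:
                continue
            res = _convert_residue(gres)
            if has_entities and gres.entity_type == gemmi.EntityType.NonPolymer:
                ligand_residues.append(res)
                continue
            if not has_entities and not (res.is_peptide or res.is_nucleotide):
                ligand_residues.append(res)
                continue
            polymer_residues.append(res)
            if entity_id is None and has_entities and gres.entity_id:
                entity_id = gres.entity_id
        if polymer_residues:
            ctype = classify_chain_type(polymer_residues)
            structure.chains.append(Chain(id=gchain.name, residues=polymer_residues,
                                          chain_type=ctype, entity_id=entity_id))
        if extract_ligands:
            for res in ligand_residues:
                structure.ligands.append(_ligand_from_residue(gchain.name, res, dictionary))
    return structure


# ---------------------------------------------------------------------------
# Fixture writers
# ---------------------------------------------------------------------------

def to_pdb_string(structure: Structure) -> str:
    """Legacy PDB encoding of a structure (fixture writer)."""
    lines: list[str] = []
    serial = 1

    def atom_line(record: str, a: Atom, res_name: str, chain_id: str,
                  number: int, icode: str) -> str:
        nonlocal serial
        name = a.name
        # 1-3 character names are padded to start in column 14
        field = f" {name:<3s}" if len(name) < 4 else name
        ln = (f"{record:<6s}{serial:5d} {field:<4s}{'':1s}{res_name:>3s} "
              f"{chain_id:1s}{number:4d}{icode or ' ':1s}   "
              f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
              f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}")
        serial += 1
        return ln

    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                lines.append(atom_line("ATOM", a, res.name, chain.id,
                                       res.number, res.icode))
        last = chain.residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name:>3s} {chain.id:1s}{last.number:4d}")
        serial += 1
    for lig in structure.ligands:
        for a in lig.atoms:
            lines.append(atom_line("HETATM", a, lig.name, lig.chain_id or "X",
                                   lig.residue_number, ""))
    lines.append("END")
    return "\n".join(lines) + "\n"


_POLY_TYPE = {PEPTIDE: "polypeptide(L)", NUCLEOTIDE: "polyribonucleotide"}


def to_mmcif_string(structure: Structure,
                    entity_map: Optional[dict[str, str]] = None) -> str:
    """PDBx/mmCIF encoding of a structure (fixture writer).

    ``entity_map`` assigns chains to entities explicitly (chain id ->
    entity id); by default chains with identical sequences share an entity.
    """
    if entity_map is None:
        entity_map = {}
        seq_entity: dict[tuple[str, str], str] = {}
        for chain in structure.chains:
            key = (chain.chain_type, extract_sequence(chain))
            if key not in seq_entity:
                seq_entity[key] = str(len(seq_entity) + 1)
            entity_map[chain.id] = seq_entity[key]
    n_poly = len(set(entity_map.values()))
    lig_entities: dict[str, str] = {}
    for lig in structure.ligands:
        if lig.name not in lig_entities:
            lig_entities[lig.name] = str(n_poly + len(lig_entities) + 1)

    out = [f"data_{structure.name or 'structscore'}", ""]
    out += ["loop_", "_entity.id", "_entity.type"]
    for eid in sorted(set(entity_map.values()), key=int):
        out.append(f"{eid} polymer")
    for eid in lig_entities.values():
        out.append(f"{eid} non-polymer")
    out.append("")
    poly_chains: dict[str, list[Chain]] = {}
    for chain in structure.chains:
        poly_chains.setdefault(entity_map[chain.id], []).append(chain)
    out += ["loop_", "_entity_poly.entity_id", "_entity_poly.type",
            "_entity_poly.pdbx_strand_id"]
    for eid in sorted(poly_chains, key=int):
        chains = poly_chains[eid]
        ptype = _POLY_TYPE.get(chains[0].chain_type, "other")
        out.append(f"{eid} {ptype} {','.join(c.id for c in chains)}")
    out.append("")
    out += ["loop_", "_atom_site.group_PDB", "_atom_site.id",
            "_atom_site.type_symbol", "_atom_site.label_atom_id",
            "_atom_site.label_alt_id", "_atom_site.label_comp_id",
            "_atom_site.label_asym_id", "_atom_site.label_entity_id",
            "_atom_site.label_seq_id", "_atom_site.pdbx_PDB_ins_code",
            "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
            "_atom_site.occupancy", "_atom_site.B_iso_or_equiv",
            "_atom_site.auth_seq_id", "_atom_site.auth_asym_id",
            "_atom_site.pdbx_PDB_model_num"]
    serial = 1
    asym_counter = 0
    for chain in structure.chains:
        asym_counter += 1
        asym = chain.id
        eid = entity_map[chain.id]
        for seq_pos, res in enumerate(chain.residues, start=1):
            icode = res.icode or "?"
            for a in res.atoms:
                name = f'"{a.name}"' if "'" in a.name else a.name
                out.append(
                    f"ATOM {serial} {a.element} {name} . {res.name} {asym} {eid} "
                    f"{seq_pos} {icode} {a.pos[0]:.3f} {a.pos[1]:.3f} {a.pos[2]:.3f} "
                    f"{a.occupancy:.2f} 0.00 {res.number} {chain.id} 1")
                serial += 1
    for li, lig in enumerate(structure.ligands):
        asym = f"Z{li}"
        eid = lig_entities[lig.name]
        for a in lig.atoms:
            name = f'"{a.name}"' if "'" in a.name else a.name
            out.append(
                f"HETATM {serial} {a.element} {name} . {lig.name} {asym} {eid} "
                f". ? {a.pos[0]:.3f} {a.pos[1]:.3f} {a.pos[2]:.3f} "
                f"1.00 0.00 {lig.residue_number} {lig.chain_id or 'X'} 1")
            serial += 1
    out.append("")
    return "\n".join(out) + "\n"


def write_pdb(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_pdb_string(structure))


def write_mmcif(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_mmcif_string(structure))
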