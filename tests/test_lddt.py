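"""LDDT engine: oracle equivalence, variants, symmetries, stereo checks."""

import copy
import itertools

import numpy as np
import pytest

from structscore.lddt import (LddtParams, build_contact_table, lddt, lddt_score,
                              stereo_filter)
from structscore.model import NUCLEOTIDE, PEPTIDE, Atom, Chain, Residue, Structure
from structscore.synth import FixtureSpec, make_complex
from tests.conftest import identity_alignments, single_atom_chain


def naive_lddt_counts(reference, model, mapping, alignments, params):
    """Independent O(n^2) double-loop LDDT: returns (preserved per
    threshold, total contacts).  No symmetry handling."""
    atoms = []
    for chain in reference.polymer_chains:
        for ri, res in enumerate(chain.residues):
            if params.variant == "backbone":
                rep = res.backbone_rep(chain.chain_type)
                sel = [rep] if rep is not None else []
            else:
                sel = [a for a in res.atoms if not a.is_hydrogen]
            for a in sel:
                atoms.append((chain.id, ri, a.name, np.asarray(a.pos)))
    mdl_chains = {c.id: c for c in model.polymer_chains}
    lut = {cid: dict(aln.pairs) for cid, aln in alignments.items()}

    def model_pos(cid, ri, aname):
        if cid not in mapping or ri not in lut.get(cid, {}):
            return None
        mres = mdl_chains[mapping[cid]].residues[lut[cid][ri]]
        a = mres.atom(aname)
        return None if a is None else np.asarray(a.pos)

    preserved = np.zeros(len(params.thresholds), dtype=int)
    total = 0
    for i in range(len(atoms)):
        ci, ri, ni, pi = atoms[i]
        for j in range(i + 1, len(atoms)):
            cj, rj, nj, pj = atoms[j]
            if (ci, ri) == (cj, rj):
                continue
            if params.variant == "interface_only" and ci == cj:
                continue
            d_ref = np.linalg.norm(pi - pj)
            if d_ref > params.inclusion_radius:
                continue
            total += 1
            mi, mj = model_pos(ci, ri, ni), model_pos(cj, rj, nj)
            if mi is None or mj is None:
                continue
            delta = abs(np.linalg.norm(mi - mj) - d_ref)
            for k, t in enumerate(params.thresholds):
                if delta <= t:
                    preserved[k] += 1
    return preserved, total


@pytest.mark.parametrize("radius", [15.0, 30.0])
@pytest.mark.parametrize("variant", ["full", "backbone", "interface_only"])
def test_engine_matches_naive_oracle(radius, variant):
    """Optimized engine reproduces the double-loop counts bit-exactly."""
    rng = np.random.default_rng(7)
    for trial in range(6):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry=["A2", "A3", "A1B1"][trial % 3], chain_length=8,
            seed=100 + trial, noise_sigma=float(rng.uniform(0.1, 1.5))))
        alns = identity_alignments(ref, mdl, truth.mapping)
        params = LddtParams(inclusion_radius=radius, variant=variant, symmetry=False)
        table = build_contact_table(ref, params)
        res = lddt(mdl, table, truth.mapping, alns, params)
        preserved, total = naive_lddt_counts(ref, mdl, truth.mapping, alns, params)
        assert table.n_contacts == total
        if total == 0:
            assert res.score is None
        else:
            expected = [p / total for p in preserved]
            assert res.per_threshold == pytest.approx(expected, abs=0)


class TestBasicBehavior:
    def test_self_comparison_is_one(self, dimer_pair):
        ref, mdl, truth = dimer_pair
        alns = identity_alignments(ref, mdl, truth.mapping)
        res = lddt_score(ref, mdl, truth.mapping, alns)
        assert res.score == 1.0
        assert all(v == 1.0 for v in res.per_residue.values())

    def test_uniform_07_distance_shift_scores_075(self):
        """Every contact off by exactly 0.7 Å: thresholds (0.5,1,2,4) give
        fractions (0,1,1,1) and LDDT 0.75."""
        spacing = 14.0
        ref = Structure(chains=[single_atom_chain(
            "A", [(i * spacing, 0, 0) for i in range(8)])])
        mdl = Structure(chains=[single_atom_chain(
            "A", [(i * (spacing + 0.7), 0, 0) for i in range(8)])])
        alns = identity_alignments(ref, mdl, {"A": "A"})
        res = lddt_score(ref, mdl, {"A": "A"}, alns)
        assert res.per_threshold == [0.0, 1.0, 1.0, 1.0]
        assert res.score == 0.75

    def test_contact_radius_is_sharp(self):
        ref = Structure(chains=[
            single_atom_chain("A", [(0, 0, 0)] ),
            single_atom_chain("B", [(14.9, 0, 0)]),
            single_atom_chain("C", [(-15.1, 0, 0)])])
        table = build_contact_table(ref, LddtParams(inclusion_radius=15.0))
        pairs = {(table.atom_keys[i][0], table.atom_keys[j][0])
                 for i, j in table.pairs}
        assert ("A", "B") in pairs
        assert ("C", "A") not in pairs and ("A", "C") not in pairs

    def test_single_residue_structure_has_no_contacts(self):
        ref = Structure(chains=[single_atom_chain("A", [(0, 0, 0)])])
        table = build_contact_table(ref, LddtParams())
        assert table.n_contacts == 0

    def test_monomer_interface_lddt_not_computable(self):
        ref, mdl, truth = make_complex(FixtureSpec(stoichiometry="A1", seed=2))
        alns = identity_alignments(ref, mdl, truth.mapping)
        res = lddt_score(ref, mdl, truth.mapping, alns,
                         LddtParams(variant="interface_only"))
        assert res.score is None and res.reason

    def test_backbone_equals_full_on_backbone_only_structure(self):
        ref = Structure(chains=[
            single_atom_chain("A", [(i * 3.8, 0, 0) for i in range(8)]),
            single_atom_chain("B", [(i * 3.8, 7, 0) for i in range(8)])])
        mdl = copy.deepcopy(ref)
        rng = np.random.default_rng(3)
        for c in mdl.chains:
            for r in c.residues:
                r.atoms[0].pos = r.atoms[0].pos + rng.normal(0, 0.5, 3)
        alns = identity_alignments(ref, mdl, {"A": "A", "B": "B"})
        full = lddt_score(ref, mdl, {"A": "A", "B": "B"}, alns,
                          LddtParams(variant="full"))
        bb = lddt_score(ref, mdl, {"A": "A", "B": "B"}, alns,
                        LddtParams(variant="backbone"))
        assert bb.score == pytest.approx(full.score)

    def test_score_degrades_with_noise_amplitude(self):
        scores = []
        for sigma in (0.2, 1.0, 3.0):
            ref, mdl, truth = make_complex(
                FixtureSpec(stoichiometry="A2", seed=55, noise_sigma=sigma))
            alns = identity_alignments(ref, mdl, truth.mapping)
            scores.append(lddt_score(ref, mdl, truth.mapping, alns).score)
        assert scores[0] > scores[1] > scores[2]

    def test_missing_model_atoms_count_unpreserved(self):
        ref = Structure(chains=[single_atom_chain(
            "A", [(i * 10.0, 0, 0) for i in range(6)])])
        mdl = copy.deepcopy(ref)
        mdl.chains[0].residues = mdl.chains[0].residues[:3]
        alns = identity_alignments(ref, mdl, {"A": "A"})
        res = lddt_score(ref, mdl, {"A": "A"}, alns)
        assert 0 < res.score < 1


class TestSymmetry:
    def _nuc_pair(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", chain_type=NUCLEOTIDE, chain_length=6, seed=1))
        return ref, mdl, truth

    def test_op1_op2_swap_scores_one(self):
        ref, mdl, truth = self._nuc_pair()
        res3 = mdl.chain("A").residues[2]
        a, b = res3.atom("OP1"), res3.atom("OP2")
        a.name, b.name = "OP2", "OP1"
        alns = identity_alignments(ref, mdl, truth.mapping)
        res = lddt_score(ref, mdl, truth.mapping, alns)
        assert res.score == 1.0

    def test_swap_penalized_without_symmetry_handling(self):
        ref, mdl, truth = self._nuc_pair()
        res3 = mdl.chain("A").residues[2]
        a, b = res3.atom("OP1"), res3.atom("OP2")
        a.name, b.name = "OP2", "OP1"
        alns = identity_alignments(ref, mdl, truth.mapping)
        res = lddt_score(ref, mdl, truth.mapping, alns,
                         LddtParams(inclusion_radius=30.0, symmetry=False))
        assert res.score < 1.0

    def test_glutamate_oe_swap_scores_one(self):
        def glu_chain(cid, swap=False):
            chain = Chain(id=cid, chain_type=PEPTIDE)
            for i in range(6):
                res = Residue(name="GLU", number=i + 1)
                base = np.array([i * 6.0, 0.0, 0.0])
                names = ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"]
                offs = [(0, 1.4, 0), (0, 0, 0), (1.2, 0, 0.6), (1.2, 1.2, 0.8),
                        (0.3, -1.4, 0.3), (0.6, -2.7, 0.3), (1.0, -3.9, 0.5),
                        (0.6, -4.9, 1.0), (2.2, -4.1, 0.2)]
                if swap:
                    names[-2], names[-1] = names[-1], names[-2]
                for n, o in zip(names, offs):
                    el = "O" if n.startswith("O") else ("N" if n == "N" else "C")
                    res.atoms.append(Atom(name=n, element=el, pos=base + np.array(o)))
                chain.residues.append(res)
            return chain
        ref = Structure(chains=[glu_chain("A")])
        mdl = Structure(chains=[glu_chain("A", swap=True)])
        alns = identity_alignments(ref, mdl, {"A": "A"})
        assert lddt_score(ref, mdl, {"A": "A"}, alns).score == 1.0


def _ideal_peptide_chain(cid="A", n=6):
    """Backbone geometry built from the stereo table's ideal values."""
    chain = Chain(id=cid, chain_type=PEPTIDE)
    x = 0.0
    for i in range(n):
        res = Residue(name="ALA", number=i + 1)
        res.atoms.append(Atom("N", "N", (x, 0.0, 0.0)))
        # ideal values from the stereo table: N-CA 1.458, CA-C 1.525,
        # C-O 1.231, CA-CB 1.530; angles N-CA-C 111.0, CA-C-O 120.1,
        # N-CA-CB 110.5, C-CA-CB 110.1 (CB solved off-plane)
        ca = np.array([x + 1.458, 0.0, 0.0])
        res.atoms.append(Atom("CA", "C", ca))
        ang = np.deg2rad(180.0 - 111.0)
        c = ca + 1.525 * np.array([np.cos(ang), np.sin(ang), 0.0])
        res.atoms.append(Atom("C", "C", c))
        o_dir = np.array([np.cos(np.deg2rad(9.1)), np.sin(np.deg2rad(9.1)), 0.0])
        res.atoms.append(Atom("O", "O", c + 1.231 * o_dir))
        cb = ca + 1.530 * np.array([0.3500, -0.5028, -0.7904])
        res.atoms.append(Atom("CB", "C", cb))
        x += 6.0  # consecutive residues far apart: no link bond, no clashes
        chain.residues.append(res)
    return chain


class TestStereoFilter:
    def test_ideal_geometry_passes(self):
        s = Structure(chains=[_ideal_peptide_chain()])
        filtered, violations = stereo_filter(s)
        assert violations == []
        assert sum(len(r.atoms) for r in filtered.chains[0].residues) == \
            sum(len(r.atoms) for r in s.chains[0].residues)

    def test_stretched_cb_bond_drops_side_chain(self):
        s = Structure(chains=[_ideal_peptide_chain()])
        res = s.chains[0].residues[2]
        cb = res.atom("CB")
        ca = res.atom("CA")
        # stretch CA-CB by 20 standard deviations (0.02 Å each)
        direction = (cb.pos - ca.pos) / np.linalg.norm(cb.pos - ca.pos)
        cb.pos = cb.pos + direction * (20 * 0.020)
        filtered, violations = stereo_filter(s)
        assert any(v.kind == "bond" and "CB" in v.detail for v in violations)
        assert filtered.chains[0].residues[2].atom("CB") is None
        assert filtered.chains[0].residues[2].atom("CA") is not None

    def test_distorted_sugar_bond_flagged(self):
        ref, _, _ = make_complex(FixtureSpec(
            stoichiometry="A1", chain_type=NUCLEOTIDE, chain_length=4, seed=3))
        res = ref.chains[0].residues[1]
        c3 = res.atom("C3'")
        c2 = res.atom("C2'")
        c2.pos = c3.pos + (c2.pos - c3.pos) * 2.0  # gross bond stretch
        _, violations = stereo_filter(ref)
        assert any(v.kind == "bond" and "C2'" in v.detail for v in violations)

    def test_filtered_atoms_penalize_lddt(self):
        ref = Structure(chains=[_ideal_peptide_chain()])
        mdl = ref.copy()
        res = mdl.chains[0].residues[2]
        cb = res.atom("CB")
        ca = res.atom("CA")
        direction = (cb.pos - ca.pos) / np.linalg.norm(cb.pos - ca.pos)
        # keep CB at the same distance to everything else is impossible; move
        # it along the bond so only the bond length is badly wrong
        cb.pos = cb.pos + direction * 0.5
        alns = identity_alignments(ref, mdl, {"A": "A"})
        with_checks = lddt_score(ref, mdl, {"A": "A"}, alns,
                                 LddtParams(stereo_checks=True))
        without = lddt_score(ref, mdl, {"A": "A"}, alns,
                             LddtParams(stereo_checks=False))
        assert with_checks.score < without.score
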