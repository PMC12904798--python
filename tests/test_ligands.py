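"""Ligand matching, binding sites, BiSyRMSD/LDDT-PLI/LDDT-LP, assignment."""

import copy
import itertools

import numpy as np
import pytest

from structscore.ligand_scores import (assign_ligands, bisy_rmsd,
                                       detect_binding_site, lddt_pli)
from structscore.ligands import (Ligand, SymmetryCapExceeded, match_ligands)
from structscore.model import Atom, Structure
from structscore.synth import (FixtureSpec, _rotation, make_complex, make_ligand,
                               place_ligand_near_chain)


def _shifted(lig, vec):
    out = copy.deepcopy(lig)
    for a in out.atoms:
        a.pos = a.pos + np.asarray(vec, dtype=float)
    return out


def _permuted(lig, perm):
    out = copy.deepcopy(lig)
    out.atoms = [copy.deepcopy(lig.atoms[i]) for i in perm]
    inv = {old: new for new, old in enumerate(perm)}
    out.bonds = [(inv[i], inv[j]) for i, j in lig.bonds]
    return out


def brute_force_automorphisms(lig):
    """Count element- and bond-preserving atom permutations by enumeration."""
    n = len(lig.atoms)
    bonds = {frozenset(b) for b in lig.bonds}
    count = 0
    for perm in itertools.permutations(range(n)):
        if any(lig.atoms[i].element != lig.atoms[perm[i]].element for i in range(n)):
            continue
        if {frozenset((perm[i], perm[j])) for i, j in bonds} == bonds:
            count += 1
    return count


class TestMatching:
    def test_benzene_has_twelve_automorphisms(self):
        ring = make_ligand("ring")
        match = match_ligands(ring, copy.deepcopy(ring))
        assert len(match.correspondences) == 12
        assert len(match.correspondences) == brute_force_automorphisms(ring)

    def test_linear_ligand_single_correspondence(self):
        lin = make_ligand("linear")
        match = match_ligands(lin, copy.deepcopy(lin))
        assert len(match.correspondences) == 1

    def test_different_molecules_do_not_match(self):
        # ethanol-like vs methanol-like heavy-atom graphs
        ethanol = Ligand("ETH", [Atom("C1", "C", (0, 0, 0)),
                                 Atom("C2", "C", (1.5, 0, 0)),
                                 Atom("O1", "O", (2.2, 1.2, 0))],
                         [(0, 1), (1, 2)])
        methanol = Ligand("MEO", [Atom("C1", "C", (0, 0, 0)),
                                  Atom("O1", "O", (1.4, 0, 0))], [(0, 1)])
        assert match_ligands(ethanol, methanol) is None

    def test_subgraph_match_reports_coverage(self):
        ring = make_ligand("ring")
        partial = copy.deepcopy(ring)
        partial.atoms = partial.atoms[:4]
        partial.bonds = [(i, j) for i, j in partial.bonds if i < 4 and j < 4]
        assert match_ligands(partial, ring) is None
        match = match_ligands(partial, ring, allow_subgraph=True)
        assert match is not None
        assert match.coverage == pytest.approx(4 / 6)
        assert match.subgraph_mode

    def test_model_smaller_than_reference_never_matches(self):
        ring = make_ligand("ring")
        partial = copy.deepcopy(ring)
        partial.atoms = partial.atoms[:4]
        partial.bonds = [(i, j) for i, j in partial.bonds if i < 4 and j < 4]
        assert match_ligands(ring, partial, allow_subgraph=True) is None

    def test_symmetry_cap(self):
        ring = make_ligand("ring")
        with pytest.raises(SymmetryCapExceeded):
            match_ligands(ring, copy.deepcopy(ring), max_symmetries=5)

    def test_correspondences_preserve_elements_and_bonds(self):
        frag = make_ligand("fragments")
        match = match_ligands(frag, copy.deepcopy(frag))
        bonds = {frozenset(b) for b in frag.bonds}
        for corr in match.correspondences:
            for r, m in corr.items():
                assert frag.atoms[r].element == frag.atoms[m].element
            assert {frozenset((corr[i], corr[j])) for i, j in frag.bonds} == bonds


class TestBindingSite:
    def test_radius_is_sharp(self):
        from tests.conftest import single_atom_chain
        ref = Structure(chains=[
            single_atom_chain("A", [(0, 0, 0)] + [(i * 3.8 + 10, 40, 0) for i in range(6)])])
        lig = make_ligand("ion")
        lig.atoms[0].pos = np.array([3.9, 0.0, 0.0])
        assert len(detect_binding_site(ref, lig, 4.0)) == 1
        lig.atoms[0].pos = np.array([4.1, 0.0, 0.0])
        assert len(detect_binding_site(ref, lig, 4.0)) == 0

    def test_isolated_ion_unscoreable_until_radius_raised(self, ring_ligand_complex):
        ref, mdl, _, _ = ring_ligand_complex
        ion = make_ligand("ion")
        # park the ion 8 Å away from everything
        coords = np.array([a.pos for c in ref.chains for r in c.residues for a in r.atoms])
        far = coords.mean(axis=0)
        far = far + 8.0 * (far - coords[np.argmin(np.linalg.norm(coords - far, axis=1))]) \
            / max(np.linalg.norm(far - coords[0]), 1)
        ion.atoms[0].pos = coords[0] + np.array([0.0, -8.0, 0.0])
        site4 = detect_binding_site(ref, ion, 4.0)
        site12 = detect_binding_site(ref, ion, 12.0)
        assert len(site4) == 0 and len(site12) > 0
        mion = copy.deepcopy(ion)
        res = bisy_rmsd(ref, mdl, ion, mion, match_ligands(ion, mion))
        assert res.bisy_rmsd is None and "empty binding site" in res.reasons["bisy_rmsd"]


class TestBisyRmsd:
    def test_self_comparison(self, ring_ligand_complex):
        ref, mdl, rlig, mlig = ring_ligand_complex
        match = match_ligands(rlig, mlig)
        res = bisy_rmsd(ref, mdl, rlig, mlig, match)
        assert res.bisy_rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.rmsd_lp == pytest.approx(0.0, abs=1e-9)
        assert res.lddt_lp == pytest.approx(1.0)

    def test_flipped_ring_recovered_by_symmetry(self, ring_ligand_complex):
        ref, mdl, rlig, mlig = ring_ligand_complex
        center = np.mean(rlig.coords(), axis=0)
        rot = _rotation(np.array([1.0, 0.0, 0.0]), np.pi)
        for a in mlig.atoms:
            a.pos = np.round(rot @ (a.pos - center) + center, 3)
        naive = np.sqrt(np.mean(np.sum((rlig.coords() - mlig.coords()) ** 2, axis=1)))
        assert naive > 0.5
        match = match_ligands(rlig, mlig)
        res = bisy_rmsd(ref, mdl, rlig, mlig, match)
        assert res.bisy_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_over_mappings_and_symmetries(self):
        """Exhaustive oracle: all chain permutations x atom correspondences."""
        from structscore.superpose import apply_transform, kabsch, rmsd as rmsd_of
        from structscore.grouping import align_chains
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", seed=77, noise_sigma=0.4))
        rlig = place_ligand_near_chain(make_ligand("ring"), ref.chains[0], 3.5)
        mlig = _shifted(rlig, (0.8, 0.3, -0.2))
        match = match_ligands(rlig, mlig)
        res = bisy_rmsd(ref, mdl, rlig, mlig, match)
        # oracle
        site = detect_binding_site(ref, rlig, 4.0)
        best = np.inf
        for perm in itertools.permutations([c.id for c in mdl.chains]):
            mapping = dict(zip([c.id for c in ref.chains], perm))
            ref_pts, mdl_pts = [], []
            for cid, ri in site.residues:
                aln = dict(align_chains(ref.chain(cid), mdl.chain(mapping[cid])).pairs)
                if ri not in aln:
                    continue
                a = ref.chain(cid).residues[ri].atom("CA")
                b = mdl.chain(mapping[cid]).residues[aln[ri]].atom("CA")
                if a is not None and b is not None:
                    ref_pts.append(a.pos)
                    mdl_pts.append(b.pos)
            if len(ref_pts) < 3:
                continue
            rot, t = kabsch(np.asarray(mdl_pts), np.asarray(ref_pts))
            moved = apply_transform(mlig.coords(), rot, t)
            for corr in match.correspondences:
                ridx = sorted(corr)
                midx = [corr[i] for i in ridx]
                best = min(best, rmsd_of(rlig.coords()[ridx], moved[midx]))
        assert res.bisy_rmsd == pytest.approx(best, abs=1e-12)

    def test_invariant_under_atom_order_permutation(self, ring_ligand_complex):
        ref, mdl, rlig, mlig = ring_ligand_complex
        rng = np.random.default_rng(1)
        base = None
        for _ in range(6):
            perm = rng.permutation(len(mlig.atoms))
            permuted = _permuted(mlig, list(perm))
            match = match_ligands(rlig, permuted)
            res = bisy_rmsd(ref, mdl, rlig, permuted, match)
            pli, _ = lddt_pli(ref, mdl, rlig, permuted, match)
            if base is None:
                base = (res.bisy_rmsd, pli)
            assert res.bisy_rmsd == pytest.approx(base[0], abs=1e-9)
            assert pli == pytest.approx(base[1], abs=1e-9)

    def test_single_residue_site_lddt_lp_is_zero(self):
        from structscore.model import Chain, PEPTIDE, Residue
        chain = Chain(id="A", chain_type=PEPTIDE)
        first = Residue(name="GLY", number=1)
        for name, pos in [("N", (-1.4, 0, 0)), ("CA", (0, 0, 0)),
                          ("C", (1.0, 1.1, 0)), ("O", (1.0, 2.3, 0))]:
            first.atoms.append(Atom(name, name[0], pos))
        chain.residues.append(first)
        for i in range(7):
            res = Residue(name="GLY", number=i + 2)
            res.atoms.append(Atom("CA", "C", (40 + i * 3.8, 40, 0)))
            chain.residues.append(res)
        ref = Structure(chains=[chain])
        mdl = copy.deepcopy(ref)
        lig = make_ligand("ion")
        lig.atoms[0].pos = np.array([3.0, 0.0, 0.0])
        mlig = copy.deepcopy(lig)
        res = bisy_rmsd(ref, mdl, lig, mlig, match_ligands(lig, mlig))
        assert len(res.site) == 1
        assert res.lddt_lp == 0.0

    def test_disconnected_fragment_far_away(self):
        """A fragment misplaced by 100 Å blows up BiSyRMSD while LDDT-PLI
        stays above zero for the correctly placed part."""
        ref, mdl, truth = make_complex(FixtureSpec(stoichiometry="A2", seed=21))
        rlig = place_ligand_near_chain(make_ligand("fragments"), ref.chains[0], 3.5)
        mlig = copy.deepcopy(rlig)
        for a in mlig.atoms[6:]:
            a.pos = a.pos + np.array([100.0, 0.0, 0.0])
        match = match_ligands(rlig, mlig)
        res = bisy_rmsd(ref, mdl, rlig, mlig, match)
        pli, _ = lddt_pli(ref, mdl, rlig, mlig, match)
        assert res.bisy_rmsd > 30.0
        assert pli is not None and pli > 0.0


class TestLddtPli:
    def test_self_comparison(self, ring_ligand_complex):
        ref, mdl, rlig, mlig = ring_ligand_complex
        pli, reason = lddt_pli(ref, mdl, rlig, mlig, match_ligands(rlig, mlig))
        assert pli == 1.0 and reason is None

    def test_extra_chain_through_site_penalized(self, ring_ligand_complex):
        """A model chain threaded through the binding pocket adds only-model
        contacts (its reference counterpart sits elsewhere), which the score
        counts as unpreserved."""
        ref, mdl, rlig, mlig = ring_ligand_complex
        center = np.mean(rlig.coords(), axis=0)
        dirty = mdl.copy()
        intruder = dirty.chain("B")
        for i, res in enumerate(intruder.residues):
            shift = center + np.array([0.0, 0.0, -4.0 + i * 1.3]) - res.atoms[0].pos
            for a in res.atoms:
                a.pos = a.pos + shift
        pli_clean, _ = lddt_pli(ref, mdl, rlig, mlig, match_ligands(rlig, mlig))
        pli_dirty, _ = lddt_pli(ref, dirty, rlig, mlig, match_ligands(rlig, mlig))
        assert pli_dirty < pli_clean

    def test_translation_ladder_monotone(self, ring_ligand_complex):
        ref, mdl, rlig, _ = ring_ligand_complex
        plis, bisys = [], []
        for shift in (0.0, 2.0, 4.0, 6.0, 8.0, 10.0):
            mlig = _shifted(rlig, (0, 0, shift))
            match = match_ligands(rlig, mlig)
            res = bisy_rmsd(ref, mdl, rlig, mlig, match)
            pli, _ = lddt_pli(ref, mdl, rlig, mlig, match)
            bisys.append(res.bisy_rmsd)
            plis.append(pli)
        assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(bisys, bisys[1:]))
        assert all(p2 <= p1 + 1e-9 for p1, p2 in zip(plis, plis[1:]))

    def test_no_contacts_not_computable(self):
        from tests.conftest import single_atom_chain
        ref = Structure(chains=[single_atom_chain(
            "A", [(i * 3.8, 0, 0) for i in range(6)])])
        mdl = copy.deepcopy(ref)
        lig = make_ligand("ion")
        lig.atoms[0].pos = np.array([0.0, 200.0, 0.0])
        mlig = copy.deepcopy(lig)
        pli, reason = lddt_pli(ref, mdl, lig, mlig, match_ligands(lig, mlig))
        assert pli is None and reason


class TestAssignment:
    def test_single_pair(self):
        asg = assign_ligands([("R", "M", 1.0, 0.4)], ["R"], ["M"],
                             "bisy_rmsd", higher_is_better=False)
        assert asg.pairs == [("R", "M", 0.4)]
        assert not asg.unassigned_reference and not asg.unassigned_model

    def test_one_to_one_with_duplicate_models(self):
        cands = [("R", "M1", 1.0, 0.2), ("R", "M2", 1.0, 1.5)]
        asg = assign_ligands(cands, ["R"], ["M1", "M2"],
                             "bisy_rmsd", higher_is_better=False)
        assert asg.pairs == [("R", "M1", 0.2)]
        assert asg.unassigned_model == ["M2"]

    def test_coverage_window_excludes_solvent(self):
        # solvent-like match (coverage 0.2) scores better but is outside the
        # coverage window of the full-coverage cofactor match
        cands = [("COF", "M", 1.0, 2.0), ("SOL", "M", 0.2, 0.5)]
        asg = assign_ligands(cands, ["COF", "SOL"], ["M"],
                             "bisy_rmsd", higher_is_better=False)
        assert asg.pairs[0][0] == "COF"
        assert asg.unassigned_reference == ["SOL"]

    def test_greedy_consistency_after_removing_first_pair(self):
        cands = [("R1", "M1", 1.0, 0.1), ("R1", "M2", 1.0, 0.3),
                 ("R2", "M1", 1.0, 0.2), ("R2", "M2", 1.0, 0.6)]
        full = assign_ligands(cands, ["R1", "R2"], ["M1", "M2"],
                              "bisy_rmsd", higher_is_better=False)
        first = full.pairs[0]
        rest = [c for c in cands if c[0] != first[0] and c[1] != first[1]]
        again = assign_ligands(rest, ["R2"], ["M2"],
                               "bisy_rmsd", higher_is_better=False)
        assert full.pairs[1:] == again.pairs

    def test_separate_assignments_can_differ(self):
        bisy = assign_ligands([("R", "M1", 1.0, 0.5), ("R", "M2", 1.0, 0.8)],
                              ["R"], ["M1", "M2"], "bisy_rmsd", False)
        pli = assign_ligands([("R", "M1", 1.0, 0.6), ("R", "M2", 1.0, 0.9)],
                             ["R"], ["M1", "M2"], "lddt_pli", True)
        assert bisy.pairs[0][1] == "M1"
        assert pli.pairs[0][1] == "M2"
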