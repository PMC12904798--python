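"""QS-score, ICS/IPS, DockQ family, GDT and backbone RMSD."""

import copy

import numpy as np
import pytest

from structscore.dockq import DockQComponents, dockq, dockq_aggregate
from structscore.gdt import backbone_rmsd, gdt
from structscore.interfaces import ics_ips, residue_contacts
from structscore.model import Structure
from structscore.qs import qs_score
from structscore.superpose import kabsch, apply_transform, superposed_rmsd
from structscore.synth import FixtureSpec, make_complex, random_rotation
from tests.conftest import identity_alignments, single_atom_chain


def _pair_with_alignments(spec):
    ref, mdl, truth = make_complex(spec)
    return ref, mdl, truth.mapping, identity_alignments(ref, mdl, truth.mapping)


class TestQsScore:
    def test_self_comparison(self):
        ref, mdl, mapping, alns = _pair_with_alignments(
            FixtureSpec(stoichiometry="A2B2", seed=11))
        res = qs_score(ref, mdl, mapping, alns)
        assert res.qs_global == pytest.approx(1.0)
        assert res.qs_best == pytest.approx(1.0)

    def test_symmetric_under_swap(self):
        ref, mdl, mapping, _ = _pair_with_alignments(
            FixtureSpec(stoichiometry="A3", seed=13, noise_sigma=0.8))
        alns = identity_alignments(ref, mdl, mapping)
        fwd = qs_score(ref, mdl, mapping, alns)
        inverse = {m: r for r, m in mapping.items()}
        alns_rev = identity_alignments(mdl, ref, inverse)
        rev = qs_score(mdl, ref, inverse, alns_rev)
        assert fwd.qs_global == pytest.approx(rev.qs_global, abs=1e-9)

    def test_duplicated_dimer_penalizes_global_not_best(self):
        ref4, mdl4, _ = make_complex(FixtureSpec(stoichiometry="A4", seed=9))
        ref = ref4.copy()
        ref.chains = [c for c in ref.chains if c.id in ("A", "B")]
        mapping = {"A": "A", "B": "B"}
        alns = identity_alignments(ref, mdl4, mapping)
        res = qs_score(ref, mdl4, mapping, alns)
        assert res.qs_best == pytest.approx(1.0)
        assert res.qs_global < res.qs_best

    def test_best_at_least_global_on_incomplete_references(self):
        for seed in range(5):
            ref, mdl, truth = make_complex(FixtureSpec(
                stoichiometry="A3", seed=seed, noise_sigma=0.5,
                drop_reference_chains=("C",)))
            alns = identity_alignments(ref, mdl, truth.mapping)
            res = qs_score(ref, mdl, truth.mapping, alns)
            assert res.qs_best >= res.qs_global

    def test_no_interfaces_not_computable(self):
        far = Structure(chains=[
            single_atom_chain("A", [(i * 3.8, 0, 0) for i in range(6)]),
            single_atom_chain("B", [(i * 3.8, 500, 0) for i in range(6)])])
        alns = identity_alignments(far, far, {"A": "A", "B": "B"})
        res = qs_score(far, far, {"A": "A", "B": "B"}, alns)
        assert res.qs_global is None and res.reason


class TestIcsIps:
    def test_identical_dimers_score_one(self):
        ref, mdl, mapping, alns = _pair_with_alignments(
            FixtureSpec(stoichiometry="A2", seed=11))
        res = ics_ips(ref, mdl, mapping, alns)
        assert res.ics == pytest.approx(1.0)
        assert res.ips == pytest.approx(1.0)

    def test_half_recall_gives_two_thirds(self):
        # two chains of single-atom residues with 6 reference contacts at
        # 4.5 Å; the model breaks half of them and adds none, so precision
        # is 1 and recall 0.5, giving ICS = F1 = 2/3
        ref = Structure(chains=[
            single_atom_chain("A", [(i * 20.0, 0, 0) for i in range(6)]),
            single_atom_chain("B", [(i * 20.0, 4.5, 0) for i in range(6)])])
        mdl = copy.deepcopy(ref)
        for i in (0, 1, 2):
            mdl.chains[1].residues[i].atoms[0].pos = \
                mdl.chains[1].residues[i].atoms[0].pos + np.array([0, 10.0, 0])
        assert len(residue_contacts(ref)) == 6
        mapping = {"A": "A", "B": "B"}
        alns = identity_alignments(ref, mdl, mapping)
        res = ics_ips(ref, mdl, mapping, alns)
        assert res.precision == pytest.approx(1.0)
        assert res.recall == pytest.approx(0.5)
        assert res.ics == pytest.approx(2 / 3)

    def test_trimmed_at_least_untrimmed_with_extra_model_region(self):
        for seed in (1, 2, 3):
            ref, mdl, truth = make_complex(FixtureSpec(
                stoichiometry="A2", seed=seed, noise_sigma=0.3))
            # graft an extra region onto the model near the interface
            extra = single_atom_chain("Z", [(i * 3.0, 2.0, 3.0) for i in range(8)])
            mdl.chains[0].residues.extend(extra.residues)
            for i, r in enumerate(mdl.chains[0].residues):
                r.number = i + 1
            alns = identity_alignments(ref, mdl, truth.mapping)
            plain = ics_ips(ref, mdl, truth.mapping, alns, trimmed=False)
            trimmed = ics_ips(ref, mdl, truth.mapping, alns, trimmed=True)
            assert trimmed.ics >= plain.ics

    def test_precision_recall_swap_under_exchange(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", seed=31, noise_sigma=1.0))
        alns = identity_alignments(ref, mdl, truth.mapping)
        fwd = ics_ips(ref, mdl, truth.mapping, alns)
        inverse = {m: r for r, m in truth.mapping.items()}
        rev = ics_ips(mdl, ref, inverse, identity_alignments(mdl, ref, inverse))
        assert fwd.precision == pytest.approx(rev.recall)
        assert fwd.recall == pytest.approx(rev.precision)
        assert fwd.ics == pytest.approx(rev.ics)


class TestDockQ:
    def test_self_comparison_perfect(self):
        ref, mdl, mapping, alns = _pair_with_alignments(
            FixtureSpec(stoichiometry="A2", seed=7))
        comp = dockq(ref, mdl, mapping, alns, ("A", "B"))
        assert comp.fnat == 1.0
        assert comp.i_rmsd == pytest.approx(0.0, abs=1e-9)
        assert comp.l_rmsd == pytest.approx(0.0, abs=1e-9)
        assert comp.dockq == pytest.approx(1.0)

    def test_displaced_ligand_chain_hits_rmsd_floor(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", seed=7, displace_chain="B",
            displace_distance=80.0))
        alns = identity_alignments(ref, mdl, truth.mapping)
        comp = dockq(ref, mdl, truth.mapping, alns, ("A", "B"))
        assert comp.fnat == 0.0
        expected = (0.0 + 1 / (1 + (comp.i_rmsd / 1.5) ** 2)
                    + 1 / (1 + (comp.l_rmsd / 8.5) ** 2)) / 3
        assert comp.dockq == pytest.approx(expected)
        assert comp.dockq < 0.1

    def test_dockq_consistent_with_components(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", seed=19, noise_sigma=1.0))
        alns = identity_alignments(ref, mdl, truth.mapping)
        comp = dockq(ref, mdl, truth.mapping, alns, ("A", "B"))
        recomputed = (comp.fnat + 1 / (1 + (comp.i_rmsd / 1.5) ** 2)
                      + 1 / (1 + (comp.l_rmsd / 8.5) ** 2)) / 3
        assert comp.dockq == pytest.approx(recomputed)

    def test_capri_peptide_changes_parameters(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", seed=23, noise_sigma=0.8))
        alns = identity_alignments(ref, mdl, truth.mapping)
        default = dockq(ref, mdl, truth.mapping, alns, ("A", "B"))
        peptide = dockq(ref, mdl, truth.mapping, alns, ("A", "B"),
                        capri_peptide=True)
        assert default.n_native_contacts >= peptide.n_native_contacts

    def test_aggregate_weighted_mean(self):
        one = DockQComponents(1, 0, 0.0, 0.0, 1.0, 90, 90)
        zero = DockQComponents(0, 1, 50.0, 50.0, 0.0, 10, 10)
        agg = dockq_aggregate([one, zero])
        assert agg["dockq_ave"] == pytest.approx(0.5)
        assert agg["dockq_wave"] == pytest.approx(0.9)

    def test_aggregate_single_and_equal(self):
        comp = DockQComponents(0.5, 0.2, 1.0, 2.0, 0.61, 30, 30)
        agg = dockq_aggregate([comp])
        assert agg["dockq_ave"] == agg["dockq_wave"] == comp.dockq
        agg2 = dockq_aggregate([comp, DockQComponents(0.5, 0.2, 1.0, 2.0, 0.61, 5, 5)])
        assert agg2["dockq_ave"] == pytest.approx(agg2["dockq_wave"])

    def test_empty_aggregate_not_computable(self):
        agg = dockq_aggregate([])
        assert agg["dockq_ave"] is None and agg["dockq_wave"] is None


class TestGdt:
    def test_self_comparison(self):
        ref, mdl, mapping, alns = _pair_with_alignments(
            FixtureSpec(stoichiometry="A2", seed=3))
        res = gdt(ref, mdl, mapping, alns)
        assert res.gdt_ts == pytest.approx(1.0)
        assert res.gdt_ha == pytest.approx(1.0)

    def test_half_displaced_gives_half(self):
        n = 24
        ref = Structure(chains=[single_atom_chain(
            "A", [(i * 3.8, 0, 0) for i in range(n)])])
        mdl = copy.deepcopy(ref)
        rng = np.random.default_rng(5)
        for res in mdl.chains[0].residues[n // 2:]:
            res.atoms[0].pos = res.atoms[0].pos + np.array([100.0, 0, 0]) \
                + rng.normal(0, 5.0, 3)
        alns = identity_alignments(ref, mdl, {"A": "A"})
        res = gdt(ref, mdl, {"A": "A"}, alns)
        assert all(f == pytest.approx(0.5) for f in res.fractions.values())
        assert res.gdt_ts == pytest.approx(0.5)

    def test_fractions_monotone_in_threshold(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A2", seed=29, noise_sigma=1.5))
        alns = identity_alignments(ref, mdl, truth.mapping)
        res = gdt(ref, mdl, truth.mapping, alns)
        ts = sorted(res.fractions)
        values = [res.fractions[t] for t in ts]
        assert values == sorted(values)

    def test_incomplete_model_penalized(self):
        ref, mdl, truth = make_complex(FixtureSpec(stoichiometry="A2", seed=2))
        mdl.chains[0].residues = mdl.chains[0].residues[:6]
        alns = identity_alignments(ref, mdl, truth.mapping)
        res = gdt(ref, mdl, truth.mapping, alns)
        assert res.gdt_ts < 1.0

    def test_hinge_rotation_hurts_gdt_more_than_lddt(self):
        from structscore.lddt import lddt_score
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A1", chain_length=30, seed=37,
            hinge_chain="A", hinge_angle_deg=90.0))
        alns = identity_alignments(ref, mdl, truth.mapping)
        g = gdt(ref, mdl, truth.mapping, alns)
        l = lddt_score(ref, mdl, truth.mapping, alns)
        assert g.gdt_ts < 0.9
        assert l.score > g.gdt_ts

    def test_too_few_positions_not_computable(self):
        ref = Structure(chains=[single_atom_chain("A", [(0, 0, 0), (3.8, 0, 0)])])
        mdl = copy.deepcopy(ref)
        alns = identity_alignments(ref, mdl, {"A": "A"})
        res = gdt(ref, mdl, {"A": "A"}, alns)
        assert res.gdt_ts is None and res.reason


class TestBackboneRmsd:
    def test_identical_structures_zero(self):
        ref, mdl, mapping, alns = _pair_with_alignments(
            FixtureSpec(stoichiometry="A2", seed=3))
        assert backbone_rmsd(ref, mdl, mapping, alns) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_invariance(self):
        ref, mdl, truth = make_complex(FixtureSpec(
            stoichiometry="A3", seed=41, global_rigid=True))
        alns = identity_alignments(ref, mdl, truth.mapping)
        # fixture coordinates are rounded to 0.001 Å
        assert backbone_rmsd(ref, mdl, truth.mapping, alns) < 2e-3

    def test_single_displaced_atom_bound(self):
        n, d = 20, 6.0
        ref = Structure(chains=[single_atom_chain(
            "A", [(i * 3.8, 0, 0) for i in range(n)])])
        mdl = copy.deepcopy(ref)
        mdl.chains[0].residues[0].atoms[0].pos = \
            mdl.chains[0].residues[0].atoms[0].pos + np.array([0, d, 0])
        alns = identity_alignments(ref, mdl, {"A": "A"})
        value = backbone_rmsd(ref, mdl, {"A": "A"}, alns)
        assert 0 < value <= d / np.sqrt(n) + 1e-9

    def test_kabsch_removes_random_rigid_transform(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(30, 3)) * 10
        rot = random_rotation(rng)
        moved = apply_transform(pts, rot, rng.uniform(-50, 50, 3))
        assert superposed_rmsd(moved, pts) == pytest.approx(0.0, abs=1e-9)
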