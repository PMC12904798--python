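import copy

import numpy as np
import pytest

from structscore.grouping import align_chains
from structscore.model import PEPTIDE, Atom, Chain, Residue, Structure
from structscore.synth import FixtureSpec, make_complex, make_ligand, place_ligand_near_chain


def identity_alignments(reference, model, mapping):
    """Residue alignments for a given chain mapping (sequence mode)."""
    return {rc: align_chains(reference.chain(rc), model.chain(mc))
            for rc, mc in mapping.items()}


def single_atom_chain(cid, positions, res_name="GLY", atom_name="CA"):
    """Chain of single-atom residues at the given positions."""
    chain = Chain(id=cid, chain_type=PEPTIDE)
    for i, pos in enumerate(positions):
        res = Residue(name=res_name, number=i + 1)
        res.atoms.append(Atom(name=atom_name, element="C", pos=np.asarray(pos, float)))
        chain.residues.append(res)
    return chain


@pytest.fixture
def dimer_pair():
    ref, mdl, truth = make_complex(FixtureSpec(stoichiometry="A2", seed=42))
    return ref, mdl, truth


@pytest.fixture
def noisy_trimer_pair():
    ref, mdl, truth = make_complex(
        FixtureSpec(stoichiometry="A3", seed=17, noise_sigma=0.4))
    return ref, mdl, truth


@pytest.fixture
def ring_ligand_complex():
    """Dimer with an aromatic-ring ligand docked near chain A."""
    ref, mdl, truth = make_complex(FixtureSpec(stoichiometry="A2", seed=21))
    rlig = place_ligand_near_chain(make_ligand("ring"), ref.chains[0], 3.5)
    mlig = copy.deepcopy(rlig)
    return ref, mdl, rlig, mlig
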