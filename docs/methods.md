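# Methods

This note documents the models, numerical choices and limitations behind
`structscore`.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Structures are read with gemmi from PDBx/mmCIF or legacy PDB; only the
first model of multi-model files is used (with a warning).  Alternate
locations are collapsed to the highest-occupancy conformer (ties: first
altloc alphabetically).  Before polymer scoring, modified residues are
replaced by their parent (SEP→SER and similar), residues unknown to the
component dictionary are removed, hydrogens, terminal OXT and atoms whose
names do not match the dictionary entry are dropped, and chains shorter
than 6 residues (peptides) or 4 (nucleotides) are excluded.  Receptors for
ligand scores keep nonstandard residues.  The component dictionary is a
compact built-in subset (standard amino acids and nucleotides, a few
common modifications, monatomic ions); additional components can be
registered at runtime.  Chain typing uses mmCIF entity annotation when
available and a residue-name majority rule (≥ 50 % nucleotides →
nucleotide chain) for legacy PDB.

## Chain grouping

Pairwise global alignments use Needleman–Wunsch with BLOSUM62
(gap open −11, extend −1) for proteins and NUC44 (−5/−2) for nucleotides;
sequence identity is the fraction of identical columns among aligned
non-gap column pairs.  These two conventions (gap penalties, identity
denominator) are not dictated by the method definition and are exposed in
`AlignmentParams`.  NUC44 carries no U column, so RNA is aligned on the
DNA alphabet (U→T) without altering the stored sequences.  Reference
chains cluster by single-linkage over the ≥ 95 %-identity graph — the
weakest assumption consistent with "clustering" and fully deterministic —
unless mmCIF entity records cover all polymer chains, in which case the
entities define the groups directly (this also merges chains covering
non-overlapping fragments of one target, which sequence identity cannot).
Model chains join the group of maximal identity to the group
representative, subject to a 70 % threshold that can be lowered or removed
(`identity_threshold=None`); removal forces every chain into its best
group, at the cost of possibly pairing unrelated chains.  A
residue-number alignment mode pairs residues with equal author numbering
instead, the recommended setting when models are numbered according to the
target sequence.

## Chain mapping

Both mappers restrict assignments to within chemically equivalent groups.
The number of candidate complete mappings is the product over groups of
C(r,k)·C(m,k)·k! with k = min(r, m); problems at or below 8! candidates
(QSMap) or 5! (QSMapR) are enumerated exhaustively, larger ones fall to
the greedy search.  Both objectives are pairwise decomposable, so each
(reference chain pair → model chain pair) contribution is computed once
and cached; candidate mappings are then scored from cached blocks, and the
greedy search maintains additive gain vectors per candidate pair so a step
costs O(candidates).

The greedy search seeds from every same-group reference/model chain pair,
repeatedly adds the accessible pair that maximizes the objective, and —
when extension stalls before completeness (disconnected complexes) —
re-seeds with every unmapped pair, keeping the best complete mapping over
all seeds.  Accessibility for the QS objective requires a representative
position (Cβ, Cα for glycine) within 12 Å of a mapped chain *and* at least
3 residue contacts at 8 Å; for the LDDT objective, presence within the
inclusion radius (reference side) or radius + 4 Å (model side).
Tie-breaks prefer the lexicographically smallest (reference, model) pair,
making the output deterministic.  A periodic swap-refinement step was
considered and rejected: it multiplies cost without improving the mapping
on these objectives.

QSMapR's objective is the RMSD of one Kabsch superposition over per-group
alignment columns.  The per-group "MSA" is built by aligning every member
(reference and model) pairwise to the group representative; representative
columns covered in all members and carrying a backbone representative are
eligible, and 50 equidistant eligible columns are kept (both choices
config-exposed — the exact MSA construction is open in the method
definition).  The greedy variant ranks extension candidates by their RMSD
under the *current* superposition and refits Kabsch once per step, so a
homo-N-mer costs ~N³ superpositions versus N! for enumeration.

## LDDT

Contacts are reference heavy-atom pairs within the inclusion radius
(default 15 Å; 30 Å as soon as nucleotide chains are present, because
nucleotide backbones are sparser), excluding intra-residue pairs.  A
contact is preserved at threshold t when the model reproduces its distance
within t; missing model atoms count as unpreserved; extra model atoms are
ignored (contrast LDDT-PLI).  The score averages preserved fractions over
0.5/1/2/4 Å.  `backbone` restricts atoms to Cα/C3′; `interface_only`
keeps inter-chain contacts and is undefined (not 0) for monomers.
Residue atom-name symmetries (Asp, Glu, Arg, Phe, Tyr ring flips;
nucleotide OP1/OP2) are resolved greedily per residue — each residue picks
the relabeling maximizing its own preserved contacts, ties keeping the
input labeling.  Global resolution is exponential and the per-residue
choice is exact whenever symmetric residues do not interact with each
other's symmetric atoms, which covers the realistic cases.

### Stereochemistry pre-checks

`stereo_filter` compares bond lengths and angles against a built-in table
of conventional ideal values with standard deviations — peptide backbone
plus Cα–Cβ, and the nucleotide sugar–phosphate skeleton — and removes the
side chain (side-chain violation) or the whole residue (backbone
violation) beyond a 12 σ tolerance; non-bonded heavy atoms closer than the
sum of covalent radii − 0.4 Å are clashes and lose the offending atoms.
Emptied residues remain as placeholders so residue indices and alignments
stay valid.  Side chains beyond Cβ are covered only by the clash check;
the bond/angle table is intentionally compact.  The checks are off by
default in the library (`LddtParams.stereo_checks`) and opt-in on the CLI
(`--stereo-checks`): they presuppose near-ideal covalent geometry, which
the synthetic fixtures used throughout the tests only approximate, and the
tests exercise them on purpose-built ideal/violating fixtures instead.

## QS-score

Interface contacts are residue pairs from different chains with
representative positions (Cβ, Cα for glycine) within 12 Å.  Each contact
carries weight w(d) = 1 for d ≤ 5 Å and exp(−2·((d−5)/4.28)²) beyond, so
loose long-range contacts count less.  For a chain mapping, a contact
present in both structures with distances d₁, d₂ contributes
w(d̄)·(1 − min(|d₁−d₂|, 12)/12) to the numerator and w(d̄) to the
denominator; contacts seen in only one structure contribute their weight
to the denominator — to the *mutual* denominator when both residues are
resolved in both structures, otherwise to the global-only denominator.
QS-global divides by everything (symmetric under model↔reference swap;
extra chains or extra contacts on either side penalize it); QS-best
divides by the mutual part only, so incomplete models and wrong
stoichiometry are not penalized.  The exact weight and difference terms
are this package's documented convention, pinned by golden tests
(self-comparison = 1, symmetry, best ≥ global, the dimer-versus-duplicated
-dimer contrast).

## ICS / IPS

Interface contacts for these scores are residue pairs from different
chains with any heavy-atom pair within 5 Å (the community convention;
configurable).  Model contacts are mapped into reference residue keys via
the chain mapping and alignments; unmappable model contacts still count
against precision.  ICS is the F1 of model versus reference contact sets,
IPS the Jaccard coefficient of interface residue sets.  The full-complex
score pools all contacts (no per-interface weighting — deliberate, since
any aggregation convention would be arbitrary); per-interface values are
reported separately.  The trimmed variants first remove model residues
with no reference counterpart, so regions not covered by experiment cannot
penalize the model.

## DockQ family

Per dimer interface: fnat is the recovered fraction of reference contacts
(5 Å heavy-atom criterion); i-RMSD superposes the backbone (N, CA, C, O —
full sugar-phosphate set for nucleotides) of reference interface residues
(any heavy atom within 10 Å of the partner chain); L-RMSD superposes the
receptor (the larger reference chain; ties by chain id) and measures the
other chain; DockQ = (fnat + 1/(1+(iRMSD/1.5)²) + 1/(1+(LRMSD/8.5)²)) / 3.
The CAPRI peptide parameterization tightens contacts to 4 Å and defines
the interface by Cβ within 8 Å.  DockQ-ave is the plain mean over scored
interfaces and DockQ-wave the native-contact-weighted mean; small but
biologically critical interfaces are down-weighted by -wave, which is why
both are reported.

## GDT and RMSD

GDT works on mapped representative positions (Cα/C3′).  For each
threshold, sliding windows of 7/9/12/24/48 positions (each placed at most
1000 times, equidistantly) seed an iteration of superpose → re-select all
pairs within the threshold → repeat until the set stabilizes (cycle
detection caps the iteration); the largest set ever seen defines the
fraction, with the *total* reference representative count as denominator,
so incomplete models lose score.  GDT_TS averages thresholds 1/2/4/8 Å,
GDT_HA 0.5/1/2/4 Å, both on 0–1.  Backbone RMSD is a single Kabsch
superposition over all mapped representatives; oligomer mappings for both
come from QSMapR, since these are topology-sensitive scores.

## Ligand scores

Ligands are heavy-atom molecular graphs with element node labels.
Connectivity comes from SDF (authoritative), then the component
dictionary, then a last-resort heuristic (bond iff distance <
0.6·(r_vdw,i + r_vdw,j)).  Matching enumerates graph isomorphisms — or
induced subgraph isomorphisms of the reference into the model when
substructure matching is enabled, so incomplete reference density is
tolerated while the model must contain the entire reference ligand.
Coverage is |reference atoms| / |model atoms|.  Enumeration is capped
(default 10⁵ correspondences) with an explicit error advising a larger
cap.

**BiSyRMSD**: the binding site is every reference polymer residue with a
heavy atom within 4 Å of the reference ligand (radius configurable; an
ion coordinated only by another ligand has an empty site and is reported
not-computable unless the radius is raised).  Candidate model chains are
those with a heavy atom within 25 Å of the model ligand — deliberately
lenient so a badly placed site still maps.  Site and candidate chains are
grouped exactly as for chain mapping and *all* group-respecting mappings
are enumerated; per mapping, site residues map through pairwise
alignments, the model site superposes onto the reference site by Kabsch
(Cα/C3′; all backbone atoms when the site has ≤ 2 residues), the
transformed model ligand is compared to the reference ligand under every
symmetry correspondence, and the minimum RMSD over mappings × symmetries
is reported.  RMSD-LP is the site-backbone RMSD of the winning mapping;
LDDT-LP an all-atom LDDT restricted to site residues under the same
mapping, defined as 0 for a single-residue site.

**LDDT-PLI**: contacts are ligand-atom/polymer-atom pairs within 6 Å in
the reference, *plus* pairs within 6 Å in the model whose atoms both map
to the reference (experimental evidence exists for them) — this is the
penalty for contact overprediction; every contact is judged by
|d_model − d_reference| ≤ threshold with the LDDT thresholds.  Chains with
any atom within 10 Å (radius + largest threshold) of the ligand are
included; a contacting model chain whose group has no reference chain in
that set borrows the chemically equivalent reference chain closest to the
reference ligand, so its added contacts can be evaluated rather than
silently dropped.  The reported value is the maximum over chain mappings,
ligand symmetry correspondences and (greedy per-residue) polymer residue
symmetries.  No stereochemistry checks apply.

**Assignment**: BiSyRMSD and LDDT-PLI each get their own greedy
one-to-one assignment: repeatedly take the best-scoring remaining pair,
restricted in each round to pairs whose coverage is within 0.2 (default)
of the maximum remaining coverage; ties prefer higher coverage, then
lexicographic ids.  The window is what keeps a 0.2-coverage solvent match
from displacing a full-coverage cofactor match.  Unscoreable pairs carry
an explicit reason string, never a sentinel value.

## Synthetic fixtures

The generator (`structscore.synth`) builds chains on helix-like parametric
curves arranged on a ring whose spacing (8.5 Å between adjacent chain
axes) guarantees interface contacts without steric collapse; entities get
seeded random sequences, nucleotide chains carry a sugar-phosphate-like
atom set including OP1/OP2.  Perturbations with known ground truth —
per-atom Gaussian noise, a global rigid transform, chain relabeling, chain
displacement, domain hinges, dropped chains — drive every test surface,
and ligand templates (aromatic ring, linear chain, ion, disconnected
fragments) cover the symmetry and multi-fragment cases.  Coordinates are
rounded to 0.001 Å so mmCIF, PDB and SDF encodings round-trip exactly.
These toys emulate the combinatorial and geometric structure of the
benchmarking problem, not protein physics: passing tests demonstrate
correctness of the scoring and search machinery, not performance on real
experimental pathologies (density gaps, alternate conformers, exotic
chemistry).  Stereochemistry tests use purpose-built ideal/violating
fixtures instead of the curve-based chains.

## Problem sizes and determinism

The test suite and the acceptance script run everything at desk scale:
mapping-oracle checks use homo-3- to 6-mers (where brute-force
enumeration is exact and fast), LDDT-oracle checks use ≤ 500-atom
complexes, and the scaling check runs the greedy mapper on 10- and
20-chain homomers, asserting completion.  The acceptance script samples
fewer fixtures per quantity than the test suite (its `n` fields state the
sizes used); both derive all randomness from explicit seeds.  Every
algorithm is deterministic — identical inputs produce byte-identical
JSON reports.

## Known limitations

* The component dictionary subset covers standard residues, a few common
  modifications and monatomic ions; exotic components need runtime
  registration or fall back to heuristic connectivity.
* Stereochemistry tables stop at Cα–Cβ; side-chain torsion pathologies
  surface only through clashes.
* Polymer symmetry enumeration inside LDDT-PLI is greedy per residue, not
  global; a contrived fixture with interacting symmetric residues could in
  principle score below the true optimum.
* Peptide and oligosaccharide ligands, interaction fingerprints and
  biological-relevance filtering of ligands are out of scope, as are
  rigid-superposition scores delegated to external tools elsewhere
  (TM-score, CAD-score).
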