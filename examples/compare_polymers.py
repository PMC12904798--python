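"""Compare a perturbed model complex against its reference.

Builds a synthetic hetero-2-1 complex, perturbs the model with 0.4 Å of
coordinate noise, and runs the full polymer comparison pipeline (chain
mapping, LDDT family, QS-score, ICS/IPS, DockQ, GDT, RMSD).
"""

from structscore import io
from structscore.reports import RunConfig, compare_structures
from structscore.synth import FixtureSpec, make_complex

ref, mdl, truth = make_complex(
    FixtureSpec(stoichiometry="A2B1", seed=3, noise_sigma=0.4))
io.write_mmcif(ref, "/tmp/example_ref.cif")
io.write_pdb(mdl, "/tmp/example_mdl.pdb")

report = compare_structures(RunConfig(
    reference="/tmp/example_ref.cif", model="/tmp/example_mdl.pdb",
    lddt=True, bb_lddt=True, i_lddt=True, qs_score=True, ics_ips=True,
    dockq=True, gdt=True, rmsd=True))

print("chain mapping (QSMap):", report["qsmap"]["pairs"],
      f"search={report['qsmap']['search_mode']}")
for name, entry in sorted(report["scores"].items()):
    value = entry["value"]
    print(f"  {name:12s} {value if value is None else round(value, 4)}")

print("""
LDDT/QS/ICS near 1 and RMSD well under 1 Å mean the 0.4 Å noise barely
disturbs local distances, interface contacts or the superposed backbone;
i-LDDT isolates the interface contribution, and qs_best equals qs_global
because model and reference share the same stoichiometry.""")
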