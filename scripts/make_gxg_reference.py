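"""Regenerate the Gly-X-Gly relative-SASA reference data file.

Run from the repository root; uses only the package itself.
"""
from protvarmap.fixtures import synth_structure
from protvarmap.pdbio import ResidueID
from protvarmap.sasa import SASAParams, compute_sasa
from protvarmap.variants import AA1, ONE_TO_THREE

lines = ["# Reference solvent accessible areas (Angstrom^2): central",
         "# residue of a fully extended Gly-X-Gly tripeptide built with",
         "# the package's own backbone generator and side-chain templates.",
         "name3\tarea"]
for x in sorted(AA1):
    ids = [ResidueID("A", i) for i in (1, 2, 3)]
    s = synth_structure(f"G{x}G", ids, "EXTENDED")
    rep = compute_sasa(s, SASAParams())
    area = rep.per_residue_abs[ids[1]]
    lines.append(f"{ONE_TO_THREE[x]}\t{area:.2f}")
open("src/protvarmap/data/gxg_reference.tsv", "w").write(
    "\n".join(lines) + "\n")
print("\n".join(lines[3:8]))
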