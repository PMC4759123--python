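# Methods

This note documents the models, parameter choices and limitations behind
`protvarmap`. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is quoted from
external runs.

## Problem setting

Missense variants are reported in UniProt canonical coordinates
(1-based positions on the single canonical sequence per gene; isoforms
are out of scope). Experimental structures carry *author numbering*,
which frequently disagrees with canonical numbering: insertion codes
(`60A`), constant offsets from truncated constructs, offsets that change
mid-chain, engineered mutations, expression tags, and residues without
coordinates. Placing a variant on a structure therefore requires an
explicit residue-level correspondence, which this package derives from
sequence alignment rather than trusting author numbers.

## Structure reading

The fixed-column PDB reader keeps exactly the identity details the
mapping depends on: chain id, author number, insertion code, altloc and
occupancy. Policies, chosen where the format leaves freedom:

- **Multi-model (NMR) files**: only MODEL 1 is kept, giving one
  coordinate set per entry and hence one model per mutation per entry.
- **Altlocs**: the highest-occupancy conformer wins; ties go to the
  first conformer in file order. The reduction never changes residue
  counts.
- **MSE** (selenomethionine) translates to `M`; other modified residues
  become `X`, which deliberately fails the no-mismatch quality filter —
  a conservative default for chemistry the mutant builder cannot
  represent.
- **Polymer membership**: a HETATM residue counts as polymer if its
  name is in the amino-acid table and it lies between ATOM residues of
  its chain in file order; terminal HETATMs and ligands do not.
- **Hydrogens** are read but ignored by every downstream computation
  (mutation, SASA); the modelling is heavy-atom based.

Observed sequences come from ATOM records only, never SEQRES, because
the mapping must describe residues that actually have coordinates.

## Alignment

A Gotoh three-state dynamic program over BLOSUM62 (shipped in EMBOSS
data-file syntax) with affine gaps: open 10.0, extend 0.5, end gaps
free by default. These are the defaults of the EMBOSS `needle` program,
whose behaviour this module is parameter-compatible with. The gap cost
convention is `open + (L−1)·extend` for a run of length L — asserted
against an exhaustive all-alignments oracle in the tests rather than
assumed. Traceback ties break diagonal > up > left, which fixes the
pairing deterministically but never affects the score. `X` scores use
the matrix's own X row.

## Mapping, quality control, renumbering

Residue–residue alignment columns become mapped pairs. Derived
quantities per chain:

- **mismatches** — pairs whose letters differ (engineered mutations,
  unmodelled chemistry);
- **missing internal** — canonical positions between the first and last
  mapped position with no structure residue (the testable reading of
  "missing residues in the mapped range");
- **offsets** — canonical position minus author number, per pair. These
  need not be constant along a chain.

A chain passes QC iff it has no mismatches, no internal missing
positions, and **more than 20** mapped residues (21 is the minimum
accepted; the boundary is tested both sides). Each chain is mapped and
QC'd independently; one bad chain does not reject an entry.

Renumbering assigns each mapped residue its canonical position with a
blank insertion code and leaves every coordinate bit-identical.
Unmapped polymer flanks (expression tags, termini beyond the canonical
range) are retained and renumbered by constant-offset extrapolation from
the nearest mapped residue, and flagged in provenance — dropping them
would silently change solvent accessibility. Collisions or
non-monotone results raise an error. Renumbering is idempotent:
re-mapping a renumbered chain yields the identity mapping.

## Variant handling

Input rows carry rs id, gene, accession and a protein change
(`p.Arg280Ile`, `R280I`, or ref/pos/alt columns). Only single
amino-acid substitutions are kept; synonymous, frameshift, indel, stop
and unparseable rows are dropped and counted per reason, and row
accounting (rows in = kept + dropped) is enforced. rs ids are stored as
bare digits to match the model filename convention. Placement requires
the canonical letter at the variant position to equal the claimed
reference residue; positions outside the mapped range are NOT_COVERED,
disagreements are REF_MISMATCH. Prediction scores (PolyPhen2/SIFT) and
site annotations are pass-through columns, never computed.

## Mutant models

Exactly one residue changes, and only its side chain: N, CA, C, O keep
bit-identical coordinates, the original CB is retained whenever both
residues have one, and the remaining side-chain atoms are rebuilt by
sequential internal-coordinate (NeRF) placement from a plain-text
template file. Template bond lengths, angles and ring torsions were
measured from the PDB Chemical Component Dictionary ideal coordinates;
chi defaults are common backbone-independent rotamers (chi1 −65° for
most types, +62° for Ser/Thr, 175° for Val; 180° for any unlisted
chi), overridable per call. Glycine targets simply drop the side
chain; proline is built entirely from template torsions, so its ring
closure (CD–N) is approximate rather than ideal. No rotamer search,
clash relief or minimisation is performed — heavy-atom contacts with
the environment under 2.0 Å are counted and reported in provenance, not
fixed. Exact mutant side-chain coordinates from any particular external
modelling program are therefore not reproduced, by design; what is
guaranteed is the minimal-perturbation contract and ideal geometry
(CA–CB 1.53 ± 0.02 Å, template bonds to numerical precision).

## Solvent accessible surface area

Shrake–Rupley: each heavy atom's sphere is expanded by the probe
(1.4 Å) and sampled with a deterministic Fibonacci-spiral point set
(default 960 points/atom); the accessible fraction scales the expanded
sphere's area. Radii are a NACCESS-style per-element set (C 1.87,
N 1.65, O 1.40, S 1.85, P 1.80, Se 1.90 Å) shipped as data. Waters are
excluded by default; other hetero molecules (ligands, nucleic acids)
are included so a mutation site keeps its interacting environment.

Numerical behaviour, measured on fixtures: an isolated sphere matches
4π(r+1.4)² to well under 1%; a two-sphere overlap matches the analytic
spherical-cap formula to under 1%; totals at 960 vs 3840 points agree
to 0.5%. The spiral quadrature has a small orientation dependence
(about 0.2–0.3% at 960 points on a ten-residue chain), which vanishes
with resolution; rigid-motion invariance to 0.1% is asserted at 61440
points.

Relative accessibility normalises a residue's area by the area of the
same residue type in a fully extended Gly-X-Gly tripeptide built with
this package's own backbone generator and side-chain templates
(reference table shipped as data, regenerable from the package). By
construction the central residue of each reference tripeptide scores
1.0 ± 0.05. Chain-terminal residues can legitimately exceed 1. The
normalisation is self-consistent rather than tied to any external
program's reference table, so relative values are comparable within
this package but not bit-compatible with other tools.

## Synthetic fixtures

The generator produces physically plausible toy structures (ideal
backbone geometry: extended or alpha-helical, CA–CA 3.8 Å, template
side chains) paired with a canonical sequence and the exact
ground-truth mapping, for eight pathology kinds: clean, insertion code,
constant offset, inconsistent offset (an author-number jump with no
residue missing), missing internal residue, point mutation, tag flank
and short chain. The backbone is deterministic; only the sequence draw
uses the seed. Minimal local constraints keep the optimal alignment
unique so truth recovery is exact (a deleted residue differs from its
neighbours; a histidine tag cannot slide onto a leading canonical H).
Two labelled emulations reproduce published numbering pathologies
residue-for-residue: the insertion-code case (Gly60/Cys60A/Phe61
against canonical Gly60/Cys61/Phe62) and the offset-jump case (author
Ile116/Thr118 against canonical Ile129/Thr130, offset 12 at canonical
Lys238 ↔ author 226).

What fixtures do *not* emulate: real protein folds, crystallographic
disorder, real B-factors/occupancy patterns, nucleic acids, and real
expression-construct sequences. Passing the truth-recovery suite shows
the mapping logic is correct on every catalogued numbering pathology;
it does not certify behaviour on pathologies outside the catalogue
(e.g. chimeric constructs or circular permutants).

## Pipeline

For each structure chain, the best-scoring canonical sequence in the
FASTA is taken as the chain's protein (deterministic, FASTA order
breaks ties) — a deliberate simplification standing in for the
RefSeq/UniParc cross-referencing a production database would use. Every
(variant × matching chain) yields one output row; models are built only
for QC-accepted chains with cleanly placed variants, one model per
(variant, entry, chain) — a first-chain-only flag gives one per entry.
Per-record failures become rows and log entries, never aborts. Outputs
(table, renumbered structures, mapping TSVs, models, drop report, count
log) are byte-identical across re-runs.

## Problem sizes in the checks

The acceptance checks run entirely offline on generated inputs:
500 random pairs (length ≤ 6) against the exhaustive alignment oracle;
100 seeds × 8 pathology kinds for truth recovery; ten-to-twelve-residue
chains for mutation and SASA contracts; a one-structure/one-variant
corpus for pipeline idempotence. These sizes exercise every branch of
the method while keeping the whole suite in about a minute of CPU.

## Known limitations

- mmCIF, ANISOU, symmetry/biological assemblies and SEQRES are out of
  scope; very large entries with >9999-residue chains cannot be written
  back to fixed columns.
- Chain–accession association is by alignment score, not curated
  cross-references; with near-identical paralogues in one FASTA the
  tie-break is deterministic but arbitrary.
- Side-chain conformation is a fixed rotamer policy; buried mutations
  will often clash (reported, not relieved).
- Absolute SASA values depend on the radius set and quadrature;
  relative values depend on this package's own reference conformation.
  Portal- or program-specific absolute numbers from other tools are not
  comparable targets.
- Counts from any particular historical variant/structure snapshot
  (how many proteins, entries or models a database release contains)
  are properties of those snapshots, not of this method, and are not
  asserted anywhere.
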