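"""PDB-to-UniProt residue renumbering.

Author numbering in deposited structures frequently disagrees with the
UniProt canonical sequence: insertion codes (``Cys60A``), constant offsets
from truncated constructs, offsets that change mid-chain, engineered point
mutations and expression tags.  This module derives the residue-level
correspondence from a global alignment of the coordinate-derived sequence
against the canonical sequence, applies the quality filters (no mutations,
no internal missing residues, mapped range longer than 20 residues), and
rewrites structures with canonical numbering.

Each chain is mapped and quality-controlled independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

from .align import AlignParams, global_align
from .pdbio import ObservedSequence, ResidueID, Structure

__all__ = [
    "CanonicalSequence",
    "MappedPair",
    "ResidueMapping",
    "QCVerdict",
    "RenumberProvenance",
    "EmptyMappingError",
    "RenumberingConflictError",
    "QCError",
    "build_mapping",
    "qc_evaluate",
    "apply_renumbering",
    "read_canonical_fasta",
    "mapping_to_tsv",
]


class EmptyMappingError(ValueError):
    """Alignment produced no residue-residue column."""


class RenumberingConflictError(ValueError):
    """Two residues would share a number after renumbering."""


class QCError(ValueError):
    """Renumbering requested for a mapping that failed quality control."""


@dataclass(frozen=True)
class CanonicalSequence:
    """A UniProt canonical sequence; positions are 1-based, no isoforms."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty canonical sequence")
        if not self.sequence.isalpha() or not self.sequence.isupper():
            raise ValueError("canonical sequence must be uppercase A-Z")

    def letter(self, position: int) -> str:
        return self.sequence[position - 1]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappedPair:
    residue: ResidueID
    canonical_position: int
    pdb_aa: str
    canonical_aa: str

    @property
    def offset(self) -> int:
        """Canonical position minus author number."""
        return self.canonical_position - self.residue.author_number

    @property
    def is_mismatch(self) -> bool:
        return self.pdb_aa != self.canonical_aa


@dataclass
class ResidueMapping:
    """Alignment-derived correspondence for one chain."""

    accession: str
    chain: str
    pairs: list[MappedPair]
    missing_internal: list[int]
    score: float

    @property
    def mismatches(self) -> list[MappedPair]:
        return [p for p in self.pairs if p.is_mismatch]

    @property
    def mapped_range(self) -> tuple[int, int]:
        return (self.pairs[0].canonical_position,
                self.pairs[-1].canonical_position)

    @property
    def offsets(self) -> list[int]:
        return [p.offset for p in self.pairs]

    def canonical_positions(self) -> dict[int, MappedPair]:
        return {p.canonical_position: p for p in self.pairs}


@dataclass(frozen=True)
class QCVerdict:
    """Structure filter: accepted iff no rejection reason fired."""

    reasons: frozenset[str]

    @property
    def accepted(self) -> bool:
        return not self.reasons


@dataclass
class RenumberProvenance:
    """What :func:`apply_renumbering` did to each residue."""

    id_map: dict[ResidueID, ResidueID] = field(default_factory=dict)
    extrapolated: list[ResidueID] = field(default_factory=list)


def build_mapping(obs: ObservedSequence, canon: CanonicalSequence,
                  p: AlignParams | None = None) -> ResidueMapping:
    """Align an observed chain sequence to the canonical sequence.

    Residue-residue alignment columns become mapped pairs; columns where
    the letters differ are recorded as mismatches; canonical positions
    between the first and last mapped position with no structure residue
    are recorded as internal missing residues.
    """
    if not obs.letters:
        raise EmptyMappingError(f"chain {obs.chain}: no polymer residues")
    aln = global_align(obs.letters, canon.sequence, p)
    pairs = [
        MappedPair(obs.ids[i], j + 1, obs.letters[i], canon.sequence[j])
        for i, j in aln.pairs
    ]
    if not pairs:
        raise EmptyMappingError(
            f"chain {obs.chain}: alignment has no residue-residue column"
        )
    covered = {pr.canonical_position for pr in pairs}
    first, last = min(covered), max(covered)
    missing = [pos for pos in range(first, last + 1) if pos not in covered]
    return ResidueMapping(canon.accession, obs.chain, pairs, missing,
                          aln.score)


#: Minimum mapped length that passes quality control ("more than 20").
MIN_MAPPED_LENGTH = 21


def qc_evaluate(m: ResidueMapping) -> QCVerdict:
    """Quality filter on a mapping.

    Rejects structures with mutations in the mapped range, internal
    missing residues, or a mapped range of 20 residues or fewer.
    """
    reasons = set()
    if m.mismatches:
        reasons.add("MUTATION_IN_RANGE")
    if m.missing_internal:
        reasons.add("MISSING_RESIDUE")
    if len(m.pairs) < MIN_MAPPED_LENGTH:
        reasons.add("SHORT_RANGE")
    return QCVerdict(frozenset(reasons))


def apply_renumbering(
    s: Structure,
    m: ResidueMapping,
    force: bool = False,
) -> tuple[Structure, RenumberProvenance]:
    """Rewrite one chain of ``s`` with canonical numbering.

    Mapped residues take their canonical position with a blank insertion
    code.  Unmapped polymer flank residues (expression tags, disordered
    termini that still have coordinates) are kept and renumbered by
    constant-offset extrapolation from the nearest mapped residue, and
    flagged in the returned provenance.  Coordinates are untouched.
    """
    if not force:
        verdict = qc_evaluate(m)
        if not verdict.accepted:
            raise QCError(
                f"mapping {m.accession}/{m.chain} failed QC: "
                f"{sorted(verdict.reasons)}"
            )
    out = s.copy()
    prov = RenumberProvenance()
    chain_residues = out.chains.get(m.chain)
    if chain_residues is None:
        raise KeyError(f"no chain {m.chain!r} in structure {s.pdb_id}")

    by_old_id = {p.residue: p for p in m.pairs}
    mapped_idx = [i for i, r in enumerate(chain_residues)
                  if r.id in by_old_id]
    if not mapped_idx:
        raise EmptyMappingError("mapping touches no residue of the chain")

    new_ids: dict[int, ResidueID] = {}
    for i in mapped_idx:
        r = chain_residues[i]
        new_ids[i] = ResidueID(m.chain, by_old_id[r.id].canonical_position)

    # Flanks: extrapolate sequentially outward from the nearest mapped
    # residue so insertion-coded or irregularly numbered tags still get
    # unique, monotone numbers.
    first_m, last_m = mapped_idx[0], mapped_idx[-1]
    from .pdbio import _polymer_flags
    polymer = _polymer_flags(chain_residues)
    for i in range(first_m - 1, -1, -1):
        if not polymer[i]:
            continue
        nxt = min(k for k in new_ids if k > i and polymer[k])
        new_ids[i] = ResidueID(m.chain, new_ids[nxt].author_number - 1)
        prov.extrapolated.append(chain_residues[i].id)
    for i in range(last_m + 1, len(chain_residues)):
        if not polymer[i]:
            continue
        prv = max(k for k in new_ids if k < i and polymer[k])
        new_ids[i] = ResidueID(m.chain, new_ids[prv].author_number + 1)
        prov.extrapolated.append(chain_residues[i].id)

    seen: set[tuple[int, str]] = set()
    previous = None
    for i, r in enumerate(chain_residues):
        if i not in new_ids:
            continue  # waters / non-polymer ligands keep author numbers
        nid = new_ids[i]
        key = (nid.author_number, nid.insertion_code)
        if key in seen:
            raise RenumberingConflictError(
                f"residue number {nid.author_number} assigned twice in "
                f"chain {m.chain}"
            )
        seen.add(key)
        if previous is not None and nid.author_number <= previous:
            raise RenumberingConflictError(
                f"renumbering not strictly increasing at {nid}"
            )
        previous = nid.author_number
        prov.id_map[r.id] = nid
        r.id = nid
    return out, prov


def read_canonical_fasta(path) -> dict[str, CanonicalSequence]:
    """Read canonical sequences from FASTA, keyed by accession.

    The accession is the first word of the header; the UniProt
    ``sp|P11766|ADHX_HUMAN`` dialect is recognised and the middle field
    used.
    """
    out: dict[str, CanonicalSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id.split()[0]
        if "|" in acc:
            fields = acc.split("|")
            if len(fields) >= 3 and fields[0] in ("sp", "tr"):
                acc = fields[1]
        out[acc] = CanonicalSequence(acc, str(rec.seq).upper())
    return out


def mapping_to_tsv(m: ResidueMapping) -> str:
    """Mapping export: one row per aligned pair."""
    lines = ["chain\tauthor_number\tinsertion_code\tcanonical_position"
             "\tpdb_aa\tcanonical_aa\toffset"]
    for p in m.pairs:
        lines.append(
            f"{p.residue.chain}\t{p.residue.author_number}\t"
            f"{p.residue.insertion_code}\t{p.canonical_position}\t"
            f"{p.pdb_aa}\t{p.canonical_aa}\t{p.offset}"
        )
    return "\n".join(lines) + "\n"
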