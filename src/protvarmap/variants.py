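"""Missense variant tables: parsing, filtering and structure placement.

Input rows carry a dbSNP rs identifier, a gene symbol, a UniProt accession
and a protein change.  Only single amino-acid substitutions are retained;
synonymous changes, frameshifts, indels, stop gains and unparseable
strings are dropped and counted per reason.  A retained variant is placed
onto a renumbered chain by looking its canonical position up in the
residue mapping and checking the reference letter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from io import StringIO

import pandas as pd

from .pdbio import ResidueID, THREE_TO_ONE
from .renumber import CanonicalSequence, ResidueMapping

__all__ = [
    "MissenseVariant",
    "PlacedVariant",
    "DropReason",
    "ParseReport",
    "parse_change",
    "parse_variants",
    "place_variant",
    "ChangeParseError",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
_THREE_TO_ONE_AA = {k: v for k, v in THREE_TO_ONE.items() if k != "MSE"}


class ChangeParseError(ValueError):
    pass


class DropReason:
    SYNONYMOUS = "SYNONYMOUS"
    FRAMESHIFT = "FRAMESHIFT"
    INDEL = "INDEL"
    STOP = "STOP"
    UNPARSEABLE = "UNPARSEABLE"


@dataclass(frozen=True)
class MissenseVariant:
    """One single amino-acid substitution in UniProt canonical coordinates.

    The rs identifier is stored as bare digits (``121912660``, not
    ``rs121912660``) to match the model filename convention.
    """

    rs_id: str
    gene: str
    accession: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref and alt residues must differ")
        if self.position < 1:
            raise ValueError("canonical positions are 1-based")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA1:
                raise ValueError(f"{aa!r} is not a standard amino acid")

    @property
    def ref_aa3(self) -> str:
        return ONE_TO_THREE[self.ref_aa]

    @property
    def alt_aa3(self) -> str:
        return ONE_TO_THREE[self.alt_aa]


@dataclass(frozen=True)
class PlacedVariant:
    variant: MissenseVariant
    pdb_id: str
    chain: str
    residue: ResidueID | None
    status: str  # PLACED | NOT_COVERED | REF_MISMATCH


_RE_P3 = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{1,3}|\*|=)$")
_RE_P1 = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*=])$")
_FS = re.compile(r"fs", re.IGNORECASE)
_INDEL = re.compile(r"(del|ins|dup)", re.IGNORECASE)


def parse_change(change: str) -> tuple[str, int, str]:
    """Parse a protein change string into (ref, position, alt) one-letter.

    Accepts ``p.Arg280Ile`` and ``R280I`` spellings.  Raises
    :class:`ChangeParseError` with a reason attribute for everything that
    is not a simple substitution.
    """
    change = change.strip()
    if _FS.search(change):
        raise ChangeParseError(DropReason.FRAMESHIFT)
    if _INDEL.search(change):
        raise ChangeParseError(DropReason.INDEL)
    m = _RE_P3.match(change)
    if m:
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        ref = _THREE_TO_ONE_AA.get(ref3.upper())
        if ref is None:
            raise ChangeParseError(DropReason.UNPARSEABLE)
        if alt3 in ("*",) or alt3.upper() == "TER":
            raise ChangeParseError(DropReason.STOP)
        if alt3 == "=":
            raise ChangeParseError(DropReason.SYNONYMOUS)
        alt = _THREE_TO_ONE_AA.get(alt3.upper())
        if alt is None:
            raise ChangeParseError(DropReason.UNPARSEABLE)
    else:
        m = _RE_P1.match(change)
        if not m:
            raise ChangeParseError(DropReason.UNPARSEABLE)
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "*":
            raise ChangeParseError(DropReason.STOP)
        if alt == "=":
            raise ChangeParseError(DropReason.SYNONYMOUS)
        if ref not in AA1 or alt not in AA1:
            raise ChangeParseError(DropReason.UNPARSEABLE)
    if ref == alt:
        raise ChangeParseError(DropReason.SYNONYMOUS)
    return ref, pos, alt


@dataclass
class ParseReport:
    """Bookkeeping for a parsed variant table.

    ``rows_in == len(variants) + sum(dropped_by_reason.values())`` always
    holds.
    """

    rows_in: int
    variants: list[MissenseVariant]
    dropped: list[tuple[int, str]]  # (row number, reason)

    @property
    def dropped_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.dropped:
            out[reason] = out.get(reason, 0) + 1
        return out

    def drop_report_tsv(self) -> str:
        lines = ["row\treason"]
        lines += [f"{row}\t{reason}" for row, reason in self.dropped]
        return "\n".join(lines) + "\n"


def parse_variants(table: str | StringIO) -> ParseReport:
    """Parse a variant TSV with columns rs_id, gene, accession, change.

    Alternatively the change may be given as three columns ``ref``,
    ``pos``, ``alt``.  Extra columns (e.g. polyphen2, sift annotations)
    are ignored here; the pipeline carries them through separately.
    """
    if isinstance(table, str):
        table = StringIO(table)
    df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    required = {"rs_id", "gene", "accession"}
    if not required <= set(df.columns):
        raise ValueError(
            f"variant table must have columns {sorted(required)} plus "
            "'change' or 'ref'/'pos'/'alt'"
        )
    has_change = "change" in df.columns
    if not has_change and not {"ref", "pos", "alt"} <= set(df.columns):
        raise ValueError("no 'change' column and no ref/pos/alt columns")

    variants: list[MissenseVariant] = []
    dropped: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based with header
        try:
            if has_change and row["change"]:
                ref, pos, alt = parse_change(row["change"])
            else:
                ref, alt = str(row["ref"]).upper(), str(row["alt"]).upper()
                if len(ref) == 3:
                    ref = _THREE_TO_ONE_AA.get(ref, "?")
                if len(alt) == 3:
                    alt = _THREE_TO_ONE_AA.get(alt, "?")
                pos = int(row["pos"])
                if ref == alt:
                    raise ChangeParseError(DropReason.SYNONYMOUS)
                if ref not in AA1 or alt not in AA1:
                    raise ChangeParseError(DropReason.UNPARSEABLE)
        except ChangeParseError as e:
            dropped.append((rownum, str(e)))
            continue
        except (ValueError, KeyError):
            dropped.append((rownum, DropReason.UNPARSEABLE))
            continue
        rs = str(row["rs_id"]).strip()
        if rs.lower().startswith("rs"):
            rs = rs[2:]
        variants.append(MissenseVariant(
            rs_id=rs, gene=str(row["gene"]).strip(),
            accession=str(row["accession"]).strip(),
            position=pos, ref_aa=ref, alt_aa=alt,
        ))
    return ParseReport(len(df), variants, dropped)


def place_variant(v: MissenseVariant, m: ResidueMapping,
                  canon: CanonicalSequence,
                  pdb_id: str = "XXXX") -> PlacedVariant:
    """Locate a variant on a mapped chain.

    PLACED means the canonical position is covered by the mapping and the
    canonical letter matches the variant's reference residue; the returned
    residue identity is the post-renumbering one (author number equals
    canonical position).
    """
    if v.accession != canon.accession:
        raise ValueError(
            f"variant accession {v.accession} does not match canonical "
            f"sequence {canon.accession}"
        )
    pair = m.canonical_positions().get(v.position)
    if pair is None:
        return PlacedVariant(v, pdb_id, m.chain, None, "NOT_COVERED")
    if canon.letter(v.position) != v.ref_aa or pair.pdb_aa == "X":
        # an 'X' structure residue (unknown chemistry) cannot anchor a
        # substitution even if the canonical letter agrees
        return PlacedVariant(v, pdb_id, m.chain, None, "REF_MISMATCH")
    return PlacedVariant(
        v, pdb_id, m.chain, ResidueID(m.chain, v.position), "PLACED")
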