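"""Synthetic structure/sequence fixtures with known ground truth.

Generates physically plausible toy protein structures (ideal-geometry
backbone, template-built side chains) paired with a canonical sequence
and the exact residue mapping an analysis must recover.  Each pathology
kind reproduces a numbering discrepancy seen in deposited structures:

- ``CLEAN``              author numbers equal canonical positions
- ``INSERTION_CODE``     a residue numbered like 60A, shifting later
                         numbers down by one
- ``CONSTANT_OFFSET``    author numbers shifted by a constant
- ``INCONSISTENT_OFFSET`` a jump in author numbers with no residue
                         actually missing, so the offset changes mid-chain
- ``MISSING_INTERNAL``   an interior residue without coordinates
- ``POINT_MUTATION``     one engineered substitution
- ``TAG_FLANK``          an expression tag before the native N terminus
- ``SHORT_CHAIN``        a mapped range too short to pass quality control

The backbone is deterministic; only the sequence draw uses the seed, so
geometry assertions stay stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import place_atom
from .mutate import build_sidechain, load_templates
from .pdbio import (Atom, Residue, ResidueID, Structure, THREE_TO_ONE,
                    write_structure)
from .renumber import (CanonicalSequence, MappedPair, QCVerdict,
                       ResidueMapping, qc_evaluate)
from .variants import AA1, ONE_TO_THREE

__all__ = [
    "PathologySpec",
    "SpecError",
    "KINDS",
    "synth_backbone",
    "synth_structure",
    "synth_pair",
    "synth_insertion_code_case",
    "synth_offset_jump_case",
    "write_corpus",
]

KINDS = ("CLEAN", "INSERTION_CODE", "CONSTANT_OFFSET",
         "INCONSISTENT_OFFSET", "MISSING_INTERNAL", "POINT_MUTATION",
         "TAG_FLANK", "SHORT_CHAIN")

# ideal backbone geometry (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.5
_CONF = {
    "EXTENDED": (-180.0, 180.0),  # fully extended strand
    "HELIX": (-57.0, -47.0),      # alpha helix
}


class SpecError(ValueError):
    """Pathology parameters inconsistent with the requested kind."""


@dataclass(frozen=True)
class PathologySpec:
    kind: str
    seed: int = 0
    length: int = 40          # canonical sequence length
    window: tuple[int, int] | None = None  # canonical range with coords
    site: int | None = None   # canonical position of the pathology
    offset: int = 12          # author-number shift (CONSTANT_OFFSET)
    offset2: int = 11         # shift after the jump (INCONSISTENT_OFFSET)
    tag_length: int = 6       # His-tag length (TAG_FLANK)
    chain: str = "A"
    conformation: str = "EXTENDED"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SpecError(f"unknown pathology kind {self.kind!r}")
        if self.length < 3:
            raise SpecError("chain length must be at least 3")

    def resolved_window(self) -> tuple[int, int]:
        if self.window is not None:
            w = self.window
        elif self.kind == "TAG_FLANK":
            w = (1, self.length)
        elif self.kind == "SHORT_CHAIN":
            w = (4, 4 + 20 - 1)  # exactly 20 mapped residues: rejected
        else:
            w = (4, self.length - 3)
        if not (1 <= w[0] <= w[1] <= self.length):
            raise SpecError(f"window {w} outside canonical 1..{self.length}")
        return w

    def resolved_site(self) -> int:
        w = self.resolved_window()
        site = self.site if self.site is not None else (w[0] + w[1]) // 2
        if not (w[0] + 1 < site < w[1] - 1):
            raise SpecError(f"site {site} too close to window edge {w}")
        return site


def synth_backbone(n: int, conformation: str = "EXTENDED") -> list[dict]:
    """Ideal-geometry backbone: N, CA, C, O coordinates per residue.

    Deterministic; consecutive CA-CA distances are ~3.8 Angstrom and an
    alpha-helical trace has the usual ~5.4 Angstrom CA(i)-CA(i+3)
    spacing.
    """
    if n < 1:
        raise ValueError("need at least one residue")
    phi, psi = _CONF[conformation]
    res: list[dict] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    for i in range(n):
        if i > 0:
            prevN, prevCA, prevC = res[-1]["N"], res[-1]["CA"], res[-1]["C"]
            N = place_atom(prevN, prevCA, prevC, _B_C_N, _A_CA_C_N, psi)
            CA = place_atom(prevCA, prevC, N, _B_N_CA, _A_C_N_CA, 180.0)
            C = place_atom(prevC, N, CA, _B_CA_C, _A_N_CA_C, phi)
        res.append({"N": N, "CA": CA, "C": C})
    for i in range(n):
        # carbonyl O anti to the next amide N (trans peptide)
        if i + 1 < n:
            o_tor = 180.0 + psi
        else:
            o_tor = 180.0 + psi  # same convention for the C terminus
        res[i]["O"] = place_atom(
            res[i]["N"], res[i]["CA"], res[i]["C"], _B_C_O, _A_CA_C_O,
            o_tor)
    return res


def synth_structure(
    sequence: str,
    ids: list[ResidueID],
    conformation: str = "EXTENDED",
    pdb_id: str = "SYNT",
    with_ligand: bool = False,
) -> Structure:
    """Build a structure for ``sequence`` with the given residue identities.

    Side chains use the mutation module's own templates.  ``with_ligand``
    appends a rigid one-atom dummy ligand for hetero-handling tests.
    """
    if len(sequence) != len(ids):
        raise ValueError("sequence and ids must be parallel")
    templates = load_templates()
    backbone = synth_backbone(len(sequence), conformation)
    chains: dict[str, list[Residue]] = {}
    for letter, rid, frame in zip(sequence, ids, backbone):
        name3 = ONE_TO_THREE.get(letter, "UNK")
        atoms = [
            Atom("N", "N", tuple(map(float, frame["N"]))),
            Atom("CA", "C", tuple(map(float, frame["CA"]))),
            Atom("C", "C", tuple(map(float, frame["C"]))),
            Atom("O", "O", tuple(map(float, frame["O"]))),
        ]
        if name3 in templates and templates[name3].atoms:
            atoms += build_sidechain(templates[name3], frame)
        chains.setdefault(rid.chain, []).append(
            Residue(rid, name3, atoms))
    s = Structure(pdb_id=pdb_id, method="XRAY", resolution=1.8,
                  chains=chains)
    if with_ligand:
        chain0 = next(iter(chains))
        far = np.asarray(backbone[-1]["C"]) + np.array([8.0, 0.0, 0.0])
        chains[chain0].append(Residue(
            ResidueID(chain0, 900), "LIG",
            [Atom("C1", "C", tuple(map(float, far)))], is_hetero=True))
    return s


def _draw_sequence(rng: np.random.Generator, n: int) -> list[str]:
    return [AA1[i] for i in rng.integers(0, len(AA1), size=n)]


def synth_pair(
    spec: PathologySpec,
) -> tuple[str, CanonicalSequence, ResidueMapping, QCVerdict]:
    """Generate one fixture: PDB text, canonical sequence, truth mapping
    and the quality verdict the truth mapping implies.

    The truth mapping is exactly what alignment-based mapping must
    recover; sequence content is drawn uniformly under the seed, with
    minimal local constraints that keep the optimal alignment unique
    (e.g. a deleted residue differs from its neighbours).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    lo, hi = spec.resolved_window()
    seq = _draw_sequence(rng, L)
    chain = spec.chain

    # sequence-level adjustments first, so the canonical sequence and all
    # derived dictionaries agree
    if spec.kind == "MISSING_INTERNAL":
        site = spec.resolved_site()
        # the deleted residue must differ from both neighbours so the
        # alignment gap position is unambiguous
        banned = {seq[site - 2], seq[site]}
        if seq[site - 1] in banned:
            choices = [a for a in AA1 if a not in banned]
            seq[site - 1] = choices[int(rng.integers(0, len(choices)))]
    elif spec.kind == "TAG_FLANK" and seq[0] == "H":
        seq[0] = "M"  # a leading His would let the tag slide one position

    positions = list(range(lo, hi + 1))          # canonical, with coords
    letters = {pos: seq[pos - 1] for pos in positions}
    ids: dict[int, ResidueID] = {
        pos: ResidueID(chain, pos) for pos in positions}
    structure_letters: dict[int, str] = dict(letters)
    prefix: list[tuple[ResidueID, str]] = []     # tag residues, in order

    if spec.kind == "INSERTION_CODE":
        site = spec.resolved_site()
        # author numbering: ..., site-1, (site-1)A, site, ... (shift -1
        # after the inserted code, like Gly60 / Cys60A / Phe61)
        ids[site] = ResidueID(chain, site - 1, "A")
        for pos in positions:
            if pos > site:
                ids[pos] = ResidueID(chain, pos - 1)
    elif spec.kind == "CONSTANT_OFFSET":
        for pos in positions:
            ids[pos] = ResidueID(chain, pos - spec.offset)
    elif spec.kind == "INCONSISTENT_OFFSET":
        site = spec.resolved_site()
        if spec.offset2 >= spec.offset:
            raise SpecError(
                "INCONSISTENT_OFFSET needs offset2 < offset so author "
                "numbers jump but stay increasing")
        for pos in positions:
            off = spec.offset if pos < site else spec.offset2
            ids[pos] = ResidueID(chain, pos - off)
    elif spec.kind == "MISSING_INTERNAL":
        positions.remove(site)
        for d in (ids, letters, structure_letters):
            d.pop(site)
    elif spec.kind == "POINT_MUTATION":
        site = spec.resolved_site()
        ref = seq[site - 1]
        choices = [a for a in AA1 if a != ref]
        structure_letters[site] = choices[int(rng.integers(0, len(choices)))]
    elif spec.kind == "TAG_FLANK":
        for k in range(spec.tag_length):
            prefix.append(
                (ResidueID(chain, k - spec.tag_length + 1), "H"))

    acc = f"Q{KINDS.index(spec.kind)}{spec.seed % 10000:04d}"
    canon = CanonicalSequence(acc, "".join(seq))
    file_ids = [rid for rid, _ in prefix] + [ids[p] for p in positions]
    file_letters = "".join(letter for _, letter in prefix) + \
        "".join(structure_letters[p] for p in positions)
    pdb_label = f"S{spec.seed % 1000:03d}"
    structure = synth_structure(file_letters, file_ids, spec.conformation,
                                pdb_id=pdb_label)
    pdb_text = write_structure(structure)

    truth_pairs = [
        MappedPair(ids[p], p, structure_letters[p], letters[p])
        for p in positions
    ]
    covered = set(positions)
    missing = [p for p in range(min(covered), max(covered) + 1)
               if p not in covered]
    truth = ResidueMapping(canon.accession, chain, truth_pairs, missing,
                           float("nan"))
    return pdb_text, canon, truth, qc_evaluate(truth)


def synth_insertion_code_case(seed: int = 0):
    """Synthetic stand-in for the classic alcohol-dehydrogenase
    insertion-code discrepancy (PDB entry 1TEH vs UniProt P11766).

    The canonical sequence carries Gly60, Cys61, Phe62; the structure
    numbers them Gly60, Cys60A, Phe61, so every author number after 60
    is one below its canonical position.  Sequence content away from
    those three residues is random under ``seed``.  Returns
    ``(pdb_text, CanonicalSequence)``.
    """
    rng = np.random.default_rng(seed)
    seq = _draw_sequence(rng, 120)
    seq[59], seq[60], seq[61] = "G", "C", "F"
    lo, hi = 40, 100
    ids = []
    for pos in range(lo, hi + 1):
        if pos < 61:
            ids.append(ResidueID("A", pos))
        elif pos == 61:
            ids.append(ResidueID("A", 60, "A"))
        else:
            ids.append(ResidueID("A", pos - 1))
    s = synth_structure("".join(seq[lo - 1:hi]), ids, pdb_id="ITEH")
    return write_structure(s), CanonicalSequence("QI0001", "".join(seq))


def synth_offset_jump_case(seed: int = 0):
    """Synthetic stand-in for the alcohol-dehydrogenase chain whose
    author numbering jumps mid-chain (PDB entry 1D1S vs UniProt P40394).

    Author numbers run 13 below canonical up to canonical 129 (Ile129 is
    author Ile116) and 12 below from canonical 130 (Thr130 is author
    Thr118), so Thr118 directly follows Ile116 with no residue actually
    missing; canonical Lys238 sits at author residue 226.  Returns
    ``(pdb_text, CanonicalSequence)``.
    """
    rng = np.random.default_rng(seed)
    seq = _draw_sequence(rng, 260)
    seq[128], seq[129], seq[237] = "I", "T", "K"
    lo, hi = 100, 250
    ids = [ResidueID("A", pos - (13 if pos < 130 else 12))
           for pos in range(lo, hi + 1)]
    s = synth_structure("".join(seq[lo - 1:hi]), ids, pdb_id="ID1S")
    return write_structure(s), CanonicalSequence("QJ0001", "".join(seq))


def write_corpus(out_dir: str | Path, seeds: list[int],
                 kinds: tuple[str, ...] = KINDS) -> list[Path]:
    """Emit a fixture corpus: PDB files, a FASTA of canonical sequences
    and truth-mapping TSVs, one trio per (kind, seed)."""
    from .renumber import mapping_to_tsv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    fasta: list[str] = []
    for kind in kinds:
        for seed in seeds:
            spec = PathologySpec(kind=kind, seed=seed)
            pdb_text, canon, truth, verdict = synth_pair(spec)
            stem = f"{kind.lower()}_{seed:04d}"
            p = out_dir / f"{stem}.pdb"
            p.write_text(pdb_text)
            written.append(p)
            t = out_dir / f"{stem}.truth.tsv"
            t.write_text(mapping_to_tsv(truth))
            written.append(t)
            fasta.append(f">sp|{canon.accession}|{stem.upper()}\n"
                         f"{canon.sequence}")
    f = out_dir / "canonical.fasta"
    f.write_text("\n".join(fasta) + "\n")
    written.append(f)
    return written
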