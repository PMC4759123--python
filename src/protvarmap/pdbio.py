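"""Reading and writing PDB-format coordinate files.

The renumbering method downstream depends on details that generic readers
often normalise away: author residue numbers, insertion codes (``Cys60A``),
alternate-location duplicates and chain boundaries.  This module keeps all
of them explicit.  Only the first coordinate model of a multi-model (NMR)
file is retained, and altloc duplicates are reduced to the
highest-occupancy conformer so that every downstream step sees exactly one
copy of each atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ResidueID",
    "Atom",
    "Residue",
    "Structure",
    "ObservedSequence",
    "PDBParseError",
    "PDBWriteError",
    "parse_structure",
    "chain_sequence",
    "write_structure",
    "THREE_TO_ONE",
]

# Standard residues plus MSE (selenomethionine), which substitutes for MET
# in selenomethionine-derivatised crystals and is read as 'M'.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records; names the line number."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be expressed in fixed columns."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """Identity of a residue as printed by the depositor.

    ``(chain, author_number, insertion_code)`` is unique within a
    structure; the insertion code is blank or a single letter A-Z.
    """

    chain: str
    author_number: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.insertion_code and not (
            len(self.insertion_code) == 1 and self.insertion_code.isalpha()
        ):
            raise ValueError(f"bad insertion code {self.insertion_code!r}")

    def __str__(self) -> str:
        return f"{self.chain}{self.author_number}{self.insertion_code}"


@dataclass
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0


@dataclass
class Residue:
    id: ResidueID
    name3: str
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    @property
    def is_water(self) -> bool:
        return self.name3 in _WATER_NAMES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """One coordinate model, residues grouped by chain in file order."""

    pdb_id: str = "XXXX"
    method: str = "OTHER"  # XRAY | NMR | OTHER
    resolution: float | None = None
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    model_number: int = 1

    def residues(self):
        for chain_residues in self.chains.values():
            yield from chain_residues

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def find_residue(self, rid: ResidueID) -> Residue | None:
        for r in self.chains.get(rid.chain, []):
            if r.id == rid:
                return r
        return None

    def copy(self) -> "Structure":
        chains = {
            c: [
                Residue(r.id, r.name3, [replace(a) for a in r.atoms], r.is_hetero)
                for r in rs
            ]
            for c, rs in self.chains.items()
        }
        return Structure(self.pdb_id, self.method, self.resolution, chains,
                         self.model_number)


@dataclass
class ObservedSequence:
    """One-letter sequence read off the polymer ATOM records of a chain."""

    chain: str
    letters: str
    ids: list[ResidueID]

    def __post_init__(self) -> None:
        if len(self.letters) != len(self.ids):
            raise ValueError("letters and ids must be parallel")


def _parse_float(text: str, line_no: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise PDBParseError(
            f"line {line_no}: malformed {what} field {text.strip()!r}"
        ) from None


def parse_structure(text: str, pdb_id: str | None = None) -> Structure:
    """Parse a PDB-format record stream into a :class:`Structure`.

    Only MODEL 1 of a multi-model file is kept.  Altloc duplicates of an
    atom are reduced to the highest-occupancy conformer (ties broken by
    file order).  HETATM residues whose name is in the amino-acid table
    and which lie between ATOM records of the same chain are treated as
    polymer (the MSE case).
    """
    s = Structure(pdb_id=pdb_id or "XXXX")
    residues: list[Residue] = []
    res_index: dict[tuple[ResidueID, str], Residue] = {}
    in_model = 0
    have_atoms = False

    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "HEADER" and pdb_id is None and len(line) >= 66:
            code = line[62:66].strip()
            if len(code) == 4:
                s.pdb_id = code
        elif rec == "EXPDTA":
            tag = line[10:].upper()
            if "X-RAY" in tag:
                s.method = "XRAY"
            elif "NMR" in tag:
                s.method = "NMR"
        elif rec == "REMARK" and line[7:10].strip() == "2":
            tail = line[10:].upper()
            if "RESOLUTION" in tail and "NOT APPLICABLE" not in tail:
                for tok in tail.replace("RESOLUTION.", " ").split():
                    try:
                        s.resolution = float(tok)
                        break
                    except ValueError:
                        continue
        elif rec == "MODEL":
            in_model += 1
        elif rec == "ENDMDL":
            if in_model >= 1:
                break  # keep first model only
        elif rec in ("ATOM", "HETATM"):
            if in_model > 1:
                continue
            if len(line) < 54:
                raise PDBParseError(f"line {line_no}: truncated {rec} record")
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or " "
            try:
                resseq = int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"line {line_no}: malformed residue number "
                    f"{line[22:26].strip()!r}"
                ) from None
            icode = line[26].strip()
            x = _parse_float(line[30:38], line_no, "x coordinate")
            y = _parse_float(line[38:46], line_no, "y coordinate")
            z = _parse_float(line[46:54], line_no, "z coordinate")
            occ = _parse_float(line[54:60], line_no, "occupancy") \
                if line[54:60].strip() else 1.0
            bf = _parse_float(line[60:66], line_no, "B-factor") \
                if line[60:66].strip() else 0.0
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = name[:1] if name[:1].isalpha() else name[1:2]
            rid = ResidueID(chain, resseq, icode)
            key = (rid, resname)
            residue = res_index.get(key)
            if residue is None:
                residue = Residue(rid, resname, [], is_hetero=(rec == "HETATM"))
                res_index[key] = residue
                residues.append(residue)
            atom = Atom(name, element, (x, y, z), occ, altloc, bf)
            existing = residue.atom(name)
            if existing is None:
                residue.atoms.append(atom)
            elif atom.occupancy > existing.occupancy:
                # altloc reduction: highest occupancy wins, ties keep the
                # earlier conformer
                residue.atoms[residue.atoms.index(existing)] = atom
            have_atoms = True

    if not have_atoms:
        raise PDBParseError("no ATOM/HETATM records: empty structure")

    for r in residues:
        s.chains.setdefault(r.id.chain, []).append(r)
    return s


def _polymer_flags(chain_residues: list[Residue]) -> list[bool]:
    """Which residues of a chain count as polymer.

    ATOM residues are polymer.  A HETATM residue is polymer if its name
    translates to an amino acid and it lies between ATOM residues of the
    same chain in file order (the in-chain MSE case); terminal HETATMs and
    ligands are not.
    """
    atom_positions = [i for i, r in enumerate(chain_residues)
                      if not r.is_hetero]
    if not atom_positions:
        return [False] * len(chain_residues)
    lo, hi = atom_positions[0], atom_positions[-1]
    return [
        (not r.is_hetero)
        or (r.name3 in THREE_TO_ONE and lo < i < hi)
        for i, r in enumerate(chain_residues)
    ]


def chain_sequence(s: Structure, chain: str) -> ObservedSequence:
    """Sequence observed in the coordinates of one chain.

    One letter per polymer residue in file order; unknown residue names
    become ``X``; waters and non-polymer ligands are excluded.
    """
    if chain not in s.chains:
        raise KeyError(f"no chain {chain!r} in structure {s.pdb_id}")
    letters: list[str] = []
    ids: list[ResidueID] = []
    flags = _polymer_flags(s.chains[chain])
    for r, polymer in zip(s.chains[chain], flags):
        if r.is_water or not polymer:
            continue
        letters.append(r.one_letter)
        ids.append(r.id)
    return ObservedSequence(chain, "".join(letters), ids)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(s: Structure) -> str:
    """Serialise to fixed-column PDB text.

    Atom serials are re-sequenced from 1; coordinates are printed to three
    decimals; a TER record follows each chain.  The output round-trips
    through :func:`parse_structure`.
    """
    if not any(True for _ in s.residues()):
        raise PDBWriteError("empty structure")
    lines: list[str] = []
    if s.pdb_id and s.pdb_id != "XXXX":
        lines.append(f"HEADER    PROTEIN{'':33s}{'':12s}{s.pdb_id:>4s}")
    if s.method == "XRAY":
        lines.append("EXPDTA    X-RAY DIFFRACTION")
    elif s.method == "NMR":
        lines.append("EXPDTA    SOLUTION NMR")
    if s.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {s.resolution:7.2f} ANGSTROMS."
        )
    serial = 1
    for chain_id, chain_residues in s.chains.items():
        last = None
        for r in chain_residues:
            if not (-999 <= r.id.author_number <= 9999):
                raise PDBWriteError(
                    f"residue number {r.id.author_number} does not fit the "
                    "4-column field"
                )
            rec = "HETATM" if r.is_hetero else "ATOM  "
            for a in r.atoms:
                x, y, z = a.xyz
                lines.append(
                    f"{rec}{serial:5d} {_format_atom_name(a.name, a.element)}"
                    f"{a.altloc or ' '}{r.name3:>3s} {chain_id}"
                    f"{r.id.author_number:4d}{r.id.insertion_code or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                    f"{a.bfactor:6.2f}          {a.element:>2s}"
                )
                serial += 1
            last = r
        if last is not None:
            lines.append(
                f"TER   {serial:5d}      {last.name3:>3s} {chain_id}"
                f"{last.id.author_number:4d}{last.id.insertion_code or ' '}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
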