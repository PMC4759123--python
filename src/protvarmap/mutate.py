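"""Side-chain-only mutant model building.

A missense model is the wild-type structure with exactly one residue's
side chain replaced: backbone atoms N, CA, C, O keep bit-identical
coordinates (and the original CB is retained when both residues have
one), the remaining side-chain atoms are deleted and rebuilt with
idealised internal-coordinate geometry placed NeRF-style from the
backbone frame.  No other residue is touched and no refinement is done;
steric clashes with the environment are counted and reported, not fixed.

Side-chain conformation comes from a deterministic chi policy: by default
the most common backbone-independent rotamer per residue type (shipped in
the template data file), with 180 degrees for any unlisted chi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .geometry import GeometryError, place_atom
from .pdbio import Atom, Residue, ResidueID, Structure
from .variants import MissenseVariant, ONE_TO_THREE

__all__ = [
    "SideChainTemplate",
    "TemplateAtom",
    "MutantModel",
    "CannotBuildError",
    "load_templates",
    "build_sidechain",
    "mutate_residue",
    "model_filename",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class CannotBuildError(ValueError):
    """The residue lacks the frame atoms or no template exists."""


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    refs: tuple[str, str, str]  # great-grandparent, grandparent, parent
    bond: float
    angle: float
    torsion: str  # literal degrees, "chiK", or "chiK+offset"


@dataclass(frozen=True)
class SideChainTemplate:
    name3: str
    atoms: tuple[TemplateAtom, ...]
    chi_defaults: tuple[float, ...]

    @property
    def n_chi(self) -> int:
        n = 0
        for a in self.atoms:
            if a.torsion.startswith("chi"):
                n = max(n, int(a.torsion[3]))
        return n


@lru_cache(maxsize=1)
def load_templates() -> dict[str, SideChainTemplate]:
    """Parse the shipped internal-coordinate template file."""
    text = resources.files("protvarmap.data") \
        .joinpath("sidechain_templates.dat").read_text()
    out: dict[str, SideChainTemplate] = {}
    name = None
    atoms: list[TemplateAtom] = []
    chis: tuple[float, ...] = ()

    def flush():
        if name is not None:
            out[name] = SideChainTemplate(name, tuple(atoms), chis)

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "RESIDUE":
            flush()
            name, atoms, chis = fields[1], [], ()
        elif fields[0] == "CHI":
            chis = tuple(float(v) for v in fields[1:])
        elif fields[0] == "ATOM":
            atoms.append(TemplateAtom(
                fields[1], fields[2], (fields[3], fields[4], fields[5]),
                float(fields[6]), float(fields[7]), fields[8]))
    flush()
    return out


def _resolve_torsion(spec: str, chi: Sequence[float]) -> float:
    if not spec.startswith("chi"):
        return float(spec)
    k = int(spec[3])
    base = chi[k - 1]
    if len(spec) > 4:
        base += float(spec[4:])
    return base


def _resolve_chis(t: SideChainTemplate,
                  chi_policy: Sequence[float] | Mapping[int, float] | None,
                  ) -> list[float]:
    chi = list(t.chi_defaults) + [180.0] * (t.n_chi - len(t.chi_defaults))
    if chi_policy is None:
        return chi
    if isinstance(chi_policy, Mapping):
        for k, v in chi_policy.items():
            if 1 <= k <= len(chi):
                chi[k - 1] = float(v)
        return chi
    for k, v in enumerate(chi_policy[:len(chi)]):
        chi[k] = float(v)
    return chi


def build_sidechain(
    t: SideChainTemplate,
    frame: Mapping[str, Sequence[float]],
    chi_policy: Sequence[float] | Mapping[int, float] | None = None,
) -> list[Atom]:
    """Construct side-chain atoms from the backbone frame.

    ``frame`` must supply N, CA and C coordinates; if it also supplies CB,
    that position is kept verbatim and the rest of the side chain grows
    outward from it.  Placement is sequential internal-coordinate (NeRF)
    construction and fully deterministic for a fixed chi policy.
    """
    for need in ("N", "CA", "C"):
        if need not in frame:
            raise CannotBuildError(f"frame atom {need} missing")
    coords: dict[str, np.ndarray] = {
        k: np.asarray(v, dtype=float) for k, v in frame.items()
    }
    chi = _resolve_chis(t, chi_policy)
    out: list[Atom] = []
    for ta in t.atoms:
        if ta.name in coords:  # retained original CB
            pos = coords[ta.name]
        else:
            a, b, c = (coords[r] for r in ta.refs)
            tor = _resolve_torsion(ta.torsion, chi)
            pos = place_atom(a, b, c, ta.bond, ta.angle, tor)
            coords[ta.name] = pos
        out.append(Atom(ta.name, ta.element, tuple(float(x) for x in pos)))
    return out


def model_filename(accession: str, pdb_id: str, chain: str, rs_id: str,
                   wt3: str, position: int, mut3: str) -> str:
    """Canonical model file name, e.g.
    ``P00750_1PML_A_183443805_ARG_224_CYS.pdb``."""
    return (f"{accession}_{pdb_id}_{chain}_{rs_id}_{wt3}_{position}_"
            f"{mut3}.pdb")


@dataclass
class MutantModel:
    """A structure with exactly one rebuilt side chain, plus provenance."""

    structure: Structure
    template_pdb: str
    chain: str
    position: int
    wt_name3: str
    mut_name3: str
    variant: MissenseVariant | None = None
    clash_count: int = 0
    identical: bool = False

    @property
    def filename(self) -> str | None:
        if self.variant is None:
            return None
        return model_filename(
            self.variant.accession, self.template_pdb, self.chain,
            self.variant.rs_id, self.wt_name3, self.position,
            self.mut_name3)


_CLASH_CUTOFF = 2.0  # Angstrom, heavy-atom environment contact


def _count_clashes(s: Structure, target: Residue,
                   new_atoms: list[Atom]) -> int:
    if not new_atoms:
        return 0
    env = []
    for r in s.residues():
        if r is target:
            continue
        env.extend(a.xyz for a in r.atoms if not a.name.startswith("H"))
    if not env:
        return 0
    env = np.asarray(env)
    new = np.asarray([a.xyz for a in new_atoms if a.name != "CB"])
    if new.size == 0:
        return 0
    d = np.linalg.norm(env[None, :, :] - new[:, None, :], axis=-1)
    return int((d < _CLASH_CUTOFF).sum())


def mutate_residue(
    s: Structure,
    chain: str,
    position: int,
    alt_aa: str,
    chi_policy: Sequence[float] | Mapping[int, float] | None = None,
    variant: MissenseVariant | None = None,
) -> MutantModel:
    """Build a mutant model of residue ``(chain, position)``.

    ``alt_aa`` may be a one- or three-letter code.  The residue must be a
    standard amino acid with an intact N/CA/C frame.  Everything outside
    the mutated side chain is byte-identical on write; hydrogens of the
    mutated residue are dropped (models are heavy-atom only at the site).
    """
    templates = load_templates()
    mut3 = ONE_TO_THREE.get(alt_aa, alt_aa).upper()
    if mut3 not in templates:
        raise CannotBuildError(f"no template for residue {alt_aa!r}")
    residue = s.find_residue(ResidueID(chain, position))
    if residue is None:
        raise KeyError(f"no residue {chain}{position} in {s.pdb_id}")
    wt3 = residue.name3
    if wt3 not in templates and wt3 != "MSE":
        raise CannotBuildError(f"{wt3} is not a standard amino acid")

    out = s.copy()
    new_res = out.find_residue(ResidueID(chain, position))

    if mut3 == wt3:
        warnings.warn(f"target {mut3} equals current residue at "
                      f"{chain}{position}; returning identity model")
        return MutantModel(out, s.pdb_id, chain, position, wt3, mut3,
                           variant, 0, identical=True)

    frame: dict[str, tuple[float, float, float]] = {}
    for name in ("N", "CA", "C"):
        a = new_res.atom(name)
        if a is None:
            raise CannotBuildError(
                f"residue {chain}{position} lacks backbone atom {name}")
        frame[name] = a.xyz

    template = templates[mut3]
    wt_has_cb = new_res.atom("CB") is not None
    mut_has_cb = any(ta.name == "CB" for ta in template.atoms)
    if wt_has_cb and mut_has_cb:
        frame["CB"] = new_res.atom("CB").xyz

    kept = [a for a in new_res.atoms if a.name in BACKBONE_ATOMS]
    built = build_sidechain(template, frame, chi_policy)
    new_res.atoms = kept + built
    new_res.name3 = mut3
    new_res.is_hetero = False

    clashes = _count_clashes(out, new_res, built)
    return MutantModel(out, s.pdb_id, chain, position, wt3, mut3,
                       variant, clashes)
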