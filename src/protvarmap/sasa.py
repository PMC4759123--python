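"""Solvent accessible surface area by the Shrake-Rupley method.

Each heavy atom's sphere is expanded by the probe radius (1.4 Angstrom
water by default) and sampled with a deterministic Fibonacci-spiral point
set; the accessible fraction is the fraction of points inside no
neighbouring expanded sphere, scaled by the expanded sphere's area.
Radii follow a NACCESS-style per-element set shipped as data.

Relative accessibility divides a residue's absolute area by the area the
same residue type exposes in a fully extended Gly-X-Gly tripeptide built
with this package's own backbone generator and side-chain templates
(reference values shipped as data), so a value near 1 means "as exposed
as in the reference tripeptide".

Hydrogens are ignored throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .pdbio import ResidueID, Structure

__all__ = [
    "SASAParams",
    "SASAReport",
    "SASADelta",
    "RadiusError",
    "compute_sasa",
    "compare_sasa",
    "fibonacci_sphere",
    "load_radii",
    "load_gxg_reference",
]


class RadiusError(KeyError):
    """An atom's element has no van der Waals radius."""


@lru_cache(maxsize=4)
def load_radii(name: str = "vdw_radii.dat") -> dict[str, float]:
    text = resources.files("protvarmap.data").joinpath(name).read_text()
    out: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, r = line.split()
        out[el.upper()] = float(r)
    return out


@lru_cache(maxsize=4)
def load_gxg_reference(name: str = "gxg_reference.tsv") -> dict[str, float]:
    """Fully exposed per-residue reference areas (Angstrom^2)."""
    path = resources.files("protvarmap.data").joinpath(name)
    if not path.is_file():
        return {}
    text = path.read_text()
    out: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name3"):
            continue
        name3, area = line.split()
        out[name3] = float(area)
    return out


@dataclass(frozen=True)
class SASAParams:
    probe_radius: float = 1.4
    n_points: int = 960
    radius_set: str = "vdw_radii.dat"
    radius_overrides: tuple[tuple[str, float], ...] = ()
    include_waters: bool = False
    include_hetero: bool = True

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_points < 32:
            raise ValueError("need at least 32 quadrature points")

    def radius_for(self, element: str) -> float:
        el = element.upper()
        for k, v in self.radius_overrides:
            if k.upper() == el:
                return v
        radii = load_radii(self.radius_set)
        if el not in radii:
            raise RadiusError(
                f"no van der Waals radius for element {element!r}")
        return radii[el]


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * k
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SASAReport:
    """Per-atom and per-residue accessible areas for one structure."""

    per_atom: dict[tuple[ResidueID, str], float]
    per_residue_abs: dict[ResidueID, float]
    per_residue_rel: dict[ResidueID, float | None]
    residue_names: dict[ResidueID, str]
    total: float

    def to_tsv(self) -> str:
        lines = ["chain\tposition\tinsertion_code\tname3\tabs_area\trel"]
        for rid, area in self.per_residue_abs.items():
            rel = self.per_residue_rel.get(rid)
            rel_s = f"{rel:.4f}" if rel is not None else "NA"
            lines.append(
                f"{rid.chain}\t{rid.author_number}\t{rid.insertion_code}"
                f"\t{self.residue_names[rid]}\t{area:.2f}\t{rel_s}")
        return "\n".join(lines) + "\n"


def compute_sasa(s: Structure, p: SASAParams | None = None) -> SASAReport:
    """Shrake-Rupley SASA of every included heavy atom of ``s``.

    Deterministic for a fixed point count.  Waters are excluded by
    default; hetero residues (ligands, nucleic acids) are included by
    default so the environment of a mutation keeps its interacting
    molecules.
    """
    if p is None:
        p = SASAParams()
    atoms: list[tuple[ResidueID, str, str]] = []  # rid, atom name, name3
    coords: list[tuple[float, float, float]] = []
    radii: list[float] = []
    for r in s.residues():
        if r.is_water and not p.include_waters:
            continue
        if r.is_hetero and not p.include_hetero and r.name3 != "MSE":
            continue
        for a in r.atoms:
            if a.element.upper() == "H" or a.element.upper() == "D":
                continue
            atoms.append((r.id, a.name, r.name3))
            coords.append(a.xyz)
            radii.append(p.radius_for(a.element))
    if not atoms:
        raise ValueError("structure has no heavy atom to analyse")

    xyz = np.asarray(coords)
    rad = np.asarray(radii) + p.probe_radius
    sphere = fibonacci_sphere(p.n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * rad.max()
    per_atom_area = np.zeros(len(atoms))
    neighbor_lists = tree.query_ball_point(xyz, r=max_reach)
    for i in range(len(atoms)):
        pts = xyz[i] + rad[i] * sphere
        accessible = np.ones(p.n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            accessible &= d2 > rad[j] ** 2
            if not accessible.any():
                break
        frac = accessible.sum() / p.n_points
        per_atom_area[i] = frac * 4.0 * np.pi * rad[i] ** 2

    per_atom: dict[tuple[ResidueID, str], float] = {}
    per_res: dict[ResidueID, float] = {}
    names: dict[ResidueID, str] = {}
    for (rid, aname, name3), area in zip(atoms, per_atom_area):
        per_atom[(rid, aname)] = float(area)
        per_res[rid] = per_res.get(rid, 0.0) + float(area)
        names[rid] = name3
    reference = load_gxg_reference()
    per_rel: dict[ResidueID, float | None] = {}
    for rid, area in per_res.items():
        ref = reference.get("MET" if names[rid] == "MSE" else names[rid])
        per_rel[rid] = (area / ref) if ref else None
    return SASAReport(per_atom, per_res, per_rel, names,
                      float(per_atom_area.sum()))


@dataclass
class SASADelta:
    """Mutant-minus-wild-type accessibility differences."""

    per_residue: dict[ResidueID, float]
    total: float

    def to_tsv(self) -> str:
        lines = ["chain\tposition\tinsertion_code\tdelta_abs"]
        for rid, d in self.per_residue.items():
            lines.append(f"{rid.chain}\t{rid.author_number}\t"
                         f"{rid.insertion_code}\t{d:.2f}")
        return "\n".join(lines) + "\n"


def compare_sasa(wt: SASAReport, mut: SASAReport) -> SASADelta:
    """Per-residue and total SASA deltas (mutant minus wild type).

    Both reports must cover the same residue identifiers (a side-chain-
    only mutant keeps its residue numbering, so this holds whenever the
    inputs belong together).
    """
    wt_ids, mut_ids = set(wt.per_residue_abs), set(mut.per_residue_abs)
    if wt_ids != mut_ids:
        diff = sorted(str(r) for r in wt_ids ^ mut_ids)
        raise ValueError(f"residue sets differ: {diff}")
    per = {rid: mut.per_residue_abs[rid] - wt.per_residue_abs[rid]
           for rid in wt.per_residue_abs}
    return SASADelta(per, mut.total - wt.total)
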