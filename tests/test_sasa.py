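"""Solvent accessibility: analytic references, invariances, comparison."""

import numpy as np
import pytest

from protvarmap.fixtures import synth_structure
from protvarmap.mutate import mutate_residue
from protvarmap.pdbio import Atom, Residue, ResidueID, Structure
from protvarmap.sasa import (RadiusError, SASAParams, compare_sasa,
                             compute_sasa, fibonacci_sphere,
                             load_gxg_reference)
from protvarmap.variants import AA1, ONE_TO_THREE

from _oracles import two_sphere_sasa
from conftest import make_ids


def atom_structure(entries):
    """entries: list of (element, xyz)."""
    residues = [
        Residue(ResidueID("A", i + 1), "LIG",
                [Atom(f"{el}1", el, xyz)], is_hetero=True)
        for i, (el, xyz) in enumerate(entries)
    ]
    return Structure(chains={"A": residues})


class TestAnalyticReferences:
    def test_isolated_sphere(self):
        rep = compute_sasa(atom_structure([("C", (0, 0, 0))]))
        analytic = 4 * np.pi * (1.87 + 1.4) ** 2
        assert rep.total == pytest.approx(analytic, rel=0.01)

    def test_distant_pair_additivity(self):
        one = compute_sasa(atom_structure([("C", (0, 0, 0))])).total
        two = compute_sasa(atom_structure(
            [("C", (0, 0, 0)), ("C", (100, 0, 0))])).total
        assert two == pytest.approx(2 * one, abs=1e-9)

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 6.0])
    def test_two_sphere_overlap_closed_form(self, d):
        rep = compute_sasa(atom_structure(
            [("C", (0, 0, 0)), ("N", (d, 0, 0))]))
        analytic = two_sphere_sasa(1.87 + 1.4, 1.65 + 1.4, d)
        assert rep.total == pytest.approx(analytic, rel=0.01)

    def test_buried_atom_zero(self):
        shell = fibonacci_sphere(60) * 2.2
        entries = [("C", (0.0, 0.0, 0.0))] + \
            [("C", tuple(p)) for p in shell]
        rep = compute_sasa(atom_structure(entries))
        center = rep.per_atom[(ResidueID("A", 1), "C1")]
        assert center == 0.0


class TestInvariances:
    def test_rigid_motion_invariance(self, small_structure):
        # orientation dependence of the spiral quadrature shrinks with
        # point count; at 61440 points totals agree to 0.1%
        p = SASAParams(n_points=61440)
        base = compute_sasa(small_structure, p).total
        moved = small_structure.copy()
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        for r in moved.residues():
            for a in r.atoms:
                a.xyz = tuple(R @ np.array(a.xyz) + np.array([5, -3, 2.5]))
        assert compute_sasa(moved, p).total == pytest.approx(base,
                                                             rel=0.001)

    def test_quadrature_convergence(self, small_structure):
        lo = compute_sasa(small_structure, SASAParams(n_points=960))
        hi = compute_sasa(small_structure, SASAParams(n_points=3840))
        assert abs(lo.total - hi.total) / hi.total < 0.005

    def test_totals_are_sums(self, small_structure):
        rep = compute_sasa(small_structure)
        assert rep.total == pytest.approx(sum(rep.per_atom.values()))
        assert rep.total == pytest.approx(
            sum(rep.per_residue_abs.values()))

    def test_waters_excluded_hetero_included_by_default(self,
                                                        small_structure):
        s = small_structure.copy()
        s.chains["A"].append(Residue(
            ResidueID("A", 500), "HOH",
            [Atom("O", "O", (50.0, 0.0, 0.0))], is_hetero=True))
        s.chains["A"].append(Residue(
            ResidueID("A", 600), "LIG",
            [Atom("C1", "C", (60.0, 0.0, 0.0))], is_hetero=True))
        rep = compute_sasa(s)
        ids = {rid for rid in rep.per_residue_abs}
        assert ResidueID("A", 500) not in ids
        assert ResidueID("A", 600) in ids

    def test_unknown_element_raises(self):
        with pytest.raises(RadiusError):
            compute_sasa(atom_structure([("ZZ", (0, 0, 0))]))

    def test_radius_override(self):
        rep = compute_sasa(
            atom_structure([("ZZ", (0, 0, 0))]),
            SASAParams(radius_overrides=(("ZZ", 2.0),)))
        assert rep.total == pytest.approx(4 * np.pi * 3.4 ** 2, rel=0.01)


class TestRelativeAccessibility:
    def test_gxg_central_residue_fully_exposed(self):
        """In the reference conformation every residue type's central
        tripeptide residue has relative accessibility ~1 by construction."""
        for x in sorted(AA1):
            s = synth_structure(f"G{x}G", make_ids("A", (1, 2, 3)))
            rep = compute_sasa(s)
            rel = rep.per_residue_rel[ResidueID("A", 2)]
            assert rel == pytest.approx(1.0, abs=0.05), x

    def test_reference_table_complete(self):
        ref = load_gxg_reference()
        assert {ONE_TO_THREE[a] for a in AA1} <= set(ref)

    def test_interior_residues_not_overexposed(self, small_structure):
        """Chain-interior residues cannot exceed their tripeptide
        reference by more than quadrature noise; termini may, because
        the reference residue has neighbours on both sides."""
        rep = compute_sasa(small_structure)
        for rid, rel in rep.per_residue_rel.items():
            assert rel is not None and rel >= 0.0
            if 3 <= rid.author_number <= 8:
                assert rel <= 1.05


class TestCompare:
    def test_identical_structures_zero_delta(self, small_structure):
        rep = compute_sasa(small_structure)
        delta = compare_sasa(rep, rep)
        assert delta.total == 0.0
        assert all(v == 0.0 for v in delta.per_residue.values())

    def test_total_is_sum_of_residue_deltas(self, small_structure):
        model = mutate_residue(small_structure, "A", 8, "A")  # W -> A
        delta = compare_sasa(compute_sasa(small_structure),
                             compute_sasa(model.structure))
        assert delta.total == pytest.approx(
            sum(delta.per_residue.values()))

    def test_shrinking_mutation_reduces_site_area(self, small_structure):
        model = mutate_residue(small_structure, "A", 8, "G")  # W -> G
        delta = compare_sasa(compute_sasa(small_structure),
                             compute_sasa(model.structure))
        assert delta.per_residue[ResidueID("A", 8)] < 0
        # the mutation site is always present in the output
        assert ResidueID("A", 8) in delta.per_residue

    def test_mismatched_residue_sets_rejected(self, small_structure):
        rep = compute_sasa(small_structure)
        shorter = small_structure.copy()
        shorter.chains["A"] = shorter.chains["A"][:-1]
        with pytest.raises(ValueError, match="A10"):
            compare_sasa(rep, compute_sasa(shorter))


def test_agrees_with_independent_shrake_rupley(tmp_path, small_structure):
    """Biopython's Shrake-Rupley with matched radii agrees on the total
    within 2%."""
    Bio = pytest.importorskip("Bio.PDB")
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley
    from protvarmap.pdbio import write_structure

    path = tmp_path / "s.pdb"
    path.write_text(write_structure(small_structure))
    bp = PDBParser(QUIET=True).get_structure("s", str(path))
    sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                      radii_dict={"C": 1.87, "N": 1.65, "O": 1.40,
                                  "S": 1.85})
    sr.compute(bp, level="S")
    theirs = sum(a.sasa for a in bp.get_atoms())
    mine = compute_sasa(small_structure).total
    assert mine == pytest.approx(theirs, rel=0.02)
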