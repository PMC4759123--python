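"""Mapping derivation, quality control and renumbering application."""

import numpy as np
import pytest

from protvarmap.fixtures import (KINDS, PathologySpec, synth_pair,
                                 synth_structure)
from protvarmap.pdbio import (ObservedSequence, ResidueID, chain_sequence,
                              parse_structure, write_structure)
from protvarmap.renumber import (CanonicalSequence, QCError,
                                 RenumberingConflictError, apply_renumbering,
                                 build_mapping, mapping_to_tsv, qc_evaluate,
                                 read_canonical_fasta)

from conftest import make_ids, random_sequence


def observed(chain, letters, ids):
    return ObservedSequence(chain, letters, ids)


def canonical_with(rng, length, forced: dict[int, str]):
    seq = list(random_sequence(rng, length))
    for pos, aa in forced.items():
        seq[pos - 1] = aa
    return CanonicalSequence("P99999", "".join(seq))


class TestBuildMapping:
    def test_insertion_code_shift(self, rng):
        """A Gly60/Cys60A/Phe61 chain maps 60A to canonical 61 and 61 to
        62, the alcohol-dehydrogenase numbering repair."""
        canon = canonical_with(rng, 80, {60: "G", 61: "C", 62: "F"})
        letters = canon.sequence[39:70]  # canonical 40..70 observed
        ids = []
        for pos in range(40, 71):
            if pos < 61:
                ids.append(ResidueID("A", pos))
            elif pos == 61:
                ids.append(ResidueID("A", 60, "A"))
            else:
                ids.append(ResidueID("A", pos - 1))
        m = build_mapping(observed("A", letters, ids), canon)
        by_id = {p.residue: p.canonical_position for p in m.pairs}
        assert by_id[ResidueID("A", 60, "A")] == 61
        assert by_id[ResidueID("A", 61)] == 62
        assert not m.mismatches and not m.missing_internal

    def test_identity_mapping(self, rng):
        canon = canonical_with(rng, 50, {})
        ids = make_ids("A", range(1, 51))
        m = build_mapping(observed("A", canon.sequence, ids), canon)
        assert all(p.offset == 0 for p in m.pairs)
        assert len(m.pairs) == 50

    def test_constant_offset_of_12(self, rng):
        canon = canonical_with(rng, 60, {})
        ids = make_ids("A", range(10 - 12, 50 - 12))
        m = build_mapping(
            observed("A", canon.sequence[9:49], ids), canon)
        assert set(m.offsets) == {12}

    def test_engineered_substitution_listed_as_mismatch(self, rng):
        canon = canonical_with(rng, 40, {20: "A"})
        letters = list(canon.sequence)
        letters[19] = "S"
        m = build_mapping(
            observed("A", "".join(letters), make_ids("A", range(1, 41))),
            canon)
        assert [(p.canonical_position, p.pdb_aa, p.canonical_aa)
                for p in m.mismatches] == [(20, "S", "A")]


class TestQC:
    def test_clean_long_mapping_accepted(self, rng):
        canon = canonical_with(rng, 50, {})
        m = build_mapping(
            observed("A", canon.sequence, make_ids("A", range(1, 51))),
            canon)
        assert qc_evaluate(m).accepted

    @pytest.mark.parametrize("n,accepted", [(20, False), (21, True)])
    def test_short_range_boundary(self, rng, n, accepted):
        """'More than 20 residues' is strict: 20 rejected, 21 accepted."""
        canon = canonical_with(rng, 40, {})
        m = build_mapping(
            observed("A", canon.sequence[:n], make_ids("A",
                                                       range(1, n + 1))),
            canon)
        verdict = qc_evaluate(m)
        assert verdict.accepted == accepted
        if not accepted:
            assert verdict.reasons == {"SHORT_RANGE"}

    def test_missing_internal_rejected(self):
        spec = PathologySpec("MISSING_INTERNAL", seed=5)
        pdb_text, canon, truth, _ = synth_pair(spec)
        s = parse_structure(pdb_text)
        m = build_mapping(chain_sequence(s, "A"), canon)
        verdict = qc_evaluate(m)
        assert not verdict.accepted
        assert verdict.reasons == {"MISSING_RESIDUE"}


class TestApplyRenumbering:
    def test_insertion_code_case_renumbers_to_canonical(self, rng):
        canon = canonical_with(rng, 80, {60: "G", 61: "C", 62: "F"})
        ids = []
        for pos in range(40, 71):
            if pos < 61:
                ids.append(ResidueID("A", pos))
            elif pos == 61:
                ids.append(ResidueID("A", 60, "A"))
            else:
                ids.append(ResidueID("A", pos - 1))
        s = synth_structure(canon.sequence[39:70], ids)
        m = build_mapping(chain_sequence(s, "A"), canon)
        out, prov = apply_renumbering(s, m)
        numbers = [r.id.author_number for r in out.chains["A"]]
        assert numbers == list(range(40, 71))
        assert all(r.id.insertion_code == "" for r in out.chains["A"])

    def test_identity_and_coordinates_unchanged(self, rng):
        canon = canonical_with(rng, 40, {})
        s = synth_structure(canon.sequence[4:34],
                            make_ids("A", range(5, 35)))
        m = build_mapping(chain_sequence(s, "A"), canon)
        out, _ = apply_renumbering(s, m)
        for a, b in zip(s.residues(), out.residues()):
            assert a.id == b.id and a.name3 == b.name3
            for x, y in zip(a.atoms, b.atoms):
                assert x.xyz == y.xyz

    def test_qc_failure_blocks_unless_forced(self, rng):
        canon = canonical_with(rng, 40, {})
        s = synth_structure(canon.sequence[:15], make_ids("A",
                                                          range(1, 16)))
        m = build_mapping(chain_sequence(s, "A"), canon)
        with pytest.raises(QCError):
            apply_renumbering(s, m)
        out, _ = apply_renumbering(s, m, force=True)
        assert [r.id.author_number for r in out.chains["A"]] == \
            list(range(1, 16))

    def test_flank_extrapolation_flagged(self):
        pdb_text, canon, truth, _ = synth_pair(
            PathologySpec("TAG_FLANK", seed=3))
        s = parse_structure(pdb_text)
        m = build_mapping(chain_sequence(s, "A"), canon)
        out, prov = apply_renumbering(s, m)
        assert len(prov.extrapolated) == 6
        numbers = [r.id.author_number for r in out.chains["A"]]
        assert numbers == list(range(1 - 6, canon.sequence.__len__() + 1))

    def test_idempotence(self):
        pdb_text, canon, truth, _ = synth_pair(
            PathologySpec("INSERTION_CODE", seed=11))
        s = parse_structure(pdb_text)
        m = build_mapping(chain_sequence(s, "A"), canon)
        once, _ = apply_renumbering(s, m)
        m2 = build_mapping(chain_sequence(once, "A"), canon)
        assert all(p.offset == 0 for p in m2.pairs)
        twice, _ = apply_renumbering(once, m2)
        assert write_structure(once) == write_structure(twice)


class TestTruthRecovery:
    @pytest.mark.parametrize("kind", KINDS)
    def test_generator_analyzer_closure(self, kind):
        """Alignment-based mapping recovers the generator's ground truth
        for every pathology kind across seeds."""
        for seed in range(25):
            pdb_text, canon, truth, truth_verdict = synth_pair(
                PathologySpec(kind, seed=seed))
            s = parse_structure(pdb_text)
            m = build_mapping(chain_sequence(s, "A"), canon)
            assert [(p.residue, p.canonical_position, p.pdb_aa,
                     p.canonical_aa) for p in m.pairs] == \
                [(p.residue, p.canonical_position, p.pdb_aa,
                  p.canonical_aa) for p in truth.pairs]
            assert m.missing_internal == truth.missing_internal
            assert qc_evaluate(m).reasons == truth_verdict.reasons


class TestIO:
    def test_fasta_uniprot_dialect(self, tmp_path):
        f = tmp_path / "c.fasta"
        f.write_text(">sp|P11766|ADHX_HUMAN Alcohol dehydrogenase\n"
                     "MANEVIKCKAAVAW\n>plain_acc\nGGGG\n")
        canons = read_canonical_fasta(f)
        assert canons["P11766"].sequence == "MANEVIKCKAAVAW"
        assert "plain_acc" in canons

    def test_mapping_tsv_round_numbers(self, rng):
        canon = canonical_with(rng, 30, {})
        m = build_mapping(
            observed("A", canon.sequence, make_ids("A", range(1, 31))),
            canon)
        tsv = mapping_to_tsv(m)
        lines = tsv.strip().splitlines()
        assert lines[0].split("\t") == [
            "chain", "author_number", "insertion_code",
            "canonical_position", "pdb_aa", "canonical_aa", "offset"]
        assert len(lines) == 31
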