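import pytest

from ssfe.alignment import MultipleAlignment
from ssfe.pocket import (
    PocketFingerprint,
    build_position_map,
    detect_disruption,
    extract_fingerprint,
    fingerprint_distance,
    pocket_from_structure,
)
from ssfe.synth import make_toy_structure


def msa_with_reference(annotation, member_rows):
    """Gap-free reference row plus explicit member rows."""
    return MultipleAlignment([(annotation.ref_id, annotation.ref_sequence)] + member_rows)


class TestPositionMap:
    def test_identity_map_for_identical_member(self, annotation):
        msa = msa_with_reference(annotation, [("m", annotation.ref_sequence)])
        pm = build_position_map(msa, annotation.ref_id, "m")
        assert all(pm[i] == i for i in range(1, len(annotation.ref_sequence) + 1))

    def test_deletion_marks_unaligned_and_shifts(self):
        msa = MultipleAlignment([("ref", "ACDEFGHIKL"), ("m", "ACDE--HIKL")])
        pm = build_position_map(msa, "ref", "m")
        assert pm[5] is None and pm[6] is None
        assert pm[7] == 5

    def test_insertion_shifts_member_positions(self):
        msa = MultipleAlignment([("ref", "ACDE---FGHIKL"), ("m", "ACDEWWWFGHIKL")])
        pm = build_position_map(msa, "ref", "m")
        assert [pm[i] for i in range(1, 5)] == [1, 2, 3, 4]
        assert pm[5] == 8

    def test_missing_id_is_an_error(self, annotation):
        msa = msa_with_reference(annotation, [])
        with pytest.raises(KeyError):
            build_position_map(msa, annotation.ref_id, "ghost")

    def test_mapped_positions_strictly_increasing(self, annotation):
        msa = MultipleAlignment([("ref", "ACD-EFG"), ("m", "AC-WEF-")])
        pm = build_position_map(msa, "ref", "m")
        mapped = [v for v in pm.mapping.values() if v is not None]
        assert mapped == sorted(mapped) and len(set(mapped)) == len(mapped)


class TestFingerprint:
    def test_reference_fingerprint_matches_annotation(self, annotation):
        msa = msa_with_reference(annotation, [("m", annotation.ref_sequence)])
        fp = extract_fingerprint(msa, annotation, annotation.ref_id)
        assert fp.symbols == annotation.reference_fingerprint().symbols
        sub = "".join(fp.symbol_at(p) for p in (33, 48, 69, 71, 101))
        assert sub == "HYETQ"

    def test_point_variant_changes_only_its_slot(self, annotation):
        seq = list(annotation.ref_sequence)
        seq[79 - 1] = "A"
        msa = msa_with_reference(annotation, [("m", "".join(seq))])
        fp = extract_fingerprint(msa, annotation, "m")
        ref_fp = annotation.reference_fingerprint()
        diffs = [
            p for p, a, b in zip(fp.positions, fp.symbols, ref_fp.symbols) if a != b
        ]
        assert diffs == [79]
        assert fp.symbol_at(79) == "A"

    def test_deletion_across_pocket_position_yields_gap_symbol(self, annotation):
        seq = list(annotation.ref_sequence)
        row = "".join(seq[: 125 - 1]) + "-" + "".join(seq[125:])
        msa = msa_with_reference(annotation, [("m", row)])
        fp = extract_fingerprint(msa, annotation, "m")
        assert fp.symbol_at(125) == "-"
        assert not fp.gap_free


class TestFingerprintDistance:
    def _fp(self, symbols, positions=None):
        positions = positions or tuple(range(1, len(symbols) + 1))
        return PocketFingerprint("x", symbols, positions)

    def test_identity_is_zero_and_symmetric(self, matrix):
        f = self._fp("HYETQ")
        g = self._fp("HYETA")
        assert fingerprint_distance(f, f, matrix) == 0.0
        assert fingerprint_distance(f, g, matrix) == fingerprint_distance(g, f, matrix)

    def test_single_substitution_blosum_arithmetic(self, matrix):
        # D vs E: (s(D,D)+s(E,E))/2 - s(D,E) = (6+5)/2 - 2 = 3.5
        assert fingerprint_distance(self._fp("D"), self._fp("E"), matrix) == 3.5

    def test_one_sided_gap_costs_gap_penalty(self, matrix):
        assert fingerprint_distance(self._fp("X"), self._fp("-"), matrix, gap_penalty=8) == 8.0

    def test_double_gap_costs_nothing(self, matrix):
        assert fingerprint_distance(self._fp("-A"), self._fp("-A"), matrix) == 0.0

    def test_length_mismatch_rejected(self, matrix):
        with pytest.raises(ValueError):
            fingerprint_distance(self._fp("HY"), self._fp("HYE"), matrix)

    def test_premetric_nonnegative_on_all_pairs(self, matrix):
        import itertools

        for a, b in itertools.product("ACDEFGHIKLMNPQRSTVWY", repeat=2):
            assert fingerprint_distance(self._fp(a), self._fp(b), matrix) >= 0.0


class TestDisruption:
    def test_identical_member_is_clean(self, annotation):
        msa = msa_with_reference(annotation, [("m", annotation.ref_sequence)])
        rep = detect_disruption(msa, annotation, "m")
        assert not rep.disrupted
        for stats in rep.domains.values():
            assert stats.max_insertion == 0 and stats.unaligned == 0

    def test_long_insertion_inside_span_flags_member(self, annotation):
        # 15 inserted residues between reference positions 150 and 151
        ref_row = annotation.ref_sequence[:150] + "-" * 15 + annotation.ref_sequence[150:]
        mem_row = annotation.ref_sequence[:150] + "W" * 15 + annotation.ref_sequence[150:]
        msa = MultipleAlignment([(annotation.ref_id, ref_row), ("m", mem_row)])
        rep = detect_disruption(msa, annotation, "m", max_insert=10)
        assert rep.disrupted
        assert rep.domains["solvent_exposed_domain"].max_insertion == 15
        assert not rep.domains["catalytic_domain"].exceeded

    def test_missing_span_counts_unaligned(self, annotation):
        # member entirely missing the solvent-exposed domain (positions 141-170)
        mem_row = annotation.ref_sequence[:140] + "-" * 30
        msa = MultipleAlignment([(annotation.ref_id, annotation.ref_sequence), ("m", mem_row)])
        rep = detect_disruption(msa, annotation, "m")
        assert rep.disrupted
        assert rep.domains["solvent_exposed_domain"].unaligned == 30

    def test_threshold_boundary_is_strict(self, annotation):
        ref_row = annotation.ref_sequence[:150] + "-" * 10 + annotation.ref_sequence[150:]
        mem_row = annotation.ref_sequence[:150] + "W" * 10 + annotation.ref_sequence[150:]
        msa = MultipleAlignment([(annotation.ref_id, ref_row), ("m", mem_row)])
        assert not detect_disruption(msa, annotation, "m", max_insert=10).disrupted
        assert detect_disruption(msa, annotation, "m", max_insert=9).disrupted


class TestPocketFromStructure:
    def test_contact_within_cutoff(self):
        s = make_toy_structure(3, [3.0])
        assert pocket_from_structure(s, "LIG", 4.5) == [1]

    def test_far_ligand_has_no_contacts(self):
        s = make_toy_structure(3, [100.0])
        assert pocket_from_structure(s, "LIG", 4.5) == []

    def test_boundary_is_inclusive(self):
        s = make_toy_structure(3, [4.5])
        assert pocket_from_structure(s, "LIG", 4.5) == [1]

    def test_absent_ligand_is_an_error(self):
        s = make_toy_structure(3, [3.0])
        with pytest.raises(ValueError, match="NAR"):
            pocket_from_structure(s, "NAR", 4.5)

    def test_multiple_ligands_are_listed(self):
        s = make_toy_structure(3, [3.0])
        s.ligands.append(s.ligands[0])
        with pytest.raises(ValueError, match="multiple"):
            pocket_from_structure(s, "LIG", 4.5)
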