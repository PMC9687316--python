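"""Residue-list parsing, stretch extraction, peptide design, overlap scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boomdock.mimetics import (BindingSiteRange, ResidueListError, build_peptide,
                               bundled_residue_lists, extract_stretches,
                               overlap_score, parse_residue_list,
                               parse_residue_table, peptides_fasta,
                               select_peptides)

EXPECTED_PEPTIDES = {
    "P1": "GFDNYGDPLGVF", "P2": "EVAVIVFGKGG", "P3": "KNGFYWGQN",
    "P4": "LGRGVGPK", "P5": "WGNNGSGM", "P6": "RIMGKTGP", "P7": "VAVIVFGK",
}


class TestParseResidueList:
    def test_gap_markers_get_implied_numbers(self):
        lst = parse_residue_list("K82, N83, X, F85", source="WUS")
        assert lst.entries == [("K", 82), ("N", 83), ("X", 84), ("F", 85)]

    def test_hyphenated_tokens_equivalent(self):
        a = parse_residue_list("L183, X, R-185", source="LEC2")
        b = parse_residue_list("L183, X, R185", source="LEC2")
        assert a.entries == b.entries == [("L", 183), ("X", 184), ("R", 185)]

    def test_empty_text_gives_empty_list(self):
        assert parse_residue_list("").entries == []

    def test_unknown_token_rejected(self):
        with pytest.raises(ResidueListError, match="token"):
            parse_residue_list("K82, ?!9")

    def test_strict_mode_rejects_non_monotonic_numbers(self):
        with pytest.raises(ResidueListError, match="monotonic"):
            parse_residue_list("W226, X, N228, M223", lenient=False)

    def test_lenient_mode_repairs_and_flags_typo(self):
        lst = parse_residue_list("W226, X, N228, N229, X, S231, X, M223",
                                 source="LEC2", lenient=True)
        assert lst.entries[-1] == ("M", 233)
        assert len(lst.repairs) == 1 and "M233" in lst.repairs[0]


class TestExtractStretches:
    def test_reference_block_yields_printed_stretches(self):
        text = ("R71, I72, M73, X, K75, T76, X, P78\n"
                "G131, F132, D133, N134, Y135, X, D137, P138, L139, X, V141, F142")
        stretches = extract_stretches(parse_residue_list(text, source="LEC1"))
        by_start = {s.start: s for s in stretches}
        assert set(by_start) == {71, 131}
        assert by_start[71].length == 8 and by_start[71].gaps == {74, 77}
        assert by_start[131].length == 12 and by_start[131].gaps == {136, 140}

    def test_double_gap_splits_into_singletons(self):
        stretches = extract_stretches(parse_residue_list("K10, F13"))
        assert [(s.start, s.end) for s in stretches] == [(10, 10), (13, 13)]

    def test_matches_brute_force_enumeration(self):
        def oracle(present):
            """Exhaustive scan: grow stretches while gaps stay single."""
            present = sorted(present)
            out, i = [], 0
            while i < len(present):
                j = i
                while j + 1 < len(present) and present[j + 1] - present[j] in (1, 2):
                    j += 1
                out.append((present[i], present[j]))
                i = j + 1
            return out

        rng = np.random.default_rng(19)
        for _ in range(1000):
            numbers = sorted(rng.choice(np.arange(1, 60), size=rng.integers(1, 25),
                                        replace=False))
            text = ", ".join(f"A{n}" for n in numbers)
            stretches = extract_stretches(parse_residue_list(text))
            assert [(s.start, s.end) for s in stretches] == oracle(numbers)

    def test_no_stretch_has_adjacent_gaps(self):
        for lst in bundled_residue_lists():
            for s in extract_stretches(lst):
                gaps = sorted(s.gaps)
                assert all(b - a > 1 for a, b in zip(gaps, gaps[1:]))
                assert s.start in s.present and s.end in s.present

    def test_idempotent_under_reserialization(self):
        lst = parse_residue_list("L183, X, R185, X, V187, X, P189, K190", source="LEC2")
        (stretch,) = extract_stretches(lst)
        tokens = []
        for n in range(stretch.start, stretch.end + 1):
            tokens.append("X" if n in stretch.gaps else f"{lst.present[n]}{n}")
        (again,) = extract_stretches(parse_residue_list(", ".join(tokens), source="LEC2"))
        assert (again.start, again.end, again.gaps) == (stretch.start, stretch.end,
                                                        stretch.gaps)


class TestBuildPeptide:
    @pytest.mark.parametrize("text, expected", [
        ("G131, F132, D133, N134, Y135, X, D137, P138, L139, X, V141, F142",
         "GFDNYGDPLGVF"),
        ("K82, N83, X, F85, Y86, W87, X, Q89, N90", "KNGFYWGQN"),
        ("I8, K9, R10, I11", "IKRI"),  # gapless: verbatim source codes
    ])
    def test_glycine_bridged_sequences(self, text, expected):
        lst = parse_residue_list(text)
        (stretch,) = extract_stretches(lst)
        assert build_peptide(stretch, lst).sequence == expected

    def test_length_equals_span(self):
        for lst in bundled_residue_lists():
            for stretch in extract_stretches(lst):
                pep = build_peptide(stretch, lst)
                assert pep.length == stretch.end - stretch.start + 1


class TestSelectPeptides:
    def test_full_tables_give_seven_published_candidates(self):
        peptides = select_peptides(bundled_residue_lists(), min_len=8)
        assert {p.id: p.sequence for p in peptides} == EXPECTED_PEPTIDES

    def test_published_id_order_follows_length_then_fragment(self):
        peptides = select_peptides(bundled_residue_lists(), min_len=8)
        lengths = [p.length for p in peptides]
        assert lengths == sorted(lengths, reverse=True) == [12, 11, 9, 8, 8, 8, 8]
        assert [p.fragment for p in peptides] == \
            ["frag1", "frag1", "frag2", "frag1", "frag1", "frag1", "frag2"]

    def test_min_len_too_large_gives_empty(self):
        assert select_peptides(bundled_residue_lists(), min_len=100) == []

    def test_min_len_one_exposes_short_stretches(self):
        lec2 = next(l for l in bundled_residue_lists()
                    if l.source == "LEC2" and l.fragment == "frag1")
        peptides = select_peptides([lec2], min_len=1)
        assert sorted(p.length for p in peptides) == [1, 6, 8, 8]

    def test_no_extra_long_stretch_in_fixture(self):
        long_stretches = [
            (lst.source, lst.fragment, s.start)
            for lst in bundled_residue_lists()
            for s in extract_stretches(lst) if s.length >= 8
        ]
        assert len(long_stretches) == 7

    def test_fasta_serialization(self):
        peptides = select_peptides(bundled_residue_lists(), min_len=8)
        fasta = peptides_fasta(peptides)
        assert fasta.count(">") == 7
        assert ">P4|LEC2|183-190|184,186,188\nLGRGVGPK" in fasta


class TestOverlapScore:
    def test_reference_counts(self):
        from boomdock.mimetics import score_bundled_peptides
        scores = {(s.peptide_id, s.pose_id): s.count for s in score_bundled_peptides()}
        assert scores[("P1", "dock16")] == 13
        assert scores[("P3", "dock49")] == 12
        assert scores[("P2", "dock89")] == 10
        assert scores[("P4", "dock96")] == 8

    def test_empty_interface_scores_zero(self):
        site = BindingSiteRange("frag1", 210, 276)
        assert overlap_score([], site).count == 0

    def test_range_and_complement_partition(self):
        rng = np.random.default_rng(4)
        residues = set(int(x) for x in rng.integers(1, 500, size=60))
        site = BindingSiteRange("a", 100, 300)
        below = BindingSiteRange("b", 1, 99)
        above = BindingSiteRange("c", 301, 500)
        total = (overlap_score(residues, site).count
                 + overlap_score(residues, below).count
                 + overlap_score(residues, above).count)
        assert total == len(residues)

    def test_malformed_range_rejected(self):
        with pytest.raises(ValueError):
            BindingSiteRange("bad", 300, 200)


@settings(derandomize=True, max_examples=200)
@given(st.sets(st.integers(min_value=1, max_value=80), min_size=1, max_size=30))
def test_stretch_partition_invariants(numbers):
    """Stretches partition the input residues; gaps are single and interior."""
    text = ", ".join(f"A{n}" for n in sorted(numbers))
    stretches = extract_stretches(parse_residue_list(text))
    covered = [n for s in stretches for n in s.present]
    assert sorted(covered) == sorted(numbers)
    for s in stretches:
        assert s.present | s.gaps == set(range(s.start, s.end + 1))
        assert all(g - 1 in s.present and g + 1 in s.present for g in s.gaps)


def test_sectioned_table_parser_roundtrip():
    text = "# comment\n[WUS]\nK82, N83, X, F85\nR94\n[LEC1]\nY63, M64\n"
    lists = parse_residue_table(text, fragment="frag2")
    assert [l.source for l in lists] == ["WUS", "LEC1"]
    assert lists[0].entries[-1] == ("R", 94)
    assert lists[1].block_index == 1
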