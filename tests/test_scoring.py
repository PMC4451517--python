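"""Raw residue scores, the three-step normalization, regions, painting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidsite import InputError, MappingError
from lipidsite.align import GAPCOL, IDENTITY, LocalAlignment, OTHER, POSITIVE
from lipidsite.scoring import (
    detect_enriched_regions,
    normalize_track,
    paint_structure,
    raw_residue_scores,
    regions_to_bed,
    track_to_tsv,
)


def _aln(columns, name="p"):
    qs = [q for q, _, _ in columns if q is not None]
    ps = [p for _, p, _ in columns if p is not None]
    return LocalAlignment(
        profile_name=name,
        query_span=(min(qs), max(qs) + 1) if qs else (0, 0),
        profile_span=(min(ps), max(ps) + 1) if ps else (0, 0),
        columns=columns,
        score=1.0,
        params_label="t",
    )


class TestRawScores:
    def test_no_alignments_gives_zero_vector(self):
        assert np.array_equal(raw_residue_scores([], 6), np.zeros(6, dtype=int))

    def test_identity_positive_rule(self):
        aln = _aln([(2, 0, IDENTITY), (3, 1, POSITIVE), (4, 2, IDENTITY)])
        raw = raw_residue_scores([aln], 8)
        assert raw.tolist() == [0, 0, 2, 1, 2, 0, 0, 0]

    def test_two_overlapping_alignments_sum_by_hand(self):
        # alignment 1 covers 1..3: identity, other, positive -> [0,2,0,1,0]
        # alignment 2 covers 2..4: positive, gap(skip), identity -> [0,0,1,0,2]
        a1 = _aln([(1, 0, IDENTITY), (2, 1, OTHER), (3, 2, POSITIVE)])
        a2 = _aln([(2, 0, POSITIVE), (None, 1, GAPCOL), (4, 2, IDENTITY)])
        raw = raw_residue_scores([a1, a2], 5)
        assert raw.tolist() == [0, 2, 1, 1, 2]

    def test_gap_and_other_columns_contribute_nothing(self):
        aln = _aln([(0, 0, OTHER), (None, 1, GAPCOL), (1, None, GAPCOL)])
        assert raw_residue_scores([aln], 3).tolist() == [0, 0, 0]

    def test_out_of_range_index_rejected(self):
        aln = _aln([(5, 0, IDENTITY)])
        with pytest.raises(InputError, match="outside"):
            raw_residue_scores([aln], 3)

    def test_adding_alignment_only_increases_covered_positions(self, rng):
        base = [_aln([(1, 0, IDENTITY), (2, 1, POSITIVE)])]
        extra = _aln([(2, 0, IDENTITY), (3, 1, IDENTITY)])
        before = raw_residue_scores(base, 6)
        after = raw_residue_scores(base + [extra], 6)
        assert np.all(after >= before)
        covered = {2, 3}
        for i in range(6):
            if i not in covered:
                assert after[i] == before[i]


class TestNormalization:
    def test_hand_worked_example(self):
        track = normalize_track([4, 0, 2])
        assert track.normalized.tolist() == [2.0, -2.0, 0.0]
        assert track.positive_count == 1
        assert track.positive_sum == 2.0
        assert track.avg_query_score == 2.0
        assert track.norm_avg_score == pytest.approx(200.0 / 3, abs=1e-9)

    def test_constant_raw_gives_all_zero_summaries(self):
        track = normalize_track([3, 3, 3, 3])
        assert np.all(track.normalized == 0)
        assert track.positive_count == 0
        assert track.avg_query_score == 0.0
        assert track.norm_avg_score == 0.0

    def test_empty_raw_rejected(self):
        with pytest.raises(InputError):
            normalize_track([])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        raw=st.lists(st.integers(min_value=0, max_value=500), min_size=1,
                     max_size=300)
    )
    def test_normalized_scores_sum_to_zero(self, raw):
        track = normalize_track(raw)
        assert abs(track.normalized.sum()) <= 1e-9 * track.length

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        raw=st.lists(st.integers(min_value=0, max_value=100), min_size=2,
                     max_size=100)
    )
    def test_summaries_match_direct_recomputation(self, raw):
        track = normalize_track(raw)
        ns = np.asarray(raw) - np.sum(raw) / len(raw)
        pos = ns[ns > 0]
        assert track.positive_count == pos.size
        assert track.positive_sum == pytest.approx(pos.sum(), abs=1e-12)
        expected_avg = pos.sum() / pos.size if pos.size else 0.0
        assert track.avg_query_score == pytest.approx(expected_avg, abs=1e-12)
        assert track.norm_avg_score == pytest.approx(
            expected_avg * 100.0 / len(raw), abs=1e-12
        )


class TestRegions:
    def test_everything_nonpositive_gives_no_regions(self):
        track = normalize_track([1, 1, 1])
        assert detect_enriched_regions(track) == []

    def test_single_block_with_peak(self):
        raw = [0] * 10 + [5, 8, 12, 9, 6, 5] + [0] * 10
        track = normalize_track(raw)
        regions = detect_enriched_regions(track, min_length=3, merge_gap=0)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (10, 16)
        assert regions[0].peak_residue == 12

    def test_merge_gap_bridges_short_dips(self):
        raw = [0] * 5 + [9, 9, 9, 0, 0, 9, 9, 9] + [0] * 5
        track = normalize_track(raw)
        merged = detect_enriched_regions(track, min_length=3, merge_gap=2)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (5, 13)
        split = detect_enriched_regions(track, min_length=3, merge_gap=1)
        assert len(split) == 2

    def test_short_runs_discarded(self):
        raw = [0] * 8 + [20] + [0] * 8
        track = normalize_track(raw)
        assert detect_enriched_regions(track, min_length=2, merge_gap=0) == []

    def test_regions_sorted_by_mean_score(self):
        raw = [0] * 4 + [3, 3, 3] + [0] * 6 + [9, 9, 9] + [0] * 4
        track = normalize_track(raw)
        regions = detect_enriched_regions(track, min_length=3, merge_gap=0)
        assert len(regions) == 2
        assert regions[0].mean_score >= regions[1].mean_score
        assert regions[0].start == 13


PDB_3RES = [
    "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 11.11           N",
    "ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00 11.11           C",
    "ATOM      3  N   GLY A   2       2.000   0.000   0.000  1.00 11.11           N",
    "ATOM      4  N   SER A   3       3.000   0.000   0.000  1.00 11.11           N",
    "TER",
    "END",
]


class TestPainting:
    def test_scores_written_per_residue(self):
        track = normalize_track([4, 0, 2])  # normalized 2 / -2 / 0
        painted = paint_structure(track, PDB_3RES, chain="A")
        assert painted[0][60:66] == "  2.00"
        assert painted[1][60:66] == "  2.00"
        assert painted[2][60:66] == " -2.00"
        assert painted[3][60:66] == "  0.00"
        assert painted[4:] == PDB_3RES[4:]

    def test_all_zero_track_touches_only_bfactor_columns(self):
        track = normalize_track([1, 1, 1])
        painted = paint_structure(track, PDB_3RES, chain="A")
        for old, new in zip(PDB_3RES, painted):
            if old.startswith("ATOM"):
                assert new[:60] == old[:60] and new[66:] == old[66:]
                assert new[60:66] == "  0.00"
            else:
                assert new == old

    def test_unmatched_residue_raises_mapping_error(self):
        track = normalize_track([4, 0])  # only 2 residues for a 3-residue chain
        with pytest.raises(MappingError, match=r"\[3\]"):
            paint_structure(track, PDB_3RES, chain="A")

    def test_offset_reconciles_numbering(self):
        shifted = [
            ln[:22] + f"{int(ln[22:26]) + 10:4d}" + ln[26:]
            if ln.startswith("ATOM") else ln
            for ln in PDB_3RES
        ]
        track = normalize_track([4, 0, 2])
        painted = paint_structure(track, shifted, chain="A", residue_offset=10)
        assert painted[0][60:66] == "  2.00"


class TestExports:
    def test_track_tsv_is_one_based_and_complete(self):
        track = normalize_track([4, 0, 2])
        text = track_to_tsv(track, "AGS")
        lines = text.strip().splitlines()
        assert lines[0] == "residue\tletter\traw\tnormalized"
        assert lines[1].startswith("1\tA\t4\t2.0")
        assert len(lines) == 4

    def test_bed_export_is_zero_based_half_open(self):
        raw = [0] * 5 + [9, 9, 9, 9, 9] + [0] * 5
        track = normalize_track(raw)
        regions = detect_enriched_regions(track, min_length=3, merge_gap=0)
        bed = regions_to_bed(regions, "q")
        fields = bed.strip().split("\t")
        assert (fields[1], fields[2]) == ("5", "10")
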