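"""Interval engine: BED I/O, sorting, nearest-distance, overlap counting,
window tiling and random placement, checked against exhaustive oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from g4snv.intervals import (
    BedParseError,
    GenomicInterval,
    IntervalSet,
    closest_distance,
    intersect_count,
    make_windows,
    merge_intervals,
    random_intervals,
    read_bed,
    sort_intervals,
    write_bed,
)
from conftest import brute_closest_value, brute_intersect_counts, random_interval_set


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_length_and_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert len(a) == 10
        assert a.overlaps(GenomicInterval("chr1", 9, 12))
        assert not a.overlaps(GenomicInterval("chr1", 10, 12))  # half-open
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestBedIO:
    @pytest.mark.parametrize(
        "line,expected",
        [
            ("chr1\t100\t200", ("chr1", 100, 200, ".", None)),
            ("chr2\t5\t10\tg4_1\t0\t-", ("chr2", 5, 10, "-", "g4_1")),
        ],
    )
    def test_read_single_line(self, tmp_path, line, expected):
        p = tmp_path / "x.bed"
        p.write_text(line + "\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.strand, iv.label) == expected

    def test_malformed_coordinates_raise_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\t20\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_comment_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("# c\ntrack name=t\nchr1\t0\t5\n")
        assert len(read_bed(p)) == 1

    def test_round_trip_preserves_fields(self, tmp_path):
        original = IntervalSet(
            [
                GenomicInterval("chr1", 0, 10, "+", "a"),
                GenomicInterval("chr1", 50, 60, "-", "b"),
                GenomicInterval("chr2", 5, 6),
            ]
        )
        p = tmp_path / "rt.bed"
        write_bed(original, p)
        assert read_bed(p) == original

    def test_empty_set_round_trips(self, tmp_path):
        p = tmp_path / "empty.bed"
        write_bed(IntervalSet(), p)
        assert len(read_bed(p)) == 0


class TestSort:
    def test_sorts_and_groups_by_chromosome(self):
        s = IntervalSet(
            [
                GenomicInterval("chr2", 5, 10),
                GenomicInterval("chr1", 50, 60),
                GenomicInterval("chr1", 10, 20),
            ]
        )
        ordered = sort_intervals(s)
        assert [(iv.chrom, iv.start) for iv in ordered] == [
            ("chr1", 10),
            ("chr1", 50),
            ("chr2", 5),
        ]
        assert ordered.sorted_flag

    @given(st.lists(st.tuples(st.integers(0, 100), st.integers(1, 20)), max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_sort_is_idempotent(self, spans):
        s = IntervalSet([GenomicInterval("chr1", a, a + b) for a, b in spans])
        once = sort_intervals(s)
        assert sort_intervals(once) == once


class TestClosest:
    def test_downstream_gap(self):
        q = IntervalSet([GenomicInterval("chr1", 130, 131)])
        r = IntervalSet([GenomicInterval("chr1", 100, 120)])
        (d,) = closest_distance(q, r)
        assert d.value == 10

    def test_upstream_gap_is_negative(self):
        q = IntervalSet([GenomicInterval("chr1", 80, 90)])
        r = IntervalSet([GenomicInterval("chr1", 100, 120)])
        (d,) = closest_distance(q, r)
        assert d.value == -10

    def test_overlap_is_zero(self):
        q = IntervalSet([GenomicInterval("chr1", 105, 106)])
        r = IntervalSet([GenomicInterval("chr1", 100, 120)])
        (d,) = closest_distance(q, r)
        assert d.value == 0

    def test_empty_reference_raises(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 1)])
        with pytest.raises(ValueError):
            closest_distance(q, IntervalSet())

    def test_query_on_missing_chromosome_flagged(self):
        q = IntervalSet([GenomicInterval("chrX", 0, 1)])
        r = IntervalSet([GenomicInterval("chr1", 0, 10)])
        (d,) = closest_distance(q, r)
        assert not d.has_neighbor

    def test_tie_breaks_toward_leftmost_reference(self):
        q = IntervalSet([GenomicInterval("chr1", 95, 105)])
        r = IntervalSet(
            [GenomicInterval("chr1", 80, 90, label="left"), GenomicInterval("chr1", 110, 120, label="right")]
        )
        (d,) = closest_distance(q, r)
        assert d.ref_label == "left" and d.value == 5

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            q = random_interval_set(rng, int(rng.integers(1, 50)))
            r = random_interval_set(rng, int(rng.integers(1, 50)))
            got = closest_distance(q, r)
            for query, res in zip(q, got):
                expected = brute_closest_value(query, r)
                if expected is None:
                    assert not res.has_neighbor
                else:
                    assert res.value == expected

    def test_strand_aware_flips_sign_on_minus_references(self):
        q = IntervalSet([GenomicInterval("chr1", 130, 131)])
        r = IntervalSet([GenomicInterval("chr1", 100, 120, "-")])
        (d,) = closest_distance(q, r, strand_aware=True)
        assert d.value == -10


class TestIntersect:
    def test_half_open_boundary(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 10)])
        r = IntervalSet(
            [
                GenomicInterval("chr1", 5, 6),
                GenomicInterval("chr1", 9, 10),
                GenomicInterval("chr1", 10, 11),
            ]
        )
        assert intersect_count(q, r).tolist() == [2]

    def test_disjoint_sets_all_zero(self):
        q = IntervalSet([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 20, 30)])
        r = IntervalSet([GenomicInterval("chr1", 12, 18)])
        assert intersect_count(q, r).tolist() == [0, 0]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            q = random_interval_set(rng, 40)
            r = random_interval_set(rng, 40)
            assert intersect_count(q, r).tolist() == brute_intersect_counts(q, r)


class TestMakeWindows:
    def test_fixed_end_truncated_final_tile(self):
        region = IntervalSet([GenomicInterval("chr1", 0, 12_000)])
        ws = make_windows(region, 5000)
        assert [(w.start, w.end) for w in ws] == [(0, 5000), (5000, 10_000), (10_000, 12_000)]

    def test_sliding_windows_truncate_at_region_end(self):
        region = IntervalSet([GenomicInterval("chr1", 0, 7000)])
        ws = make_windows(region, 5000, 1000)
        starts = [w.start for w in ws]
        assert starts == [0, 1000, 2000, 3000, 4000, 5000, 6000]
        assert all(w.end == min(w.start + 5000, 7000) for w in ws)

    def test_region_shorter_than_size_single_window(self):
        region = IntervalSet([GenomicInterval("chr1", 100, 1100)])
        ws = make_windows(region, 5000)
        assert [(w.start, w.end) for w in ws] == [(100, 1100)]

    def test_fixed_windows_conserve_coverage(self):
        region = IntervalSet([GenomicInterval("chr1", 37, 12_345)])
        ws = make_windows(region, 999)
        merged = merge_intervals(ws)
        assert [(iv.start, iv.end) for iv in merged] == [(37, 12_345)]

    def test_invalid_size_raises(self):
        with pytest.raises(ValueError):
            make_windows(IntervalSet([GenomicInterval("chr1", 0, 10)]), 0)


class TestRandomIntervals:
    def test_deterministic_and_contained(self):
        mask = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        a = random_intervals(mask, 200, 5, seed=7)
        b = random_intervals(mask, 200, 5, seed=7)
        assert a == b
        assert all(iv.start >= 0 and iv.end <= 1000 and len(iv) == 200 for iv in a)

    def test_mask_too_short_raises(self):
        mask = IntervalSet([GenomicInterval("chr1", 0, 150)])
        with pytest.raises(ValueError):
            random_intervals(mask, 200, 5, seed=0)

    def test_two_equal_masks_split_evenly(self):
        mask = IntervalSet(
            [GenomicInterval("chr1", 0, 10_000), GenomicInterval("chr2", 0, 10_000)]
        )
        draws = random_intervals(mask, 200, 100_000, seed=1)
        frac = sum(iv.chrom == "chr1" for iv in draws) / len(draws)
        assert abs(frac - 0.5) < 0.01

    def test_start_positions_uniform(self):
        mask = IntervalSet([GenomicInterval("chr1", 0, 100_000)])
        draws = random_intervals(mask, 200, 100_000, seed=2)
        starts = np.array([iv.start for iv in draws])
        counts, _ = np.histogram(starts, bins=20, range=(0, 100_000 - 199))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01


class TestDistanceExport:
    def test_distances_written_as_tsv(self, tmp_path):
        from g4snv.intervals import write_distances_tsv

        q = IntervalSet([GenomicInterval("chr1", 130, 131, label="snv1"),
                         GenomicInterval("chrX", 0, 1)])
        r = IntervalSet([GenomicInterval("chr1", 100, 120, label="g4_0")])
        d = closest_distance(q, r)
        p = tmp_path / "dist.tsv"
        write_distances_tsv(q, d, p)
        lines = p.read_text().splitlines()
        assert lines[1] == "chr1\t130\t131\tsnv1\tg4_0\t10"
        assert lines[2].endswith("NA")
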