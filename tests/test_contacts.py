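"""Pairwise expansion, mock paired-end emission, filtering, duplicates, stats."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from concatmap import (AlignedSegment, distance_histogram, emit_mock_pairs,
                       expand_pairwise, filter_pairs, mark_duplicates,
                       segment_stats)
from concatmap.contacts import log_spaced_edges
from concatmap.digest import reverse_complement

from oracle_utils import all_index_pairs


def make_segments(n, read_id="r", chrom="chr1", spacing=10_000, mapq=60,
                  unmapped=(), seq=None):
    segs = []
    for i in range(n):
        if i in unmapped:
            segs.append(AlignedSegment(read_id, i, None, 0, 1, "+", 0))
        else:
            start = 1000 + i * spacing
            segs.append(AlignedSegment(read_id, i, chrom, start, start + 500,
                                       "+", mapq, sequence=seq))
    return segs


class TestExpandPairwise:
    def test_17_segments_yield_136_pairs(self):
        assert len(expand_pairwise(make_segments(17))) == 136

    @pytest.mark.parametrize("n", [0, 1, 2, 5, 10])
    def test_pair_count_is_n_choose_2(self, n):
        assert len(expand_pairwise(make_segments(n))) == n * (n - 1) // 2

    @pytest.mark.parametrize("n", range(2, 11))
    def test_pair_set_matches_exhaustive_enumeration(self, n):
        pairs = expand_pairwise(make_segments(n))
        assert {(p.index1, p.index2) for p in pairs} == all_index_pairs(n)

    def test_unmapped_segments_carried_through(self):
        pairs = expand_pairwise(make_segments(4, unmapped={1}))
        assert len(pairs) == 6
        assert sum(1 for p in pairs if not p.both_mapped) == 3

    def test_mixed_read_ids_rejected(self):
        segs = make_segments(2) + make_segments(2, read_id="other")
        with pytest.raises(ValueError, match="multiple reads"):
            expand_pairwise(segs)

    def test_upper_triangle_mate_order(self):
        a = AlignedSegment("r", 0, "chr2", 500, 900, "+", 60)
        b = AlignedSegment("r", 1, "chr1", 100, 300, "+", 60)
        (pair,) = expand_pairwise([a, b])
        assert (pair.chrom1, pair.chrom2) == ("chr1", "chr2")

    def test_representative_position_is_five_prime(self):
        fwd = AlignedSegment("r", 0, "chr1", 100, 300, "+", 60)
        rev = AlignedSegment("r", 1, "chr1", 5000, 5400, "-", 60)
        (pair,) = expand_pairwise([fwd, rev])
        assert pair.pos1 == 100
        assert pair.pos2 == 5399  # 5'-most base of a reverse alignment

    def test_cis_trans_classification_and_distance(self):
        a = AlignedSegment("r", 0, "chr1", 1_000, 1_500, "+", 60)
        b = AlignedSegment("r", 1, "chr1", 51_000, 51_500, "+", 60)
        c = AlignedSegment("r", 2, "chr2", 100, 600, "+", 60)
        pairs = {(p.index1, p.index2): p for p in expand_pairwise([a, b, c])}
        assert pairs[(0, 1)].pair_class == "cis"
        assert pairs[(0, 1)].distance == 50_000
        assert pairs[(0, 2)].pair_class == "trans"
        assert pairs[(0, 2)].distance is None


class TestEmitMockPairs:
    def test_136_pairs_give_272_mates(self):
        segs = make_segments(17, seq="ACGT" * 50)
        pairs = expand_pairwise(segs)
        records = emit_mock_pairs(pairs, segs)
        assert len(records) == 136
        assert sum(2 for _ in records) == 272

    def test_no_pairs_no_records(self):
        assert emit_mock_pairs([], make_segments(1)) == []

    def test_mate_sequences_and_orientation(self):
        seq = "ACGTACGTAA" * 30
        segs = make_segments(2, seq=seq)
        (record,) = emit_mock_pairs(expand_pairwise(segs), segs, mate_length=20)
        assert record.mate1.is_first and not record.mate2.is_first
        assert record.mate1.sequence == seq[:20]
        assert record.mate2.sequence == reverse_complement(seq[:20])

    def test_mate_coordinates_equal_segment_coordinates(self):
        segs = make_segments(3)
        records = emit_mock_pairs(expand_pairwise(segs), segs)
        by_pos = {s.segment_index: s.position for s in segs}
        for rec in records:
            i, j = map(int, rec.template_id.split(":")[1].split("-"))
            assert {rec.mate1.pos, rec.mate2.pos} == {by_pos[i], by_pos[j]}

    def test_invalid_mate_length(self):
        segs = make_segments(2)
        with pytest.raises(ValueError, match="mate_length"):
            emit_mock_pairs(expand_pairwise(segs), segs, mate_length=0)


class TestFilterPairs:
    @pytest.fixture
    def mixed_pairs(self, rng):
        segs = []
        for i, mapq in enumerate([0, 5, 15, 25, 45, 60]):
            segs.append(AlignedSegment("r", i, "chr1", 1000 * (i + 1),
                                       1000 * (i + 1) + 400, "+", int(mapq)))
        segs.append(AlignedSegment("r", 6, None, 0, 1, "+", 0))
        return expand_pairwise(segs)

    def test_unmapped_mate_rejected(self, mixed_pairs):
        retained, tally = filter_pairs(mixed_pairs, mapq_min=0)
        assert tally.unmapped_mate == 6
        assert all(p.both_mapped for p in retained)

    def test_mapq_zero_mate_rejected_at_threshold_one(self):
        segs = [AlignedSegment("r", 0, "chr1", 100, 500, "+", 0),
                AlignedSegment("r", 1, "chr1", 9000, 9500, "+", 60)]
        retained, tally = filter_pairs(expand_pairwise(segs), mapq_min=1)
        assert retained == [] and tally.low_mapq == 1

    def test_threshold_zero_keeps_all_mapped(self, mixed_pairs):
        retained, tally = filter_pairs(mixed_pairs, mapq_min=0)
        assert len(retained) == 15  # C(6,2) fully mapped pairs

    def test_monotone_nesting_across_cutoffs(self, mixed_pairs):
        previous = None
        for cutoff in (0, 1, 10, 20, 30, 60):
            retained, tally = filter_pairs(mixed_pairs, mapq_min=cutoff)
            ids = {(p.index1, p.index2) for p in retained}
            if previous is not None:
                assert ids <= previous
            previous = ids
            assert tally.total == tally.retained + tally.unmapped_mate + tally.low_mapq
            assert tally.total == len(mixed_pairs)


class TestMarkDuplicates:
    def test_identical_fingerprints_flag_one_duplicate(self):
        reads = {"b": make_segments(3, read_id="b"),
                 "a": make_segments(3, read_id="a")}
        report = mark_duplicates(reads)
        assert report.duplicates == {"b"}  # representative is first in sort order

    def test_rate_on_constructed_fixture(self):
        reads = {}
        for i in range(98):
            reads[f"r{i:03d}"] = make_segments(2, read_id=f"r{i:03d}",
                                               spacing=137 * (i + 1))
        reads["dupA"] = make_segments(2, read_id="dupA", spacing=137)
        reads["dupB"] = make_segments(2, read_id="dupB", spacing=137 * 2)
        report = mark_duplicates(reads)
        assert len(report.duplicates) == 2
        assert report.rate == pytest.approx(0.02)

    def test_all_unique_rate_zero(self):
        reads = {f"r{i}": make_segments(2, read_id=f"r{i}", spacing=100 + 7 * i)
                 for i in range(20)}
        assert mark_duplicates(reads).rate == 0.0

    def test_idempotent_and_order_stable(self):
        reads = {"a": make_segments(2, read_id="a"),
                 "b": make_segments(2, read_id="b"),
                 "c": make_segments(2, read_id="c", spacing=999)}
        first = mark_duplicates(reads)
        reordered = {k: reads[k] for k in ["c", "b", "a"]}
        assert mark_duplicates(reordered).duplicates == first.duplicates
        survivors = {k: v for k, v in reads.items() if k not in first.duplicates}
        assert mark_duplicates(survivors).duplicates == set()


class TestDistanceHistogram:
    def test_known_distance_lands_in_its_bin(self):
        segs = [AlignedSegment("r", 0, "chr1", 1_000, 1_400, "+", 60),
                AlignedSegment("r", 1, "chr1", 51_000, 51_400, "+", 60)]
        hist = distance_histogram(expand_pairwise(segs))
        row = hist[(hist.bin_left <= 50_000) & (hist.bin_right > 50_000)]
        assert row["count"].sum() == 1
        assert hist["percent"].sum() == pytest.approx(100.0)

    def test_trans_only_input_is_empty(self):
        segs = [AlignedSegment("r", 0, "chr1", 100, 500, "+", 60),
                AlignedSegment("r", 1, "chr2", 100, 500, "+", 60)]
        hist = distance_histogram(expand_pairwise(segs))
        assert hist["count"].sum() == 0
        assert hist["percent"].sum() == 0.0

    def test_bin_counts_match_brute_force_tally(self, rng):
        pairs = []
        for i in range(500):
            start = int(rng.integers(0, 1_000_000))
            d = int(rng.integers(100, 500_000))
            segs = [AlignedSegment(f"r{i}", 0, "chr1", start, start + 100, "+", 60),
                    AlignedSegment(f"r{i}", 1, "chr1", start + d, start + d + 100,
                                   "+", 60)]
            pairs.extend(expand_pairwise(segs))
        edges = log_spaced_edges(100, 1_000_000, 6)
        hist = distance_histogram(pairs, edges)
        distances = [p.distance for p in pairs]
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            last = k == len(edges) - 2
            expected = sum(1 for d in distances
                           if lo <= d < hi or (last and d == hi))
            assert hist["count"].iloc[k] == expected


class TestSegmentStats:
    def test_lower_median_convention(self):
        reads = {"a": make_segments(2, read_id="a"),
                 "b": make_segments(17, read_id="b"),
                 "c": make_segments(17, read_id="c")}
        stats = segment_stats(reads)
        assert stats["segments_per_read"]["median"] == 17
        reads["d"] = make_segments(3, read_id="d")
        # even count 2,3,17,17 -> lower median 3
        assert segment_stats(reads)["segments_per_read"]["median"] == 3

    def test_single_read_summaries(self):
        stats = segment_stats({"a": make_segments(5, read_id="a")})
        s = stats["segments_per_read"]
        assert s["mean"] == s["median"] == s["mode"] == 5 and s["sd"] == 0.0

    def test_matches_independent_recomputation(self, rng):
        reads = {f"r{i}": make_segments(int(rng.integers(1, 12)), read_id=f"r{i}")
                 for i in range(40)}
        stats = segment_stats(reads)["segments_per_read"]
        counts = sorted(len(v) for v in reads.values())
        assert stats["mean"] == pytest.approx(np.mean(counts))
        assert stats["median"] == counts[(len(counts) - 1) // 2]
        assert stats["sd"] == pytest.approx(np.std(counts, ddof=1))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            segment_stats({})
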