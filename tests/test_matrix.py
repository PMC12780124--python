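"""Contact binning, Knight-Ruiz balancing, correlation, MAPQ class profiles."""

import numpy as np
import pytest

from concatmap import (AlignedSegment, ContactMatrix, bin_contacts,
                       expand_pairwise, kr_balance, mapq_class_profile,
                       matrix_correlation)

CHROMS = {"chr1": 10_000_000, "chr2": 6_000_000}


def pair_at(chrom1, pos1, chrom2, pos2, read_id="r", mapq=60):
    a = AlignedSegment(read_id, 0, chrom1, pos1, pos1 + 100, "+", mapq)
    b = AlignedSegment(read_id, 1, chrom2, pos2, pos2 + 100, "+", mapq)
    (pair,) = expand_pairwise([a, b])
    return pair


class TestBinContacts:
    def test_cis_pair_lands_in_expected_cell(self):
        matrix = bin_contacts([pair_at("chr1", 2_600_000, "chr1", 7_100_000)],
                              CHROMS, 2_500_000)
        assert matrix.counts == {(1, 2): 1}

    def test_total_mass_equals_pair_count(self, rng):
        pairs = [pair_at("chr1", int(rng.integers(0, 9_000_000)),
                         "chr1", int(rng.integers(0, 9_000_000)), read_id=f"r{i}")
                 for i in range(200)]
        matrix = bin_contacts(pairs, CHROMS, 50_000)
        assert matrix.total == 200
        dense = matrix.dense()
        assert np.allclose(dense, dense.T)

    def test_matches_dense_enumeration_oracle(self, rng):
        pairs = []
        for i in range(50):
            c1, c2 = rng.choice(list(CHROMS), size=2)
            p1 = int(rng.integers(0, CHROMS[c1] - 200))
            p2 = int(rng.integers(0, CHROMS[c2] - 200))
            pairs.append(pair_at(c1, p1, c2, p2, read_id=f"r{i}"))
        bs = 1_000_000
        matrix = bin_contacts(pairs, CHROMS, bs)
        offsets = {"chr1": 0, "chr2": 10}  # ceil(10 Mb / 1 Mb) bins on chr1
        expected = np.zeros((16, 16))
        for p in pairs:
            i = offsets[p.chrom1] + p.pos1 // bs
            j = offsets[p.chrom2] + p.pos2 // bs
            expected[i, j] += 1
            if i != j:
                expected[j, i] += 1
        assert np.array_equal(matrix.dense(), expected)

    def test_out_of_range_coordinate_rejected(self):
        with pytest.raises(ValueError):
            bin_contacts([pair_at("chr1", 2_000_000, "chr1", 10_500_000)],
                         CHROMS, 2_500_000)

    def test_bin_index_roundtrip(self):
        matrix = ContactMatrix(dict(CHROMS), 2_500_000)
        for idx in range(matrix.n_bins):
            chrom, start = matrix.bin_location(idx)
            assert matrix.bin_index(chrom, start) == idx


class TestKnightRuiz:
    def test_2x2_closed_form(self):
        A = np.array([[0.0, 2.0], [2.0, 0.0]])
        result = kr_balance(A)
        assert result.converged
        # exact solution: w = 1/sqrt(2), balanced row sums both 1
        assert result.weights == pytest.approx([2 ** -0.5, 2 ** -0.5], abs=1e-6)
        assert result.balanced(A).sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_already_balanced_matrix(self):
        A = np.eye(4)
        result = kr_balance(A)
        assert result.converged
        assert result.weights == pytest.approx(np.ones(4))

    def test_rowsum_dispersion_below_tolerance(self, rng):
        for _ in range(5):
            n = int(rng.integers(50, 500))
            M = rng.random((n, n))
            M = M + M.T + 0.05
            result = kr_balance(M)
            assert result.converged
            sums = result.balanced(M).sum(axis=1)
            assert sums.max() / sums.min() - 1 < 1e-6

    def test_zero_rows_masked(self):
        A = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        result = kr_balance(A)
        assert result.converged
        assert np.isnan(result.weights[2]) and result.mask[2]
        sums = result.balanced(A).sum(axis=1)
        assert sums[:2] == pytest.approx([1.0, 1.0])

    def test_disconnected_matrix_flagged(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        A[2, 3] = A[3, 2] = 5.0
        result = kr_balance(A)
        assert not result.converged
        assert result.status == "disconnected"

    def test_unbalanceable_star_matrix_flagged(self):
        # rows 1 and 2 touch only row 0: no diagonal scaling equalizes sums
        A = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        result = kr_balance(A, max_iter=500)
        assert not result.converged
        assert result.status == "not_converged"

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            kr_balance(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestMatrixCorrelation:
    def test_self_correlation_is_one(self, rng):
        M = rng.random((20, 20))
        M = M + M.T
        assert matrix_correlation(M, M) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(2024)
        n = 141  # ~10,000 upper-triangle cells
        A = rng.random((n, n))
        B = rng.random((n, n))
        A, B = A + A.T, B + B.T
        assert matrix_correlation(A, B) < 0.05

    def test_hand_computed_3x3(self):
        A = np.array([[1.0, 2.0, 0.0], [2.0, 3.0, 1.0], [0.0, 1.0, 4.0]])
        B = np.array([[2.0, 1.0, 1.0], [1.0, 5.0, 0.0], [1.0, 0.0, 3.0]])
        a = np.array([1.0, 2.0, 0.0, 3.0, 1.0, 4.0])  # upper triangle of A
        b = np.array([2.0, 1.0, 1.0, 5.0, 0.0, 3.0])
        expected = (np.corrcoef(a, b)[0, 1]) ** 2
        assert matrix_correlation(A, B) == pytest.approx(expected, abs=1e-12)

    def test_nonzero_cell_restriction(self):
        A = np.diag([1.0, 2.0, 3.0, 0.0])
        B = np.diag([2.0, 4.0, 6.0, 0.0])
        full = matrix_correlation(A, B, cells="all")
        nz = matrix_correlation(A, B, cells="nonzero")
        assert full == pytest.approx(1.0) and nz == pytest.approx(1.0)

    def test_mismatched_binning_rejected(self):
        m1 = ContactMatrix(dict(CHROMS), 1_000_000)
        m2 = ContactMatrix(dict(CHROMS), 500_000)
        with pytest.raises(ValueError, match="different"):
            matrix_correlation(m1, m2)


class TestMapqClassProfile:
    ANNOTATIONS = [("chr1", 0, 1000, "SINE"), ("chr1", 500, 2000, "LINE"),
                   ("chr2", 0, 500, "SINE")]

    def seg(self, chrom, start, end, mapq, idx=0, rid="r"):
        return AlignedSegment(rid, idx, chrom, start, end, "+", mapq)

    def test_all_mapq60_gives_100_percent_everywhere(self):
        segments = [self.seg("chr1", 100, 300, 60), self.seg("chr2", 10, 50, 60)]
        profile = mapq_class_profile(segments, self.ANNOTATIONS)
        for klass in profile:
            assert all(v == 100.0 for v in profile[klass]["percent_at"].values())

    def test_cutoff_sequence(self):
        profile = mapq_class_profile([self.seg("chr1", 100, 200, 60)],
                                     self.ANNOTATIONS)
        assert list(profile["SINE"]["percent_at"]) == [1, 10, 20, 30, 60]

    def test_percent_non_increasing_with_cutoff(self, rng):
        starts = rng.integers(0, 1900, size=100)
        segments = [self.seg("chr1", int(s), int(s) + 50,
                             int(rng.choice([0, 1, 15, 25, 40, 60])), idx=i)
                    for i, s in enumerate(starts)]
        profile = mapq_class_profile(segments, self.ANNOTATIONS)
        for klass in profile:
            values = list(profile[klass]["percent_at"].values())
            assert all(a >= b for a, b in zip(values, values[1:]))

    def test_any_overlap_rule_and_multi_class(self):
        segment = self.seg("chr1", 999, 1001, 30)  # 1 bp in SINE, 1 bp in LINE
        profile = mapq_class_profile([segment], self.ANNOTATIONS)
        assert profile["SINE"]["n_segments"] == 1
        assert profile["LINE"]["n_segments"] == 1

    def test_empty_class_absent_not_zero(self):
        profile = mapq_class_profile([self.seg("chr1", 100, 200, 30)],
                                     self.ANNOTATIONS + [("chr2", 600, 900, "SD")])
        assert "SD" not in profile

    def test_matches_brute_force_intersection(self, rng):
        segments = []
        for i in range(80):
            start = int(rng.integers(0, 2500))
            segments.append(self.seg("chr1", start, start + 120,
                                     int(rng.choice([0, 5, 30, 60])), idx=i))
        profile = mapq_class_profile(segments, self.ANNOTATIONS)
        for chrom, lo, hi, klass in self.ANNOTATIONS:
            if chrom != "chr1":
                continue
            members = [s for s in segments
                       if max(s.ref_start, lo) < min(s.ref_end, hi)]
            if not members:
                assert klass not in profile
                continue
            for cutoff in (1, 10, 20, 30, 60):
                expected = 100.0 * sum(s.mapq >= cutoff for s in members) / len(members)
                assert profile[klass]["percent_at"][cutoff] == pytest.approx(expected)
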