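"""Contact-matrix model, I/O round trips, merging, ICE and the quality gate."""

import numpy as np
import pytest

from tadvar.hic_core import (
    BinTable,
    ContactMatrix,
    HiCValidationError,
    MatrixParseError,
    coverage_quality_check,
    ice_normalize,
    merge_replicates,
    read_contact_matrix,
    write_contact_matrix,
)


def _random_symmetric_counts(rng, n, lam=5.0):
    upper = rng.poisson(lam, size=(n, n))
    return np.triu(upper) + np.triu(upper, 1).T


@pytest.fixture
def small(rng):
    return ContactMatrix("chr1", 100_000, _random_symmetric_counts(rng, 10))


class TestContactMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(HiCValidationError, match="symmetric"):
            ContactMatrix("chr1", 100_000, np.array([[0, 1], [2, 0]]))

    def test_rejects_negative_and_nonfinite(self):
        with pytest.raises(HiCValidationError):
            ContactMatrix("chr1", 100_000, np.array([[0, -1], [-1, 0]]))
        with pytest.raises(HiCValidationError):
            ContactMatrix("chr1", 100_000, np.array([[np.nan, 1], [1, 0]]))

    def test_marginals_count_diagonal_once(self):
        m = ContactMatrix("chr1", 100_000, np.array([[2, 3], [3, 4]]))
        assert m.marginals().tolist() == [5, 7]
        assert m.marginals(include_diagonal=False).tolist() == [3, 3]


class TestIO:
    def test_sparse_triplet_mirroring(self, tmp_path):
        bins = tmp_path / "bins.bed"
        BinTable.from_grid("chr1", 100_000, 3).to_bed(bins)
        mat = tmp_path / "m.matrix"
        mat.write_text("0\t1\t5\n")
        m = read_contact_matrix(mat, bins)
        assert m.counts[0, 1] == m.counts[1, 0] == 5
        assert m.counts.sum() == 10

    @pytest.mark.parametrize("fmt", ["hicpro_sparse", "dense_tsv"])
    def test_round_trip_integer_exact(self, tmp_path, rng, fmt):
        m = ContactMatrix("chr1", 100_000, _random_symmetric_counts(rng, 10))
        mat, bins = tmp_path / "m.matrix", tmp_path / "m.bed"
        write_contact_matrix(m, mat, bins, format=fmt)
        back = read_contact_matrix(mat, bins, format=fmt, chrom="chr1")
        np.testing.assert_array_equal(back.counts, m.counts)

    def test_round_trip_real_valued(self, tmp_path, rng):
        w = ice_normalize(
            ContactMatrix("chr1", 100_000, _random_symmetric_counts(rng, 8, 20))
        ).matrix
        mat, bins = tmp_path / "w.matrix", tmp_path / "w.bed"
        write_contact_matrix(w, mat, bins)
        back = read_contact_matrix(mat, bins)
        np.testing.assert_allclose(back.counts, w.counts, atol=1e-9)

    def test_zero_matrix_empty_triplet_body(self, tmp_path):
        m = ContactMatrix("chr1", 100_000, np.zeros((4, 4), dtype=int))
        mat = tmp_path / "z.matrix"
        write_contact_matrix(m, mat, tmp_path / "z.bed")
        assert mat.read_text() == ""

    def test_single_entry_single_line(self, tmp_path):
        m = ContactMatrix("chr1", 100_000, np.array([[0, 3], [3, 0]]))
        mat = tmp_path / "s.matrix"
        write_contact_matrix(m, mat, tmp_path / "s.bed")
        assert mat.read_text().splitlines() == ["0\t1\t3"]

    def test_out_of_range_bin_id(self, tmp_path):
        BinTable.from_grid("chr1", 100_000, 3).to_bed(tmp_path / "b.bed")
        (tmp_path / "m.matrix").write_text("0\t7\t2\n")
        with pytest.raises(IndexError, match="bin_id"):
            read_contact_matrix(tmp_path / "m.matrix", tmp_path / "b.bed")

    def test_malformed_line_names_line_number(self, tmp_path):
        BinTable.from_grid("chr1", 100_000, 3).to_bed(tmp_path / "b.bed")
        (tmp_path / "m.matrix").write_text("0\t1\t2\nnot a triplet\n")
        with pytest.raises(MatrixParseError, match="line 2"):
            read_contact_matrix(tmp_path / "m.matrix", tmp_path / "b.bed")


class TestMerge:
    def test_zero_is_identity(self, small):
        zero = small.copy_with(np.zeros_like(small.counts))
        np.testing.assert_array_equal(
            merge_replicates([small, zero]).counts, small.counts
        )

    def test_self_merge_doubles(self, small):
        np.testing.assert_array_equal(
            merge_replicates([small, small]).counts, 2 * small.counts
        )

    def test_sum_of_three(self):
        m = ContactMatrix("chr1", 100_000, np.array([[0, 1], [1, 0]]))
        assert merge_replicates([m, m, m]).counts[0, 1] == 3

    def test_commutative_and_associative(self, rng):
        ms = [
            ContactMatrix("chr1", 100_000, _random_symmetric_counts(rng, 6))
            for _ in range(3)
        ]
        a = merge_replicates([ms[0], merge_replicates([ms[1], ms[2]])])
        b = merge_replicates([merge_replicates([ms[2], ms[0]]), ms[1]])
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_shape_mismatch_and_empty(self, small):
        other = ContactMatrix("chr2", 100_000, np.zeros((10, 10)))
        with pytest.raises(HiCValidationError):
            merge_replicates([small, other])
        with pytest.raises(ValueError):
            merge_replicates([])


class TestICE:
    def test_constant_matrix_already_balanced(self):
        m = ContactMatrix("chr1", 100_000, np.full((5, 5), 4.0))
        res = ice_normalize(m)
        assert res.converged
        s = res.matrix.counts.sum(axis=1)
        np.testing.assert_allclose(s, s[0])
        # proportional to the input
        ratio = res.matrix.counts / m.counts
        np.testing.assert_allclose(ratio, ratio[0, 0])

    def test_two_by_two_scaled_copies_balance_identically(self):
        # hand iteration: off-diagonal a balances to exactly 1 under unit
        # row-sum scaling, independent of a
        m4 = ContactMatrix("chr1", 100_000, np.array([[0.0, 4.0], [4.0, 0.0]]))
        m16 = ContactMatrix("chr1", 100_000, np.array([[0.0, 16.0], [16.0, 0.0]]))
        w4, w16 = ice_normalize(m4).matrix, ice_normalize(m16).matrix
        np.testing.assert_allclose(w4.counts, [[0, 1], [1, 0]], atol=1e-9)
        np.testing.assert_allclose(w4.counts, w16.counts, atol=1e-9)

    def test_zero_row_excluded_and_flagged(self):
        c = np.array([[0, 0, 0], [0, 2, 5], [0, 5, 3]], dtype=float)
        res = ice_normalize(ContactMatrix("chr1", 100_000, c))
        assert res.bias[0] == 1.0
        assert np.all(res.matrix.counts[0] == 0)
        s = res.matrix.counts.sum(axis=1)[1:]
        np.testing.assert_allclose(s, s[0], rtol=1e-5)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            ice_normalize(ContactMatrix("chr1", 100_000, np.zeros((3, 3))))

    def test_symmetry_preserved(self, rng):
        m = ContactMatrix("chr1", 100_000, _random_symmetric_counts(rng, 20, 10))
        w = ice_normalize(m).matrix.counts
        np.testing.assert_allclose(w, w.T)


class TestQualityGate:
    def _matrix_with_marginals(self, margs):
        n = len(margs)
        c = np.zeros((n, n))
        for i, v in enumerate(margs):
            c[i, i] = v  # diagonal-only: marginal equals the diagonal entry
        return ContactMatrix("chr1", 100_000, c)

    def test_nine_of_ten_passing(self):
        r = coverage_quality_check(self._matrix_with_marginals([1001] * 9 + [0]))
        assert r.n_passing_bins == 9
        assert r.fraction_passing == pytest.approx(0.9)
        assert r.passed

    def test_seven_of_ten_fails(self):
        r = coverage_quality_check(self._matrix_with_marginals([1001] * 7 + [0] * 3))
        assert r.fraction_passing == pytest.approx(0.7)
        assert not r.passed

    def test_threshold_is_strict(self):
        r = coverage_quality_check(self._matrix_with_marginals([1000] * 10))
        assert r.n_passing_bins == 0
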