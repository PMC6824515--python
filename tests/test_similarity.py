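"""Similarity measures: boundary Jaccard, VI/TADsim, SCC/HiCRep."""

import warnings

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

import tadvar.similarity as sim
from tadvar.hic_core import ContactMatrix, HiCValidationError
from tadvar.similarity import (
    Partition,
    hicrep_genomewide,
    jaccard_index,
    scc,
    select_h,
    smooth_matrix,
    tadsim,
    variation_of_information,
)
from tadvar.tad_caller import BoundarySet, TADInterval, TADSet

BIN = 100_000


def _bs(positions, chrom="chr1"):
    return BoundarySet(chrom=chrom, positions=np.array(positions, dtype=np.int64))


def _cm(counts):
    return ContactMatrix("chr1", BIN, np.asarray(counts, dtype=float))


def _random_tads(rng, n_bins, min_len=2, max_len=8):
    intervals, pos = [], 0
    while pos < n_bins - min_len:
        pos += int(rng.integers(0, 3))
        length = int(rng.integers(min_len, max_len + 1))
        end = min(pos + length, n_bins)
        if end - pos >= min_len:
            intervals.append(TADInterval(pos, end))
        pos = end
    return TADSet("chr1", BIN, intervals)


class TestJaccard:
    def test_identity(self):
        a = _bs([1, 5, 9])
        assert jaccard_index(a, a) == 1.0

    def test_printed_formula_example(self):
        assert jaccard_index(_bs([5, 10, 15, 20]), _bs([10, 20, 30])) == pytest.approx(
            2 / 5
        )

    def test_disjoint_sets(self):
        assert jaccard_index(_bs([1, 2]), _bs([5, 6])) == 0.0

    def test_both_empty_warns_one(self):
        with pytest.warns(UserWarning):
            assert jaccard_index(_bs([]), _bs([])) == 1.0

    def test_chrom_mismatch(self):
        with pytest.raises(HiCValidationError):
            jaccard_index(_bs([1]), _bs([1], chrom="chr2"))

    @pytest.mark.parametrize("tol", [1, 2, 3])
    def test_tolerant_matching_equals_bipartite_oracle(self, rng, tol):
        for _ in range(50):
            a = np.unique(rng.integers(0, 60, size=rng.integers(1, 15)))
            b = np.unique(rng.integers(0, 60, size=rng.integers(1, 15)))
            adj = (np.abs(a[:, None] - b[None, :]) <= tol).astype(int)
            oracle = int((maximum_bipartite_matching(csr_matrix(adj)) >= 0).sum())
            ji = jaccard_index(_bs(a), _bs(b), tolerance_bins=tol)
            assert ji == pytest.approx(oracle / (len(a) + len(b) - oracle))


def _random_partition(rng, n):
    cuts = np.unique(rng.integers(1, n, size=rng.integers(1, n // 3)))
    labels = np.zeros(n, dtype=np.int64)
    for c in cuts:
        labels[c:] += 1
    return Partition(0, n, labels)


class TestVariationOfInformation:
    def test_identical_partitions(self):
        p = Partition(0, 6, [0, 0, 1, 1, 2, 2])
        assert variation_of_information(p, p) == 0.0

    def test_two_blocks_vs_one_is_ln2(self):
        p = Partition(0, 4, [0, 0, 1, 1])
        q = Partition(0, 4, [0, 0, 0, 0])
        assert variation_of_information(p, q) == pytest.approx(np.log(2), abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(100):
            p, q = _random_partition(rng, 30), _random_partition(rng, 30)
            assert variation_of_information(p, q) == pytest.approx(
                variation_of_information(q, p), abs=1e-12
            )

    def test_window_mismatch_rejected(self):
        with pytest.raises(HiCValidationError):
            variation_of_information(Partition(0, 4, [0] * 4), Partition(1, 5, [0] * 4))

    def test_cut_representation_matches_label_definition(self, rng):
        # the TADsim internals compute VI from cut positions; check that
        # route against the contingency/label definition on random windows
        from tadvar.similarity import _cuts_of, _windows_vi

        n = 40
        for _ in range(100):
            t1, t2 = _random_tads(rng, n), _random_tads(rng, n)
            lo, hi = sorted(rng.choice(np.arange(0, n + 1), 2, replace=False))
            if hi - lo < 2:
                continue
            p = Partition.from_tadset(t1, lo, hi)
            q = Partition.from_tadset(t2, lo, hi)
            vi_labels = variation_of_information(p, q)
            vi_cuts = _windows_vi(
                _cuts_of(t1, n), _cuts_of(t2, n), np.array([lo]), np.array([hi])
            )[0] * np.log(hi - lo)
            assert vi_cuts == pytest.approx(vi_labels, abs=1e-9)


class TestTadsim:
    def test_identical_tiling_full_coverage(self):
        t = TADSet("chr1", BIN, [TADInterval(i, i + 10) for i in range(0, 100, 10)])
        regions, cov = tadsim(t, t, 100, seed=1)
        assert cov == 1.0
        assert regions[0].p_value <= 0.05

    def test_one_empty_set_zero_coverage(self):
        t = TADSet("chr1", BIN, [TADInterval(0, 10)])
        empty = TADSet("chr1", BIN, [])
        assert tadsim(t, empty, 50, seed=1)[1] == 0.0

    def test_both_empty_warns(self):
        empty = TADSet("chr1", BIN, [])
        with pytest.warns(UserWarning):
            assert tadsim(empty, empty, 50, seed=1)[1] == 0.0

    def test_small_null_rejected(self):
        t = TADSet("chr1", BIN, [TADInterval(0, 10)])
        with pytest.raises(ValueError):
            tadsim(t, t, 50, n_null=50, seed=1)

    def test_seed_stability(self):
        rng = np.random.default_rng(5)
        t1, t2 = _random_tads(rng, 200, 4, 14), _random_tads(rng, 200, 4, 14)
        covs = [tadsim(t1, t2, 200, seed=s)[1] for s in range(6)]
        assert max(covs) - min(covs) <= 0.04

    def test_independent_sets_have_low_coverage(self):
        # null calibration: two unrelated simulated partitions should rarely
        # be declared structurally similar anywhere
        from tadvar.synthetic_data import SimParams, sample_tad_partition

        covs = []
        for s in range(20):
            a = sample_tad_partition(SimParams(n_bins=500, seed=100 + s)).tads
            b = sample_tad_partition(SimParams(n_bins=500, seed=200 + s)).tads
            covs.append(tadsim(a, b, 500, seed=s)[1])
        assert np.mean(covs) <= 0.15


class TestSmoothing:
    def test_h_zero_is_identity(self, rng):
        m = _cm(np.eye(5) + np.ones((5, 5)))
        assert smooth_matrix(m, 0) is m

    def test_constant_matrix_unchanged(self):
        m = _cm(np.full((6, 6), 3.0))
        np.testing.assert_allclose(smooth_matrix(m, 2).counts, 3.0)

    def test_center_cell_is_mean_of_nine(self, rng):
        c = rng.poisson(10, size=(3, 3)).astype(float)
        c = 0.5 * (c + c.T)
        sm = smooth_matrix(_cm(c), 1)
        assert sm.counts[1, 1] == pytest.approx(c.mean())

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            smooth_matrix(_cm(np.zeros((3, 3))), -1)


def _random_cm(rng, n, lam=20.0):
    upper = rng.poisson(lam, size=(n, n)).astype(float)
    return _cm(np.triu(upper) + np.triu(upper, 1).T)


class TestSCC:
    def test_self_similarity_is_one(self, rng):
        m = _random_cm(rng, 20)
        assert scc(m, m, h=1) == pytest.approx(1.0, abs=1e-12)

    def test_per_stratum_affine_invariance(self, rng):
        m1 = _random_cm(rng, 15)
        c2 = 2.0 * m1.counts.copy()
        n = m1.n_bins
        for d in range(1, n):  # add a per-stratum constant
            idx = np.arange(n - d)
            c2[idx, idx + d] += 3.0 * d
            c2[idx + d, idx] += 3.0 * d
        assert scc(m1, _cm(c2), h=0) == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_weighted_formula_on_toy(self):
        a = np.array(
            [[0, 1, 5, 2], [1, 0, 3, 7], [5, 3, 0, 4], [2, 7, 4, 0]], dtype=float
        )
        b = np.array(
            [[0, 2, 1, 6], [2, 0, 8, 3], [1, 8, 0, 5], [6, 3, 5, 0]], dtype=float
        )
        num = den = 0.0
        for d in (1, 2):
            x = np.diagonal(a, d)
            y = np.diagonal(b, d)
            r = np.corrcoef(x, y)[0, 1]
            w = len(x) * x.std() * y.std()
            num += w * r
            den += w
        assert scc(_cm(a), _cm(b), h=0, max_dist_bins=2) == pytest.approx(num / den)

    def test_degenerate_strata_rejected(self):
        m = _cm(np.full((4, 4), 2.0))
        with pytest.raises(ValueError, match="strata"):
            scc(m, m, h=0)


class TestSelectH:
    def test_constant_scc_gives_h0(self, rng, monkeypatch):
        monkeypatch.setattr(sim, "scc", lambda *a, **k: 0.8)
        assert select_h(None, None) == 0

    def test_convergence_rule(self, monkeypatch):
        values = {0: 0.50, 1: 0.55, 2: 0.555, 3: 0.556}
        monkeypatch.setattr(sim, "scc", lambda m1, m2, h, md=None: values[h])
        assert select_h(None, None) == 1

    def test_no_convergence_returns_max_with_warning(self, monkeypatch):
        values = {0: 0.1, 1: 0.3, 2: 0.5, 3: 0.7}
        monkeypatch.setattr(sim, "scc", lambda m1, m2, h, md=None: values[h])
        with pytest.warns(UserWarning):
            assert select_h(None, None) == 3

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_h(None, None, h_range=[])


class TestGenomewide:
    def test_single_chromosome(self):
        assert hicrep_genomewide([0.73]) == pytest.approx(0.73)

    def test_mean_of_two(self):
        assert hicrep_genomewide([0.8, 0.6]) == pytest.approx(0.7)

    def test_identical_pairs_give_one(self, rng):
        ms = [_random_cm(rng, 12) for _ in range(3)]
        assert hicrep_genomewide([(m, m) for m in ms], h=1) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hicrep_genomewide([])
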