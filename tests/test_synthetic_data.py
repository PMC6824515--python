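"""Synthetic cohort generator: planted partitions, Poisson matrices,
boundary perturbation and cohort assembly."""

import numpy as np
import pytest

from tadvar.hic_core import coverage_quality_check
from tadvar.similarity import jaccard_index
from tadvar.synthetic_data import (
    CellTypeSpec,
    CohortConfig,
    SampleSpec,
    SimParams,
    make_cohort,
    min_depth_for_quality,
    perturb_partition,
    replicate_cohort_config,
    sample_tad_partition,
    simulate_contact_matrix,
    write_cohort,
)
from tadvar.tad_caller import boundaries_of


class TestPlantedPartition:
    def test_same_seed_reproduces(self):
        p = SimParams(n_bins=400, seed=3)
        a, b = sample_tad_partition(p), sample_tad_partition(p)
        assert np.array_equal(a.labels, b.labels)

    def test_median_length_near_target(self):
        medians = []
        for seed in range(50):
            p = SimParams(n_bins=5000, seed=seed)
            s = sample_tad_partition(p)
            medians.append(np.median(s.tads.lengths_bins))
        assert np.mean(medians) == pytest.approx(8.8, rel=0.15)

    def test_intervals_sorted_non_overlapping(self):
        s = sample_tad_partition(SimParams(n_bins=600, seed=11))
        ivs = s.tads.intervals
        assert all(a.end_bin <= b.start_bin for a, b in zip(ivs, ivs[1:]))

    def test_chromosome_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_tad_partition(SimParams(n_bins=10, seed=0))


class TestSimulatedMatrix:
    def test_zero_depth_gives_zero_matrix(self):
        p = SimParams(n_bins=100, depth=0.0, seed=0)
        m = simulate_contact_matrix(sample_tad_partition(p), p)
        assert m.counts.sum() == 0

    def test_background_decay_monotone(self):
        p = SimParams(n_bins=120, depth=200.0, seed=0)
        sums = np.zeros(20)
        counts = np.zeros(20)
        for seed in range(20):
            pp = SimParams(n_bins=120, depth=200.0, seed=seed)
            s = sample_tad_partition(pp)
            m = simulate_contact_matrix(s, pp)
            same = (s.labels[:, None] == s.labels[None, :]) & (s.labels[:, None] >= 0)
            for d in range(1, 21):
                diag = np.diagonal(m.counts, d).astype(float)
                background = ~np.diagonal(same, d)
                sums[d - 1] += diag[background].sum()
                counts[d - 1] += background.sum()
        means = sums / counts
        assert np.all(np.diff(means) < 0)

    def test_within_tad_enrichment_matches_beta(self):
        p = SimParams(n_bins=300, depth=2000.0, tad_enrichment=2.0, seed=4)
        s = sample_tad_partition(p)
        m = simulate_contact_matrix(s, p)
        same = (s.labels[:, None] == s.labels[None, :]) & (s.labels[:, None] >= 0)
        ratios = []
        for d in range(1, 6):
            diag = np.diagonal(m.counts, d).astype(float)
            mask = np.diagonal(same, d)
            if mask.sum() > 10 and (~mask).sum() > 10:
                ratios.append(diag[mask].mean() / diag[~mask].mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.10)

    def test_quality_gate_passes_at_calibrated_depth(self):
        depth = min_depth_for_quality(300)
        p = SimParams(n_bins=300, depth=depth, seed=1)
        m = simulate_contact_matrix(sample_tad_partition(p), p)
        assert coverage_quality_check(m).passed


class TestPerturbation:
    def test_rate_zero_is_identity(self):
        s = sample_tad_partition(SimParams(n_bins=400, seed=2))
        out = perturb_partition(s, 0.0, seed=9)
        assert np.array_equal(
            boundaries_of(out.tads).positions, boundaries_of(s.tads).positions
        )

    def test_full_rate_diverges_substantially(self):
        jis = []
        for seed in range(20):
            s = sample_tad_partition(SimParams(n_bins=500, seed=seed))
            out = perturb_partition(s, 1.0, seed=1000 + seed)
            jis.append(
                jaccard_index(boundaries_of(s.tads), boundaries_of(out.tads))
            )
        assert np.mean(jis) < 0.5

    def test_output_invariants_hold(self):
        for seed in range(100):
            s = sample_tad_partition(SimParams(n_bins=200, seed=seed % 7))
            out = perturb_partition(s, 0.5, seed=seed)
            ivs = out.tads.intervals
            assert all(iv.length_bins >= 2 for iv in ivs)
            assert all(a.end_bin <= b.start_bin for a, b in zip(ivs, ivs[1:]))
            assert all(0 <= iv.start_bin and iv.end_bin <= 200 for iv in ivs)

    def test_invalid_rate_rejected(self):
        s = sample_tad_partition(SimParams(n_bins=200, seed=0))
        with pytest.raises(ValueError):
            perturb_partition(s, 1.5, seed=0)


class TestCohort:
    def test_counts_match_config(self):
        cohort = make_cohort(replicate_cohort_config(n_types=10, n_replicates=2))
        assert len(cohort.samples) == 10
        assert sum(len(s.replicates) for s in cohort.samples) == 20
        assert len(cohort.all_meta()) == 20

    def test_replicates_share_truth_and_differ_in_counts(self):
        cohort = make_cohort(replicate_cohort_config(n_types=2, seed=5))
        s = cohort.samples[0]
        assert len({id(r) for r in s.replicates}) == 2
        assert not np.array_equal(s.replicates[0].counts, s.replicates[1].counts)
        np.testing.assert_array_equal(s.truth.labels, s.truth.labels)

    def test_same_seed_bitwise_identical(self, tmp_path):
        cfg = replicate_cohort_config(n_types=3, n_bins=150, seed=21)
        a = make_cohort(cfg)
        b = make_cohort(replicate_cohort_config(n_types=3, n_bins=150, seed=21))
        for sa, sb in zip(a.samples, b.samples):
            for ra, rb in zip(sa.replicates, sb.replicates):
                np.testing.assert_array_equal(ra.counts, rb.counts)
        write_cohort(a, tmp_path / "x")
        write_cohort(b, tmp_path / "y")
        fa = (tmp_path / "x" / a.samples[0].sample_id / "rep0.matrix").read_bytes()
        fb = (tmp_path / "y" / b.samples[0].sample_id / "rep0.matrix").read_bytes()
        assert fa == fb

    def test_zero_perturbation_shares_partition_across_types(self):
        cohort = make_cohort(
            replicate_cohort_config(n_types=3, perturb_rate=0.0, seed=4)
        )
        base = cohort.samples[0].truth.labels
        for s in cohort.samples[1:]:
            np.testing.assert_array_equal(s.truth.labels, base)

    def test_invalid_replicate_count_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(
                cell_types=[CellTypeSpec("x", [SampleSpec(n_replicates=0)])],
            )

    def test_written_cohort_has_metadata_and_truth(self, tmp_path):
        cohort = make_cohort(replicate_cohort_config(n_types=2, n_bins=150, seed=3))
        manifest = write_cohort(cohort, tmp_path)
        assert (tmp_path / "metadata.tsv").exists()
        for entry in manifest["samples"].values():
            assert all(
                (tmp_path / p["matrix"].split("/")[-2] / p["matrix"].split("/")[-1]).exists()
                for p in entry["replicates"]
            )


def test_depth_calibration_formula():
    # the edge bin has the smallest expected marginal; at the calibrated
    # depth its mean marginal is safety * min_contacts
    depth = min_depth_for_quality(500, safety=1.5)
    edge = depth * np.sum((1.0 + np.arange(500)) ** -1.0)
    assert edge == pytest.approx(1500.0)
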