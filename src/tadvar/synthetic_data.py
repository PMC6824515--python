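"""Synthetic Hi-C cohorts with planted TAD structure.

The generator emulates the statistical structure of a multi-study Hi-C
corpus so that every pipeline stage is testable without downloads:

* binned symmetric count matrices with power-law distance decay
  ``E[c_ij] = depth * (1 + |i-j|)**-alpha``,
* block-enriched planted TADs (within-TAD means multiplied by ``beta``),
  lengths log-normal with the distribution median pinned to 880 kb,
* Poisson sequencing noise — replicates are independent resamples of the
  same mean matrix,
* boundary perturbations between "cell types" (shift / delete / split
  edits applied to a shared root partition),
* a protocol effect on long-range contacts: dilution-protocol samples have
  a fraction ``1 - protocol_longrange_factor`` of their long-range mean
  replaced by a protocol-shared log-normal remodeling field, so samples of
  the same protocol share long-range structure that cross-protocol pairs
  do not (a constant attenuation alone would be invisible to per-stratum
  correlation measures),
* restriction enzyme and lab as metadata-only factors by default,
  emulating robustness of structure to those variables.

All randomness flows from a single cohort seed through named
``numpy.random.SeedSequence`` substreams; identical configs and seeds give
bitwise-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hic_core import ContactMatrix, merge_replicates, write_contact_matrix
from .stats_compare import SampleMeta
from .tad_caller import TADInterval, TADSet, write_tads_bed

__all__ = [
    "SimParams",
    "PlantedStructure",
    "SampleSpec",
    "CellTypeSpec",
    "CohortConfig",
    "SimSample",
    "Cohort",
    "sample_tad_partition",
    "simulate_contact_matrix",
    "perturb_partition",
    "make_cohort",
    "write_cohort",
    "min_depth_for_quality",
    "replicate_cohort_config",
    "protocol_cohort_config",
]

_SIGMA_LOG_TAD = 0.5  # log-normal shape of TAD lengths
_GAP_PROB = 0.1
_GAP_MEAN_BINS = 2.0
_PROTOCOL_FIELD_SIGMA = 0.5


@dataclass
class SimParams:
    """Parameters of the per-chromosome Hi-C simulator.

    ``depth`` scales expected counts (the near-diagonal mean per entry);
    ``decay_exponent`` is the power-law exponent of the distance decay;
    ``tad_enrichment`` multiplies within-TAD means; the protocol factor
    weighs how much of the long-range (beyond ``longrange_cutoff_bins``)
    mean is retained versus replaced by protocol-specific structure.
    """

    n_bins: int = 300
    bin_size: int = 100_000
    decay_exponent: float = 1.0
    tad_enrichment: float = 2.0
    depth: float = 250.0
    median_tad_bases: int = 880_000
    boundary_perturb_rate: float = 0.3
    protocol_longrange_factor: float = 0.7
    longrange_cutoff_bins: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_bins < 1:
            problems.append("n_bins must be >= 1")
        if self.bin_size < 1:
            problems.append("bin_size must be >= 1")
        if self.decay_exponent <= 0:
            problems.append("decay_exponent must be > 0")
        if self.tad_enrichment <= 1:
            problems.append("tad_enrichment must be > 1")
        if self.depth < 0:
            problems.append("depth must be >= 0")
        if self.median_tad_bases < self.bin_size:
            problems.append("median_tad_bases must be >= bin_size")
        if not (0 <= self.boundary_perturb_rate <= 1):
            problems.append("boundary_perturb_rate must be in [0, 1]")
        if not (0 < self.protocol_longrange_factor <= 1):
            problems.append("protocol_longrange_factor must be in (0, 1]")
        if self.longrange_cutoff_bins < 1:
            problems.append("longrange_cutoff_bins must be >= 1")
        if problems:
            raise ValueError("invalid SimParams: " + "; ".join(problems))

    @property
    def median_tad_bins(self) -> float:
        return self.median_tad_bases / self.bin_size


@dataclass
class PlantedStructure:
    """Ground-truth TAD partition of a simulated chromosome."""

    tads: TADSet
    labels: np.ndarray  # per-bin TAD id, -1 for gap bins

    @classmethod
    def from_tadset(cls, tads: TADSet, n_bins: int) -> "PlantedStructure":
        labels = np.full(n_bins, -1, dtype=np.int64)
        for k, iv in enumerate(tads.intervals):
            labels[iv.start_bin : iv.end_bin] = k
        return cls(tads=tads, labels=labels)

    @property
    def n_bins(self) -> int:
        return len(self.labels)


def sample_tad_partition(
    p: SimParams, rng: np.random.Generator | None = None
) -> PlantedStructure:
    """Draw a planted TAD partition with log-normal domain lengths.

    Lengths are i.i.d. log-normal with distribution median equal to the
    target median TAD size (sigma_log = 0.5, so the sampled-median check is
    meaningful at realistic chromosome lengths); domains are laid
    left-to-right with occasional geometric gaps and truncated at the
    chromosome end.
    """
    if p.n_bins < 2 * p.median_tad_bins:
        raise ValueError(
            f"n_bins={p.n_bins} too small for median TAD of {p.median_tad_bins} bins"
        )
    rng = np.random.default_rng(p.seed) if rng is None else rng
    mu_log = np.log(p.median_tad_bins)
    intervals: list[TADInterval] = []
    pos = 0
    while pos < p.n_bins:
        if rng.random() < _GAP_PROB:
            pos += int(rng.geometric(1.0 / _GAP_MEAN_BINS))
        length = max(2, int(round(rng.lognormal(mu_log, _SIGMA_LOG_TAD))))
        end = min(pos + length, p.n_bins)
        if end - pos >= 2:
            intervals.append(TADInterval(pos, end))
        pos = end
    tads = TADSet(chrom="chrS", bin_size=p.bin_size, intervals=intervals)
    return PlantedStructure.from_tadset(tads, p.n_bins)


def _mean_matrix(
    labels: np.ndarray,
    p: SimParams,
    protocol: str = "in_situ",
    protocol_field: np.ndarray | None = None,
) -> np.ndarray:
    n = len(labels)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    decay = p.depth * (1.0 + d) ** (-p.decay_exponent)
    same_tad = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    mu = np.where(same_tad, p.tad_enrichment * decay, decay)
    f = p.protocol_longrange_factor
    if protocol == "dilution" and f < 1.0 and protocol_field is not None:
        lr = d > p.longrange_cutoff_bins
        mu = np.where(lr, f * mu + (1.0 - f) * decay * protocol_field, mu)
    return mu


def _protocol_field(n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Symmetric unit-mean log-normal remodeling field shared by a protocol."""
    g = rng.lognormal(
        mean=-0.5 * _PROTOCOL_FIELD_SIGMA**2,
        sigma=_PROTOCOL_FIELD_SIGMA,
        size=(n_bins, n_bins),
    )
    return np.triu(g) + np.triu(g, 1).T


def simulate_contact_matrix(
    s: PlantedStructure,
    p: SimParams,
    rng: np.random.Generator | None = None,
    protocol: str = "in_situ",
    protocol_field: np.ndarray | None = None,
) -> ContactMatrix:
    """Poisson-sample a contact matrix around the planted mean structure."""
    rng = np.random.default_rng(p.seed) if rng is None else rng
    mu = _mean_matrix(s.labels, p, protocol, protocol_field)
    n = mu.shape[0]
    upper = rng.poisson(np.triu(mu))
    counts = np.triu(upper) + np.triu(upper, 1).T
    return ContactMatrix(chrom=s.tads.chrom, bin_size=p.bin_size, counts=counts)


def perturb_partition(
    s: PlantedStructure, rate: float, seed: int | np.random.Generator | None = None
) -> PlantedStructure:
    """Randomly edit TAD boundaries to emulate between-cell-type divergence.

    Each interior boundary independently, with probability ``rate``, is
    shifted by 1–3 bins, deleted (merging the adjacent blocks) or split
    (inserting a new boundary in the adjacent domain), with equal
    probability.  Edits that would violate the minimum domain length of 2
    bins are skipped.  ``rate == 0`` returns an identical structure.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = s.n_bins
    intervals = [[iv.start_bin, iv.end_bin] for iv in s.tads.intervals]
    if rate > 0:
        original_bounds = sorted(
            {b for iv in intervals for b in iv if 0 < b < n_bins}
        )
        for b in original_bounds:
            if rng.random() >= rate:
                continue
            action = rng.choice(["shift", "delete", "split"])
            left = next((iv for iv in intervals if iv[1] == b), None)
            right = next((iv for iv in intervals if iv[0] == b), None)
            if left is None and right is None:
                continue  # boundary removed by an earlier edit
            if action == "shift":
                delta = int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                nb = b + delta
                ok = 0 < nb < n_bins
                if left is not None:
                    ok = ok and nb - left[0] >= 2
                if right is not None:
                    ok = ok and right[1] - nb >= 2
                    prev = next((iv for iv in intervals if iv[1] <= b and iv is not right
                                 and iv[1] > nb), None)
                    ok = ok and prev is None
                if left is not None:
                    nxt = next((iv for iv in intervals if iv[0] >= b and iv is not left
                                and iv[0] < nb), None)
                    ok = ok and nxt is None
                if ok:
                    if left is not None:
                        left[1] = nb
                    if right is not None:
                        right[0] = nb
            elif action == "delete":
                if left is not None and right is not None:
                    left[1] = right[1]
                    intervals.remove(right)
                elif left is not None:
                    nxt_starts = [iv[0] for iv in intervals if iv[0] >= left[1]]
                    left[1] = min(nxt_starts) if nxt_starts else n_bins
                elif right is not None:
                    prev_ends = [iv[1] for iv in intervals if iv[1] <= right[0]]
                    right[0] = max(prev_ends) if prev_ends else 0
            else:  # split the adjacent domain
                target = right if right is not None else left
                if target[1] - target[0] >= 4:
                    cut = int(rng.integers(target[0] + 2, target[1] - 1))
                    intervals.remove(target)
                    intervals.append([target[0], cut])
                    intervals.append([cut, target[1]])
            intervals.sort()
    tads = TADSet(
        chrom=s.tads.chrom,
        bin_size=s.tads.bin_size,
        intervals=[TADInterval(a, b) for a, b in sorted(intervals)],
    )
    return PlantedStructure.from_tadset(tads, n_bins)


def min_depth_for_quality(
    n_bins: int,
    decay_exponent: float = 1.0,
    min_contacts: int = 1000,
    safety: float = 1.5,
) -> float:
    """Depth at which even the shallowest (edge) bin clears the coverage gate.

    The minimum marginal belongs to bin 0 (one-sided decay); the returned
    depth makes its expected marginal ``safety * min_contacts``.
    """
    edge_marginal = np.sum((1.0 + np.arange(n_bins)) ** (-decay_exponent))
    return float(safety * min_contacts / edge_marginal)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    """One biological sample of a cell type (possibly several replicates)."""

    protocol: str = "in_situ"
    enzyme: str = "HindIII"
    lab: str = "lab1"
    n_replicates: int = 2
    donor_id: str = ""
    family_relation: str = "none"
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class CellTypeSpec:
    name: str
    samples: list[SampleSpec] = field(default_factory=lambda: [SampleSpec()])
    is_tissue: bool = False


@dataclass
class CohortConfig:
    """Full specification of a simulated cohort (one chromosome)."""

    cell_types: list[CellTypeSpec]
    sim: SimParams = field(default_factory=SimParams)
    seed: int = 0


@dataclass
class SimSample:
    sample_id: str
    cell_type: str
    meta: list[SampleMeta]  # one row per replicate
    replicates: list[ContactMatrix]
    truth: PlantedStructure

    def merged(self) -> ContactMatrix:
        return merge_replicates(self.replicates)


@dataclass
class Cohort:
    config: CohortConfig
    samples: list[SimSample]
    root_truth: PlantedStructure

    @property
    def n_bins(self) -> int:
        return self.root_truth.n_bins

    @property
    def bin_size(self) -> int:
        return self.config.sim.bin_size

    def all_meta(self) -> list[SampleMeta]:
        return [m for s in self.samples for m in s.meta]

    def sample(self, sample_id: str) -> SimSample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def make_cohort(config: CohortConfig) -> Cohort:
    """Simulate a cohort: shared root partition, per-type perturbations,
    per-sample mean matrices, per-replicate Poisson resamples.

    Substream layout (from the cohort seed): [0] root partition,
    [1] dilution-protocol remodeling field, [2 + t] perturbation of cell
    type t, then one stream per (sample, replicate) in declaration order.
    """
    if not config.cell_types:
        raise ValueError("cohort needs at least one cell type")
    p = config.sim
    n_types = len(config.cell_types)
    n_rep_streams = sum(
        spec.n_replicates for ct in config.cell_types for spec in ct.samples
    )
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(2 + n_types + n_rep_streams)
    rng_root = np.random.default_rng(streams[0])
    rng_field = np.random.default_rng(streams[1])

    root = sample_tad_partition(p, rng_root)
    needs_field = p.protocol_longrange_factor < 1.0 and any(
        spec.protocol == "dilution" for ct in config.cell_types for spec in ct.samples
    )
    field_mat = _protocol_field(p.n_bins, rng_field) if needs_field else None

    samples: list[SimSample] = []
    rep_stream_idx = 2 + n_types
    for t, ct in enumerate(config.cell_types):
        rng_perturb = np.random.default_rng(streams[2 + t])
        truth = perturb_partition(root, p.boundary_perturb_rate, rng_perturb)
        for si, spec in enumerate(ct.samples):
            sample_id = f"{ct.name}_s{si}"
            mu = _mean_matrix(truth.labels, p, spec.protocol, field_mat)
            reps: list[ContactMatrix] = []
            meta: list[SampleMeta] = []
            for ri in range(spec.n_replicates):
                rng_rep = np.random.default_rng(streams[rep_stream_idx])
                rep_stream_idx += 1
                upper = rng_rep.poisson(np.triu(mu))
                counts = np.triu(upper) + np.triu(upper, 1).T
                reps.append(
                    ContactMatrix(chrom=truth.tads.chrom, bin_size=p.bin_size, counts=counts)
                )
                meta.append(
                    SampleMeta(
                        sample_id=sample_id,
                        cell_type=ct.name,
                        is_tissue=ct.is_tissue,
                        donor_id=spec.donor_id or sample_id,
                        protocol=spec.protocol,
                        restriction_enzyme=spec.enzyme,
                        lab=spec.lab,
                        family_relation=spec.family_relation,
                        family_id=spec.family_id,
                        replicate_index=ri,
                    )
                )
            samples.append(
                SimSample(
                    sample_id=sample_id,
                    cell_type=ct.name,
                    meta=meta,
                    replicates=reps,
                    truth=truth,
                )
            )
    return Cohort(config=config, samples=samples, root_truth=root)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Emit HiC-Pro sparse + BED per replicate, truth TADs, metadata TSV.

    Returns a manifest dict of written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"samples": {}, "metadata": str(outdir / "metadata.tsv")}
    meta_rows = []
    for s in cohort.samples:
        sdir = outdir / s.sample_id
        sdir.mkdir(exist_ok=True)
        entry = {"replicates": [], "truth_bed": str(sdir / "truth_tads.bed")}
        for ri, m in enumerate(s.replicates):
            mpath = sdir / f"rep{ri}.matrix"
            bpath = sdir / f"rep{ri}.bed"
            write_contact_matrix(m, mpath, bpath, format="hicpro_sparse")
            entry["replicates"].append({"matrix": str(mpath), "bins": str(bpath)})
        write_tads_bed(s.truth.tads, entry["truth_bed"])
        manifest["samples"][s.sample_id] = entry
        for meta in s.meta:
            meta_rows.append(asdict(meta))
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    with open(outdir / "cohort_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Standard cohort designs
# ---------------------------------------------------------------------------


def replicate_cohort_config(
    n_types: int = 10,
    n_replicates: int = 2,
    perturb_rate: float = 0.3,
    n_bins: int = 300,
    depth: float = 250.0,
    seed: int = 7,
    protocol: str = "in_situ",
) -> CohortConfig:
    """Replicate-vs-cell-type design: one sample per type, shared protocol."""
    sim = SimParams(n_bins=n_bins, depth=depth, boundary_perturb_rate=perturb_rate)
    types = [
        CellTypeSpec(
            name=f"type{t:02d}",
            samples=[SampleSpec(protocol=protocol, n_replicates=n_replicates, lab=f"lab{t % 3}")],
        )
        for t in range(n_types)
    ]
    return CohortConfig(cell_types=types, sim=sim, seed=seed)


def protocol_cohort_config(
    n_bins: int = 300,
    depth: float = 250.0,
    perturb_rate: float = 0.3,
    factor: float = 0.7,
    seed: int = 9,
) -> CohortConfig:
    """Protocol-effect design: 12 cell types x 2 single-replicate samples.

    Types 0-2 pair two in-situ samples, types 3-5 two dilution samples and
    types 6-11 one of each, so half the cohort's samples are dilution and
    same-cell-type pairs split into single-protocol and mixed-protocol
    groups of equal size.
    """
    sim = SimParams(
        n_bins=n_bins,
        depth=depth,
        boundary_perturb_rate=perturb_rate,
        protocol_longrange_factor=factor,
    )
    types = []
    for t in range(12):
        if t < 3:
            protos = ("in_situ", "in_situ")
        elif t < 6:
            protos = ("dilution", "dilution")
        else:
            protos = ("in_situ", "dilution")
        types.append(
            CellTypeSpec(
                name=f"ptype{t:02d}",
                samples=[
                    SampleSpec(protocol=pr, n_replicates=1, lab=f"lab{i}")
                    for i, pr in enumerate(protos)
                ],
            )
        )
    return CohortConfig(cell_types=types, sim=sim, seed=seed)
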