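# Methods

This note documents the models, estimators and numerical choices behind
`tadvar`, and what the simulation-based validation does and does not
establish.

## Contact matrices and preprocessing

All analyses operate on symmetric, non-negative intra-chromosomal contact
matrices over fixed-width bins (default 100 kb). Bins are 0-based and
genomic coordinates 0-based half-open (BED convention). Replicates of a
sample are merged by entrywise summation before cross-sample comparison,
mirroring the practice of pooling aligned reads for optimal coverage;
replicate-pair comparisons use the individual replicate matrices.

**Coverage gate.** A sample is analysable at a given resolution when at
least 80% of bins have more than 1000 contacts (strict inequality). A bin's
contact total is its row marginal with the diagonal counted once; whether
the diagonal is included is configurable (`include_diagonal`) because the
coverage notion is convention, not physics.

**ICE balancing.** Iterative correction factorises observed counts as
`counts[i,j] = bias_i · bias_j · W[i,j]` and iterates `bias ← bias · s/s̄`
(`s` the current row sums over non-zero-marginal bins) until the maximum
relative change of the bias vector drops below `tol` (default 1e-6,
`max_iter` 200). On convergence the row-sum coefficient of variation is
below `tol` by construction, because convergence is checked before the
final update. The balanced matrix is rescaled to unit mean row sum.
All-zero rows (unmappable bins) are excluded from balancing, keep bias 1
and stay zero. Non-convergence warns and returns the partial result with a
flag rather than raising: a cohort run should not abort on one pathological
chromosome.

## TAD calling

The caller scores candidate domains by scaled density

    q_γ(k, l) = S(k, l) / (l − k + 1)^γ ,

where `S(k, l)` is the sum of contacts strictly above the diagonal within
block `[k, l]`, and centres scores per domain length:
`q′(k, l) = q_γ(k, l) − mean over all intervals of the same length`.
Centring gives the objective a natural zero — only intervals denser than
the average interval of their length can contribute — so the dynamic
program

    OPT(l) = max( OPT(l−1), max_k { OPT(k−1) + q′(k, l) : q′(k, l) > 0 } )

returns the maximum-total-quality set of non-overlapping domains with gaps
allowed. The DP optimum is verified against exhaustive tree-search
enumeration on small random matrices in the test suite. Minimum domain
length is 2 bins (a one-bin domain has no internal contacts); the maximum
domain span defaults to 3 Mb for tractability. Both are configurable.

**γ selection.** γ trades domain size against density; it has no intrinsic
scale, so it is selected per sample (and per chromosome) by sweeping
γ ∈ {0.0, 0.1, …, 1.0} and keeping the TAD set whose median domain length
is closest to a target — 880 kb by default, the expected median TAD size at
this resolution. Ties break toward smaller γ. Empty TAD sets (median
defined as 0) are only eligible when every γ produced an empty set, in
which case no TADs are callable and an error is raised. The robustness
sweep repeats all TAD-level comparisons for targets of 500 kb, 700 kb,
880 kb and 1 Mb; only boundary Jaccard and TADsim participate because the
stratum-adjusted correlation operates on the full matrix and is independent
of the TAD-size target.

## Similarity measures

**Boundary Jaccard.** TAD boundaries are the deduplicated start/end bin
positions; `JI = |A ∩ B| / |A ∪ B|`. With a positive bin tolerance the
intersection is the maximum one-to-one matching of boundaries within the
tolerance (greedy sweep; optimal because the compatibility graph of two
sorted point sets under a distance threshold is convex — cross-checked
against a generic bipartite-matching solver in the tests). Two empty sets
score 1.0 with a warning, so cohort pipelines survive empty chromosomes.
Default tolerance is 0 (exact sharing at 100-kb bins).

**Variation of information.** Partitions label each TAD as one block and
each maximal non-TAD gap run as its own background block.
`VI = H(P) + H(Q) − 2 I(P, Q)` in nats; it is a metric on partitions
(identity, symmetry, triangle inequality — property-tested). Because all
blocks are contiguous, a partition restricted to a window is fully
described by its cut positions and
`VI = 2 H(joint segments) − H(P) − H(Q)`, which the implementation
evaluates for every candidate window from prefix sums of
`len · ln(len)` over segments — the identity is cross-checked against the
label/contingency definition on random windows.

**TADsim.** The fraction of the TAD-covered genome lying in windows where
the two partitions are significantly more similar (lower normalised local
VI) than randomly placed TADs with the same length multisets:

1. Candidate windows run from one boundary of either set to a later one,
   spanning at most 3 positions of the combined boundary list
   (`max_boundary_steps`) and at least 5 bins (`min_window_bins`). The
   boundary-step cap keeps windows local — one to a few domain
   neighbourhoods — at any TAD length scale; without it, long windows are
   trivially significant for any pair with global similarity and the
   statistic saturates at 1.0. Windows in which either partition has no
   interior boundary are excluded: with nothing to compare, both sides
   clip to a single block and VI is vacuously 0.
2. Each window's VI is normalised by `ln(window length)` for comparability
   across scales.
3. The null preserves each input's TAD-length multiset and gap statistics:
   random placements are drawn left-to-right with a uniform phase offset,
   and null windows are sampled by the same boundary-pair construction as
   the candidates (including the interior-structure filter). Matching the
   construction matters: comparing boundary-anchored observed windows
   against unanchored null windows biases every p-value. Null VI values
   pool across placements into log-spaced window-length buckets; sparse
   buckets widen to neighbours until they hold at least 200 draws so the
   attainable p-value floor stays below usual significance levels.
4. Per-window empirical p-values use a strict inequality,
   `p = (1 + #{null < obs}) / (1 + pool)`, so a perfect VI of 0 is always
   significant. Because the candidate family is quadratic in the boundary
   count and highly overlapping, Benjamini–Hochberg false-discovery
   control is applied across windows before thresholding at `alpha`
   (default 0.05).
5. Significant windows are unioned and intersected with the TAD-covered
   territory; coverage is that bin count divided by the TAD-covered bin
   count. Overlapping significant windows are also merged into maximal
   structurally-similar regions for reporting.

Calibration behaviour (seeded, reproduced by the tests and acceptance
script): identical partitions score exactly 1.0; independent random
partitions average ≈ 0.14 coverage (20 draws, 500 bins); pairs of noisy
calls of the same structure score near 1; cross-cell-type pairs fall in
between. `n_null` defaults to 1000 placements (minimum 100).

**Stratum-adjusted correlation.** Both matrices are smoothed by a
`(2h+1)²` mean filter (edge-clipped, so border means use in-bounds cells
only), entries are stratified by diagonal offset `d = 1 … max_dist`
(diagonal excluded; `max_dist` defaults to 5 Mb), and per-stratum Pearson
correlations ρ_d combine as `Σ w_d ρ_d / Σ w_d` with
`w_d = N_d σ1_d σ2_d`. Zero-variance strata are skipped; if all strata are
degenerate the pair is not scorable and an error is raised. The smoothing
parameter is the smallest `h` in 0..3 with `|SCC(h+1) − SCC(h)| < 0.01`;
without convergence the range maximum is used with a warning. Genome-wide
scores are unweighted means over chromosomes.

## Group comparisons

Every unordered sample pair carries group labels (replicate, same cell
type, same tissue across donors, protocol/enzyme/lab agreement, trio
relation) and its three similarity scores. Distribution contrasts use the
Mann–Whitney U test, two-sided by default with the direction of the shift
reported; raw p-values are reported (Benjamini–Hochberg across contrasts is
available but off by default). Empty groups produce per-contrast error
records rather than aborting the suite.

**Exact vs approximate p.** For tie-free data with `n_a + n_b ≤ 12` the
exact null distribution is used. Beyond that, p-values come from a hybrid
approximation to the exact lattice null of U: a Lugannani–Rice saddlepoint
tail with lattice continuity correction built on the closed-form cumulant
generating function of the rank sum (the Gaussian-binomial product
`K(t) = Σ_i φ(t(n+i)) − φ(t·i)` with `φ(x) = ln((e^x − 1)/x)`), an
Edgeworth expansion near the centre using the exact cumulants
`κ₄ = −mn(N+1)(m² + mn + n² + m + n)/120` and the analogous κ₆ (both
derived symbolically and verified against enumeration), and the closed-form
boundary atom `P(U ≥ mn) = 1/C(N, m)`. Measured against full enumeration,
the two-sided error of this approximation is ≤ 0.002 everywhere on its
usage domain (`N ≥ 13`) and ≤ 0.013 even at `n_a = n_b = 3`, where the
null has only 20 atoms and the remaining error is lattice granularity, not
approximation bias. With ties, the tie-corrected normal approximation with
continuity correction is used.

## The synthetic cohort generator

The generator emulates the statistical structure of a multi-study Hi-C
corpus; it is the ground-truth harness for every pipeline stage.

* **Background**: `E[c_ij] = depth · (1 + |i − j|)^(−α)` with α = 1, the
  canonical contact-probability decay at the 0.1–5 Mb scale.
* **TADs**: lengths i.i.d. log-normal with distribution median pinned to
  880 kb and σ_log = 0.5 (the one heavy-tailed positive law with an
  explicit median), laid left-to-right with gap probability 0.1 and
  geometric gap lengths (mean 2 bins); within-TAD means are multiplied by
  β = 2.
* **Replicates**: independent Poisson resamples of the same mean matrix —
  the simplest count model for resequencing one library population (a
  negative-binomial overdispersion knob is deliberately absent: measured
  contrasts here concern structure, not dispersion).
* **Cell types**: each type's partition is an independently perturbed copy
  of one root partition; each interior boundary is, with the configured
  rate, shifted by 1–3 bins, deleted or split with equal probability.
* **Protocol effect**: dilution-protocol samples have their long-range
  (> 1 Mb) mean remodeled: `f·μ + (1 − f)·decay·G` with
  `f = protocol_longrange_factor` (default 0.7) and `G` a unit-mean
  log-normal field (σ = 0.5) shared by all dilution samples of a cohort.
  A protocol-*shared* field is essential: a constant long-range
  attenuation alone is a per-stratum affine map and therefore invisible to
  stratum-adjusted Pearson correlation. The remodeling leaves short-range
  structure (and hence TAD calls) nearly untouched, reproducing the
  observation that protocol choice affects full-matrix similarity more
  than TAD-level similarity. At `f = 1` the effect vanishes.
* **Enzyme and lab** are metadata-only by default, so enzyme/lab contrasts
  are true negatives.
* **Depth calibration**: `min_depth_for_quality` returns the depth at which
  the shallowest (edge) bin's expected marginal is 1.5× the coverage-gate
  threshold; standard cohorts use depth 250 at 300 bins, planted-recovery
  checks the calibrated depth at 500 bins.

All randomness flows from one cohort seed through named
`SeedSequence` substreams (root partition, protocol field, per-type
perturbations, per-replicate noise, in declaration order); identical
configs and seeds give bitwise-identical cohorts.

**What the simulations do not capture.** No A/B-compartment plaid
structure, no inter-chromosomal contacts, no mappability or GC biases (the
ICE stage therefore mostly validates its contract rather than removing
real bias), no read-level artifacts, no overdispersion beyond Poisson, and
single chromosomes of 30–50 Mb rather than whole genomes. Passing the
cohort tests shows the measures and statistics behave correctly when their
modelled assumptions hold; it does not by itself demonstrate sensitivity
on real data, where biological variation is richer.

## Study designs used in validation

* **Replicate discrimination**: 10 cell types × 2 replicates, perturbation
  rate 0.3, one protocol. Replicate pairs (n = 10, per-replicate matrices)
  versus merged non-replicate pairs (n = 45): all three measures order the
  medians correctly with two-sided MWW p < 0.01.
* **Null calibration**: perturbation rate 0 and depth-matched scoring
  (merging disabled; each sample represented by its first replicate), so
  replicate and non-replicate pairs are exchangeable by construction and
  the contrast must be flat (p > 0.05). Merging is disabled because merged
  samples have double depth, which by itself breaks exchangeability.
* **Protocol effect**: 12 cell types × 2 single-replicate samples — three
  types with two in-situ samples, three with two dilution samples, six
  mixed — so half the samples are dilution and same-type pairs split
  evenly into single-protocol and mixed-protocol groups. Mixed pairs score
  lower on SCC (p < 0.05); the TADsim median gap is smaller than the SCC
  gap on the same pairs.
* **Robustness**: the replicate > non-replicate median ordering of JI and
  TADsim holds at all four median-size targets.

Problem sizes (300–500 bins, 10–24 samples, `n_null` 200–1000) are chosen
so the full validation runs in minutes on one CPU while keeping every
qualitative contrast comfortably powered.

## Known limitations

* The TADsim variant here pins concrete choices (window locality, vacuity
  filter, construction-matched null, FDR control) that other
  implementations of local-VI similarity may not share; absolute coverage
  values are comparable only within one choice of those knobs.
* γ selection targets a median size; bimodal domain-length distributions
  can make the median a poor summary.
* The MWW approximation's accuracy claims are for the tie-free lattice
  null; heavy ties at small N fall back to the normal approximation,
  which is cruder.
* Boundary Jaccard at tolerance 0 treats a 1-bin shift as a complete
  mismatch; at 100-kb bins this is the conventional but strictest reading.
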