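# tadvar

Quantifying the structural variability of topologically associating domains
(TADs) from Hi-C contact maps.

Hi-C measures genome-wide 3D contact frequencies between fixed-width genomic
bins; TADs are the contiguous blocks along the diagonal with elevated
internal contact frequency. A central question in regulatory genomics is how
much TAD structure varies — between sequencing replicates, between cell and
tissue types, between donors and family members, and across technical
choices such as the *in situ* versus dilution cross-linking protocol or the
restriction enzyme. `tadvar` implements a complete, reproducible pipeline
for that question, for anyone comparing Hi-C samples at cohort scale:

1. **Contact-matrix handling** (`tadvar.hic_core`) — HiC-Pro sparse-triplet
   and dense-TSV I/O, replicate merging, ICE matrix balancing
   (`counts[i,j] = bias_i · bias_j · W[i,j]`, row marginals equalised), and
   the per-sample coverage gate (≥ 80% of bins with > 1000 contacts).
2. **TAD calling** (`tadvar.tad_caller`) — a dynamic program over scaled
   block densities `q_γ(k, l) = S(k, l)/(l − k + 1)^γ` (centred by the mean
   over intervals of equal length) that returns the maximum-quality
   segmentation with gaps. γ is swept over 0–1 in steps of 0.1 and chosen so
   the median called TAD size is closest to a target (880 kb by default).
3. **Similarity measures** (`tadvar.similarity`) —
   * boundary **Jaccard index** `JI(A, B) = |A ∩ B| / |A ∪ B|`,
   * **TADsim**: the fraction of the TAD-covered genome inside windows where
     the two partitions' local variation of information (VI) is
     significantly lower than a seeded random-placement null,
   * **stratum-adjusted correlation (SCC)**: per-diagonal Pearson
     correlations of smoothed matrices combined with weights
     `N_d σ1_d σ2_d`, with the smoothing half-width `h ∈ 0..3` chosen at
     the convergence point of the score.
4. **Group statistics** (`tadvar.stats_compare`) — Mann–Whitney U tests
   (exact for small tie-free groups, saddlepoint/Edgeworth approximation
   otherwise) over pair groups: replicates vs non-replicates, tissue pairs
   across donors, trios, protocol/enzyme/lab contrasts, plus a robustness
   sweep over median-TAD-size targets of 500 kb–1 Mb.
5. **Synthetic cohorts** (`tadvar.synthetic_data`) — Poisson Hi-C matrices
   with power-law distance decay, planted log-normal TADs (median 880 kb),
   boundary perturbations between cell types and a protocol-specific
   long-range remodeling effect, so the whole pipeline is testable with
   known ground truth.

## Worked example

Simulate a small cohort (4 cell types × 2 replicates, 150 bins at 100 kb,
boundary perturbation rate 0.3 between types), run the full pipeline and
test the replicate vs non-replicate contrast:

```python
from tadvar.pipeline import run_full_pipeline

res = run_full_pipeline(
    {"seed": 5, "n_null": 200, "run_robustness": False,
     "cohort": {"n_types": 4, "n_replicates": 2, "n_bins": 150, "depth": 260.0}},
    outdir="example_run",
)
df = res.group_tests
print(df[df.group_a == "replicate_vs_nonreplicate:a"]
      [["measure", "n_a", "n_b", "U", "p_value", "median_a", "median_b"]])
```

prints

```
measure  n_a  n_b    U  p_value  median_a  median_b
 hicrep    4    6 24.0 0.009524  0.990554  0.914495
     ji    4    6 23.0 0.024303  0.968750  0.684211
 tadsim    4    6 21.0 0.066568  1.000000  0.825050
```

Each row compares the 4 replicate pairs (group *a*) against the 6 merged
non-replicate pairs (group *b*) under one measure. Replicate pairs are more
similar under all three measures (e.g. median boundary Jaccard 0.97 vs
0.68): the perturbed cell-type boundaries are detected, and with U = 24 =
n_a·n_b the replicate/non-replicate separation under SCC is complete
(p ≈ 0.0095 despite only 10 pairs). At full cohort scale (10 types × 2
replicates, 300 bins) all three measures separate the groups at p < 0.01.

The same pipeline is scriptable from the shell:

```sh
tadvar simulate --config cohort.yaml --seed 5 --outdir cohort/
tadvar call-tads --matrix cohort/type00_s0/rep0.matrix \
                 --bins cohort/type00_s0/rep0.bed --out tads.bed
tadvar score --measure ji --tads1 tads.bed --tads2 cohort/type00_s0/truth_tads.bed
tadvar run-all --config cohort.yaml --seed 5 --outdir results/
```

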