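# Methods

This note documents the statistical model, conventions, parameter defaults and
limitations of `modmethyl`. All coordinates in the package are 1-based closed
unless a reader/writer explicitly converts (BED and CpG-island inputs are
0-based half-open on disk).

## 1. Base-modification tag decoding

A modBAM stores per-read methylation calls in two tags. `MM` (`C+m,d1,d2,…;`)
lists, in the read's **original** orientation, how many canonical bases (here
C) to skip before each call; `ML` holds one byte `q` per call. We interpret
`q` as the midpoint of its probability interval,

    p = (q + 0.5) / 256,

so `q = 0 ↦ p ≈ 0.002` and `q = 255 ↦ p ≈ 0.998`; `p` is never exactly 0 or 1,
which keeps the log-odds statistic finite. For a multi-code item
(e.g. `C+mh`) the `ML` bytes are interleaved position-major, code-minor. Items
with a `-` strand flag (calls on the opposite strand of the read) are skipped
with a warning; top-strand `C+m` calls on reverse-aligned reads are handled by
complementing coordinates into the stored orientation, so a read's calls land
on the reference G of each CpG (the bottom-strand C). The decoder rejects
malformed grammar, `ML` length mismatches, and skips that run past the last
canonical base, rather than guessing.

Calls are projected to reference coordinates through the CIGAR; calls under
insertions or soft-clips have no reference position and are dropped.
`collapse_strands=True` optionally shifts bottom-strand calls by −1 to the
top-strand C of the CpG so both strands accumulate at one position.

## 2. Methylation store

Calls are written to a bgzip TSV with columns (sample, chrom, pos, strand,
statistic, read_id), tabix-indexed for region queries. The stored statistic is
the log-odds

    s = ln(p / (1 − p)),

rounded to 4 decimals, symmetric around 0 at p = 0.5. Sorting is lexicographic
by chrom, then numeric by pos, with (sample, read_id) tie-breaks, implemented
as an external merge sort (bounded memory; default run size 500 000 rows). An
empty store is valid.

## 3. Count matrices

A call is **methylated** iff `s > 0` (p > 0.5); a tie at exactly 0.5 counts as
unmethylated. Per site and sample we tally methylated calls *M* and coverage
*Cov*. Sites are dropped when **any** group has zero coverage across all of
its samples — the weakest filter that leaves every retained site informative
for a between-group comparison. Region-level counts sum site counts within
each region. The log-methylation-ratio is

    LMR = log2((M + prior) / (Cov − M + prior)),   prior = 2,

a moderated log-odds; the prior shrinks extreme proportions at low coverage
and makes LMR antisymmetric under M ↔ Cov − M.

## 4. Aggregate profiles

Each region's body is mapped to relative position [0, 1] by
(pos − start)/(width − 1); flanks of `flank_bp = 2000` map linearly to
[−f, 0) and (1, 1 + f] with `f = 0.33`, so a fixed genomic flank occupies a
fixed visual fraction regardless of region width. Minus-strand regions are
mirrored. Observations (individual read calls, binarized) are pooled **within
group** across samples and regions into `n_bins = 100` equal bins; bin means
are smoothed with a centered rolling mean over 5 bins. Pooling weights sites
by coverage; it is not a per-sample average.

## 5. Multidimensional scaling

Classical (Torgerson) MDS: features (region LMRs) are ranked by variance and
the top `k = 500` retained; pairwise sample distances are Euclidean divided by
√k (a root-mean-square difference, comparable across k); the doubly centered
squared-distance matrix B = −½ J D² J is eigendecomposed and the top two
eigenpairs give coordinates. Variance explained is reported from the
eigenvalue spectrum. At least 3 samples are required.

## 6. DMR calling

The caller is deliberately simple and exactly permutation-calibrated:

1. Per site, compute the pooled methylation proportion difference between the
   two groups (sites covered in both groups only).
2. Smooth with a centered rolling mean over `smooth_sites = 5` sites.
3. Candidate regions are maximal same-sign runs with |smoothed diff| >
   `effect_cutoff = 0.1`, allowing gaps up to `max_gap = 1000` bp, and at
   least `min_sites = 20` sites. The test statistic is the **area** (sum of
   smoothed diffs); `beta` is the mean raw difference over the region.
4. Significance by whole-sample group-label permutation: all distinct
   relabelings when there are ≤ 1000 (p = hits/total, a valid exhaustive
   test), otherwise `n_perm = 200` seeded random relabelings with the
   unbiased estimator p = (1 + hits)/(1 + n). Benjamini–Hochberg adjustment
   across regions gives q-values.

**Permutation floor.** With g vs g samples, the exhaustive test has
C(2g, g)/2 distinct |statistic| values, so the smallest attainable p-value is
2/C(2g, g): 0.1 for 3 vs 3, 2/70 ≈ 0.0286 for 4 vs 4. A 3 vs 3 design can
therefore **never** reach q < 0.05 under whole-sample permutation — this is a
property of the test, not a bug. Power analyses and significance-thresholded
examples in this repository use 4 vs 4 for that reason; the permutation test
itself remains exact at any group size.

Defaults rationale: `effect_cutoff = 0.1` ignores differences below practical
relevance; `min_sites = 20` suppresses short noise runs; `max_gap = 1000` bp
bridges CpG-sparse stretches without merging unrelated regions;
`smooth_sites = 5` matches the profile smoothing span.

DMR–gene association intersects DMRs with strand-aware promoter windows
(default 5 kb upstream, 5 kb downstream of the TSS; truncated at position 1
with a warning) and reports one row per overlapping (DMR, gene) pair with the
**intersection** coordinates.

## 7. Annotation utilities

CpG-island statistics are recomputed from base counts as

    perCpg = 100 · 2 · cpgNum / length,    perGc = 100 · gcNum / length,

rounded to one decimal (the factor 2 counts both bases of each CpG). Island
files are 0-based half-open on disk (length = end − start) and converted on
read. `overlap_intersect` is a sorted sweep per chromosome, emitting one row
per overlapping pair with the intersected range and merged metadata.

## 8. Visualization

Gene plots stack a smoothed per-group trend (pooled site proportions,
centered rolling mean over ±`smooth_window_bp/2 = 1000` bp), a read-level
heatmap, and an exon track, over the gene ± `flank_bp = 2000`. Reads are
packed into rows first-fit by start coordinate; for intervals this greedy
packing is optimal — the row count equals the maximum overlap depth (verified
against a brute-force oracle in the tests). Highlight regions are clipped to
the plotting window. Rendering uses the Agg backend so it runs headless.

## 9. Simulator

The simulator emulates the *data format and sampling process*, not biology:

- A 20 kb toy chromosome whose **only** CpGs are planted ~every 50 bp
  (accidental CGs in the random background are broken), so planted sites and
  observable sites coincide exactly.
- Per group, a methylation profile: background probability plus rectangular
  windows (e.g. a 0.9-vs-0.3 window models an imprinted DMR).
- Per read call, the emitted probability is drawn from a two-point mixture:
  the high mode 0.95 with probability equal to the site's methylation level,
  else the low mode 0.05, each with Gaussian sd 0.03 (clipped to (0, 1)) —
  mimicking a well-separated basecaller. Probabilities are quantized to the
  byte `q = clip(⌊256p⌋, 0, 255)` and the ground truth records the decoded
  value (q + 0.5)/256, so round trips are exact at the bit level.
- Reads: 120 per sample, length 3000 ± 500, 50% reverse-complemented and
  written as reverse-strand alignments; MM/ML tags are delta-encoded in the
  original read orientation. Output (BAMs, sample sheet, toy exons, toy CpG
  islands, ground-truth JSON) is byte-identical given a seed.

Not modeled: sequencing errors, alignment artifacts, indels, hemimethylation,
non-CpG methylation, and realistic caller miscalibration. The two-point
emission has a known crossover probability past 0.5
(`effective_methylation_prob`), used when validating empirical frequencies.

A fast path (`simulate_site_matrix`) draws Cov ~ Poisson(depth) and
M ~ Binomial(Cov, p_eff) directly at the same planted sites, for power/null
studies that do not need BAM round trips.

## 10. Numerical conventions

- Ties at p = 0.5 are unmethylated (statistic 0 is "not > 0").
- Stored statistics carry 4 decimals; probabilities recovered from them are
  accurate to ~5 × 10⁻⁵, far below the 1/256 quantization.
- Chromosomes sort lexicographically ("chr10" < "chr2"); positions numerically.
- BH adjustment is the standard step-up with a cumulative minimum from the
  largest p-value, capped at 1 (cross-checked against `statsmodels` in tests).

## 11. Limitations

- The DMR caller tests one contrast between exactly two groups, with
  whole-sample permutation; it has no covariates, no per-sample dispersion
  model, and limited power at small group sizes (see the permutation floor).
- Strand collapsing assumes CpG context; non-CpG modifications should keep
  strands separate.
- The store keeps one row per call; for very deep datasets a pre-aggregated
  site format would be smaller, at the cost of losing read-level plots.
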