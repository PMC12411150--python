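# Methods

## Model and pipeline

`aneuscan` estimates somatic copy-number state from low-coverage WGS by
comparing a sample's binned read counts to a control cohort. The genome is
tiled with fixed-width bins (default 200 kb; terminal partial bins are kept
with their true width, and bin widths always sum to the chromosome length).
Each bin's raw coverage is standardized to

    Z_bin = (coverage_raw − mean_controls) / stdev_controls

with the per-bin control mean and sample standard deviation (n−1
denominator). Bins whose control mean or standard deviation is zero carry
no information and are masked as unusable (propagated as missing, never as
zero). A log2 copy ratio `log2(coverage_raw / mean_controls)` is computed in
parallel; zero sample counts use a pseudocount of 0.5 reads so the ratio
stays finite while the Z formula is applied verbatim to the raw zero.

The Z-score vector is the segmentation signal; the log2 ratio drives the
quality gate and reporting. Both are retained in every profile.

Assumptions: controls and cases share the same per-bin biases
(mappability/GC), so the control baseline is the only normalization; bins
are conditionally independent given copy state; at least two controls exist
so a baseline spread is defined. No GC or mappability correction is applied
beyond the baseline — a deliberate simplification; a user-supplied
correction can be applied to the count matrix before normalization.

## Sample quality gate

The QC statistic is the median over within-chromosome pairs of consecutive
usable bins of |Δ log2 ratio|. A flat (even a uniformly gained) genome gives
small adjacent differences, while bin-to-bin technical jitter inflates them
regardless of copy state. The sample fails when the statistic *exceeds*
0.38 — strictly, so a boundary value of exactly 0.38 passes. Two readings
of the rule were possible (median of absolute differences vs MAD of the
differences; log2 vs natural log); the implementation uses the median of
absolute log2 first differences, with adjacency restricted to within
chromosomes since cross-chromosome adjacency is biologically meaningless.

## Circular binary segmentation

Per chromosome, over its usable bins:

1. Enumerate arcs (i, j] of the circularized signal with both arc and
   complement ≥ `min_seg_bins` (default 3). A wrapped arc equals the
   complement of a linear one and yields the same |T|, so linear windows
   suffice; an arc ending at the last bin encodes the same two-part
   partition as the arc starting at 0, and only the latter canonical
   representative is scored so that floating-point noise cannot flip the
   tie-break. Ties resolve to smaller i, then smaller j.
2. Score each arc with the pooled two-sample t-statistic magnitude.
   Degenerate zero-variance comparisons score +∞ when the means differ and
   0 otherwise (needed for noise-free inputs); the signal is centred before
   prefix-sum accumulation to keep the sums-of-squares cancellation exact
   for binary-representable values.
3. Test the best split by permutation: p = (1 + #{max-T(shuffle) ≥ T_obs})
   / (1 + B), default B = 1000, full reshuffling of the interval. The split
   is accepted iff p < α (default 0.05). Inside the recursion every
   nonempty resulting part (including the two complement flanks) must hold
   ≥ `min_seg_bins` bins, so accepted splits always produce viable
   segments.
4. Recurse into the 2–3 resulting parts (depth bound 25), then optionally
   merge adjacent segments whose means differ by less than `merge_tol`
   (default 0.0 — no merging; pruning rules are left to the user).

The permutation loop stops early once the exceedance count makes rejection
impossible: the count only grows, so the accept/reject decision is
identical to the full run, and accepted splits always complete all B
permutations, making their reported p exact. Permutations are scored in
vectorized batches of 100. Each chromosome draws its permutation stream
from (seed, chromosome index), so results are reproducible and independent
of chromosome order.

Known behaviour: within strong gains the count variance grows with the
mean, and the permutation test sometimes detects that heteroscedasticity as
additional splits inside the event. Planted-breakpoint recovery is
therefore assessed per breakpoint (each planted boundary within ±2 bins)
rather than as exact segment identity; classic implementations prune such
splits with "undo" heuristics, which are intentionally not replicated.

## CIN calling

A segment is a gain when seg_mean ≥ `z_gain` (default +3.0) and a loss when
seg_mean ≤ `z_loss` (default −3.0), in both cases spanning at least
`min_event_bins` (default 50 bins = 10 Mb at 200 kb). A sample is
CIN-positive when it has at least one call and the aberrant fraction of its
usable genome reaches `cin_min_aberrant_fraction` (default 0 — any
qualifying event suffices). These cutoffs are an explicit, configurable
operationalization chosen so whole-arm events are CIN-positive while flat
profiles are negative — the magnitude of |seg mean| used for calling is
the principle, the specific numbers are package defaults and are recorded
in every report. Arm-level attribution requires calls to cover more than
half of the arm's usable bins (`arm_coverage_threshold` = 0.5). chrX is
excluded from calling by default: in a mixed-sex cohort normalized against
mixed-sex controls, X coverage is bimodal and would produce sex-driven
false arms. Gene calls take the overlapping segment with the largest
usable-bin overlap; an exact tie between conflicting calls is neutral, and
genes whose bins are all unusable are not evaluable.

## Microbial screen

A read matches the reference when some ungapped placement on the forward or
reverse-complement strand has Hamming distance ≤ `max_mismatches` (default
1). `N` never matches, in read or reference. The production matcher is
seed-and-extend with an exact 20-mer index (pigeonhole: with k mismatches
one of k+1 disjoint 20-mer chunks must be exact; shorter reads fall back to
the naive scan), semantically identical to the exhaustive sliding-window
scan that is kept as the test oracle. A sample is positive when strictly
more than `min_reads_exclusive` (default 4) reads match — five reads are
positive, four are not.

## Cohort statistics

Subtype × CIN-status association uses the Pearson chi-square without
continuity correction (delegated to `scipy.stats.chi2_contingency`; an
independent Σ(O−E)²/E computation is the test oracle). The undetermined
("N/A") subtype row is kept in the assembled table but excluded from the
default test: the defined-subtype contrast is the scientific question, and
hand computation shows the printed headline p-value of the 3×2 table is
reproduced only without that row. QC-failed samples are excluded from
tables and counted in a dropout report. Percentages print with two
truncated decimals (12/39 → 30.76), matching the convention of the cohort
reports these tables mirror; a half-up rounding would print 30.77. Fisher's
exact test is available for sparse 2×2 tables but is not the default, and
a warning flag is raised whenever an expected count falls below 5.

## Synthetic data

The generator emulates exactly the structure the normalization assumes:
a per-bin baseline expectation shared by all samples (lognormal bin effects
with natural-log sd `bin_effect_sd`, default 0.05, standing in for
mappability/GC structure; mean preserved at `depth_mean`), negative
binomial counts (variance μ + μ²/dispersion; defaults depth 200 reads/bin,
dispersion 50, giving a per-bin copy-change signal of |ΔZ| ≈ 6 for a
one-copy-equivalent doubling), and case bin means multiplied by
`purity·copies/2 + (1 − purity)`, so the expected log2 ratio of a 4-copy
event at purity 1 is exactly 1. The QC-failure mode multiplies bin means by
independent lognormal jitter with log2 sd `log2(noise_inflation)` (default
√2 → sd 0.5, placing the QC statistic near median|N(0, 0.5√2)| ≈ 0.48,
above the 0.38 gate). Microbial spike-ins copy substrings of a reference
with an exact number of substitutions. One global seed fans out to
per-sample substreams keyed by sample index, so enlarging a cohort never
reshuffles existing samples.

What the simulator does **not** model: FFPE fragmentation and degradation,
GC-dependent amplification curves, mappability dropout, duplicate reads,
subclonal mixtures beyond a single purity, or sequencing errors outside the
planted microbial substitutions. Passing recovery tests therefore show the
algorithms are correct under the stated count model, not that real FFPE
libraries meet that model.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: two-chromosome grids of
400 bins (40 Mb chromosomes) for segmentation studies, the six-chromosome
~2,500-bin toy genome for pipeline runs, 20-control baselines, 60–100
simulated samples per recovery study, 1,000 permutations for calibration
checks and 200 where the planted effect is overwhelming. Weighted segment
means conserve the signal mean to 1e-9; chi-square oracle agreement is
asserted at 1e-9; split-statistic oracle agreement at 1e-9 on |T| with
identical argmax. The bundled hg19-style genome (chr1–22, X lengths and
centromere midpoints) supports full-scale grids (~15,500 bins) without any
download.

## Limitations

No purity/ploidy estimation, no GISTIC-style focal significance, no
multi-sample joint segmentation, no MSI analysis, no survival modelling.
The CIN-positivity rule is a documented operationalization — cohort CIN
rates depend on its thresholds, and published cohort percentages cannot be
regenerated without the underlying samples; they enter only as fixed inputs
to the contingency-table statistics.
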