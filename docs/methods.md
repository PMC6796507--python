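# Methods

## The measurement model

Coverage bias is treated as a deviation of sequencing depth from
uniformity that is predictable from local GC content. All quantities
derive from per-base depth along a reference:

* **Per-base relative coverage.** `rel[b] = depth[b] / d̄`, where `d̄` is
  the mean depth over *all* bases of all retained contigs, zeros included.
  Zero-depth positions are genuine reference positions — dropout is the
  phenomenon being measured — so they stay in the normalizer. The pooled
  mean of `rel` is exactly 1 by construction. "Depth" is pileup depth:
  each primary, non-duplicate alignment contributes to every base its
  aligned blocks span (SAMtools semantics).
* **Windows.** Non-overlapping 200-bp tiles per contig, starting at 0;
  a trailing partial tile is dropped (a shorter window would blur the GC
  quantization below). Window GC is computed over non-N bases; by default
  any N disqualifies the window (`max_n_fraction = 0`), configurable for
  draft genomes. With N-free 200-bp windows, GC is an exact multiple of
  0.5%, so the 0.5%-wide bins below are exact classes, not approximations.
  Windows never span contig boundaries.
* **GC bins and C_GC.** A window with GC `g` (percent) joins the bin
  `[label, label + 0.5)` with `label = floor(g / 0.5) · 0.5`. `C_i` is the
  unweighted mean windowed relative coverage of bin `i`; only non-empty
  bins exist.
* **The overall bias statistic.** `B = Σ_i n_i (C_i − C̄)² / (n_T · N)`
  with `C̄` pinned at exactly 1 (the genome-wide mean relative coverage by
  construction; recomputing it from a filtered bin table would let display
  filtering leak into the statistic). `N` counts non-empty bins. A `root`
  variant returns √B; both variants are monotone transforms of each other,
  so kit rankings and regression signs are identical — the default is the
  flattened mean-square form. Note that `B` depends on bin granularity
  through `N`: halving the bin width changes both `N` and `B`, so `B`
  values are only comparable at a fixed bin width (0.5% throughout).
* **Display filtering.** C_GC curves omit bins holding < 0.5% of all
  windows (`min_bin_fraction = 0.005`), because extreme-GC bins with a
  handful of windows produce wild means that dominate a plot. This is
  reporting only; the statistic always uses all bins.
* **Cohort regression.** Ordinary least squares of `B` on genome mean GC
  (percent), classical two-sided t-test and 95% CI on the slope
  (statsmodels). Nothing about the relationship is assumed beyond
  linearity over the observed GC range.

## Reference preparation and quality gates

Draft references may carry multicopy elements (plasmids, IS elements) on
their shortest contigs; their inflated coverage would distort `d̄`. The
N90 filter drops contigs shorter than the assembly's N90 before coverage
normalization (ties at N90 kept, so ≥ 90% of assembly length always
survives). Assemblies are gated on completeness < 85% or contamination
> 5% (strict inequalities: the boundary values pass); contigs shorter than
300 bp are excluded from assembly comparisons (boundary kept). Read
subsampling to a target fold-coverage samples records (pairs as units)
uniformly without replacement and stops at the first record reaching the
target, overshooting by at most one record rather than truncating a read.

## Mock-community normalization

With `m_s` mapped reads (or bases), genome length `L_s` and relative ddPCR
copy number `k_s`, relative abundance is `a_s ∝ m_s / (L_s · k_s)`,
normalized to sum to 1. Copy numbers are rescaled to mean 1 internally so
absolute ddPCR units are irrelevant. For per-species coverage curves, all
species of one library share one normalization scale — the community mean
depth per copy-weighted base, `μ = Σ_s total_s / Σ_s L_s·k̂_s` — and
`rel_s[b] = depth_s[b] / (μ·k̂_s)`. This scale was chosen over a
per-species-mean normalizer because it has the two properties the
correction exists for: doubling a species' molarity together with its
depth leaves its curve unchanged, and depth exactly proportional to
molarity gives `rel ≡ 1` for every species even with unequal copy numbers.
A consequence worth knowing: a species globally depleted by library
chemistry shows a C_GC curve sitting below 1 (real signal), which a
per-species normalizer would hide.

## The simulator

The generator exists to make every pipeline stage testable against closed
forms.

* **Genomes.** Piecewise-constant GC landscapes: within a segment each
  base is iid G/C with probability `gc/2` each, A/T with `(1−gc)/2` each.
  `bimodal_landscape` mimics real bacterial genomes (most windows near the
  genome's modal GC, a tail across 25–65%) by putting ~90% of length in
  two GC modes plus an 8-step ramp over the full range — this is what
  makes individual GC bins populous enough (n_i ≥ 200) to test per-bin.
* **Bias families.** Strictly positive weights `f(g)` over GC fraction:
  `uniform` (f ≡ 1); `logistic_low_gc` (floor + (1−floor)·logistic((g −
  g0)/s); defaults g0 = 0.40, s = 0.03, floor = 0.2 — a smooth low-GC
  suppression of the kind transposase insertion bias produces, saturating
  near 1 above ~45% GC); `linear`; `extreme_suppression` (a Gaussian dip
  away from a preferred GC, the PCR-amplification-like signature).
  Crucially, bias is a function of the enclosing 200-bp window's GC, not
  of each fragment's own GC, so expectations are exact:
  `E[C_i] = f(g_i)/Z` with `Z = Σ_j (n_j/n_T) f(g_j)`.
* **Sampling modes.** `poisson_site` draws each base's depth from an
  independent Poisson with rate `mean_depth·f(g_w(b))/Z` — no
  read-placement correlations, so the closed form above is the exact
  expectation and Monte-Carlo error shrinks as 1/√depth. `fragment`
  places whole reads (weighted starts, truncation at the contig end) and
  produces realistic depth files for demonstrations; its window means are
  serially correlated, so analytic checks use `poisson_site`. Trailing
  partial-window bases get a rate from their own partial window's GC; test
  fixtures use window-multiple lengths so this edge never enters the
  oracles.
* **Communities.** Reads are allocated multinomially across species with
  probability ∝ `L_s · k_s · F_s`, where `F_s = Z_s` is the genome-average
  bias weight — a species whose genome the chemistry dislikes yields fewer
  library molecules overall — then placed fragment-mode within the genome.
  The realized allocation is returned as a truth table for testing the
  abundance estimator.
* **Determinism.** Every generator is a pure function of (spec, seed),
  using numpy's PCG64 `Generator`; dataset manifests record both.

## Problem sizes and numerical choices

Validation runs use sizes at which the statistical bounds are comfortable
yet everything completes in seconds: 2 Mb at 50× for analytic recovery
(10,000 windows; per-bin standard error of `C_i` ≈ √(1/(200·d̄·n_i)), an
order of magnitude below the 5% check in bins with n_i ≥ 200), 100
replicate cohorts of 20 genomes for regression calibration, and 10⁶ reads
over 9 × 150-kb species for the mock community (multinomial standard error
≈ 3·10⁻⁴ per abundance against a 0.005 bound — genome length does not
enter the abundance estimator's variance). The Monte-Carlo standard error
of `B̂` is estimated from 6 replicate simulations; the replicate mean is
compared to the analytic expectation at 3·SE/√6.

Floating-point conventions: bin labels use `floor(g/width + 1e-9)·width`
(the epsilon only matters for N-containing windows whose GC is not a
multiple of 0.5); window means use prefix sums; B is accumulated in double
precision and agrees with naive summation to 1e-12 on random inputs.
Degenerate inputs are errors, not NaNs: all-zero coverage, empty bin
tables, regression with < 3 points or constant GC. An all-N window has
undefined GC (NaN) and is always dropped with a tally.

## What the synthetic tests do not show

The simulator draws iid bases, so it reproduces none of the following
features of real data: repeats and multicopy elements (hence the N90
filter is exercised only on constructed length lists), mappability and
alignment artifacts, fragment-length distributions and paired-end
correlation, base-quality or chimera errors, and fragment-GC (rather than
window-GC) bias. Passing tests therefore demonstrate that the statistics
are computed correctly and recover known bias functions under the stated
sampling model — not that any particular laboratory protocol is biased.
Conclusions about real kits require real depth tracks, which the pipeline
ingests through the same interfaces (samtools-depth TSV, bedGraph, BAM).

## Known limitations

* `B` is granularity-dependent (see above); compare only at fixed bin
  width.
* The statistic weighs bins by `n_i` but divides by both `n_T` and `N`,
  so genomes with very different GC ranges have different effective
  normalizations; the regression over mean GC absorbs much of this, but
  cross-study comparisons should fix the windowing and binning exactly.
* No GC *correction* is provided by design — the package measures bias,
  it does not remove it.
* BAM ingestion counts aligned blocks of primary, non-duplicate reads
  with MAPQ ≥ threshold; it does not distinguish overlapping mates
  (a fragment covering a base twice via both mates counts twice).
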