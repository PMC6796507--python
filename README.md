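# gcbias

Quantification of GC-content-associated sequencing coverage bias in
bacterial genomes and mock metagenomes.

## The problem

Illumina library preparation chemistry leaves a fingerprint on sequencing
coverage. Transposase-based tagmentation kits insert less frequently into
GC-unbalanced (especially AT-rich) sequence, so low-GC regions — and whole
low-GC genomes such as staphylococci — end up underrepresented; PCR
amplification adds a milder depletion at both GC extremes. In single-genome
sequencing this costs assembly contiguity and variant-calling sensitivity;
in metagenome sequencing it systematically distorts the estimated relative
abundance of low-GC species. `gcbias` implements the windowed
relative-coverage statistics that detect and quantify this artifact, plus a
mock-community abundance workflow and a fully controlled simulator so every
stage is testable without sequencing data.

## The statistic

For one genome and one library:

1. **Per-base relative coverage** — depth at each reference base divided by
   the mean depth over the whole genome (so the genome-wide mean is 1).
2. **Windowed relative coverage** — the mean per-base relative coverage of
   each non-overlapping 200-bp window, paired with the window's GC content.
3. **C_GC curve** — windows binned by GC at 0.5% resolution; `C_i` is the
   mean windowed relative coverage of bin `i`. A flat curve at `C_GC = 1`
   is unbiased coverage.
4. **Overall GC-content-associated bias**

   ```
   B = Σ_i n_i (C_i − C̄)² / (n_T · N),     C̄ = 1
   ```

   where `n_i` is the number of windows in bin `i`, `n_T` the total number
   of windows and `N` the number of analysed bins. `B = 0` iff every bin
   sits exactly at the genome mean; a `root` variant (√B) is available and
   orders libraries identically.
5. **Cohort regression** — OLS of `B` on genome mean GC (%) with the
   classical t-test and 95% CI on the slope, for comparing chemistries
   across genomes spanning a wide GC range.

Supporting operations: samtools-depth/bedGraph/BAM depth ingestion,
N50/L50/N90 contiguity metrics, the `<300 bp` contig filter, exclusion of
contigs shorter than N90 from draft references, the completeness ≥85% /
contamination ≤5% genome quality gate, read subsampling to a target
fold-coverage, and genome-size- and ddPCR-copy-number-normalized relative
abundances for mock communities.

## Worked example

Simulate a genome with a low-GC-suppressed (tagmentation-like) library and
profile it:

```
gcbias simulate --outdir demo --length 400000 --bias-family logistic_low_gc \
    --mode poisson_site --seed 5
gcbias profile --fasta demo/genome.fasta --depth demo/depth.tsv --outdir demo/out
```

which prints

```
genome: B = 0.00182215 (mean_squared), mean GC = 45.06%, n_T = 2000, N = 91
```

`B ≈ 0.0018` is the overall GC bias of this library (the same genome with
uniform coverage gives `B = 0` exactly); `demo/out/` contains the window
table, the GC bin table, the display-filtered `C_GC` curve and a manifest.

The numbered drivers under `analysis/` run the full study on synthetic
data: `01_simulate_libraries.py` (two genomes × three chemistries),
`02_genome_bias_profiles.py` (per-kit bias table — the tagmentation-like
library shows `B = 0.00229` on the 33%-GC genome vs `0.00000` for the
PCR-free library), `03_bias_vs_gc_regression.py` (20-genome cohort; fitted
slope `−9·10⁻⁵` B per GC%, p ≈ 3·10⁻⁵), and `04_mock_community.py`
(9-species mock at 10⁶ reads: unbiased library recovers every abundance at
1/9 ± 0.001, the tagmentation-like library depresses the 28%-GC species to
0.034). Each writes its tables under `results/`.

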