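# anchorprof

Anchor-centred occupancy profiling and strand-aware expression analysis for
ChIP-seq / RNA-seq study designs, with a first-class synthetic-data
generator.

`anchorprof` reimplements, as a reusable and fully testable pipeline, the
quantitative analysis typical of chromatin studies that ask how a promoter
mark (e.g. H3K4me3 or H3K9ac) and transcription respond to a perturbation —
here modelled on a two-genotype (wild-type vs Cfp1-null) × two-treatment
(untreated vs doxorubicin) embryonic-stem-cell design with stranded
paired-end RNA-seq and low-abundance divergent antisense transcription at
gene boundaries. It is aimed at computational biologists who want each
analysis stage as a tested library function rather than a one-off script.

## What it computes

- **Coverage tracks.** Uniquely aligned fragments are filtered
  (duplicates keyed on `(chrom, start, end, strand)`), biological
  replicates pooled, and per-base coverage normalized to reads per million:
  `signal(b) = 10^6 / N · #{fragments covering b}` with `N` the library
  size. Strand-split tracks (from paired-end fragment orientation) satisfy
  `plus + minus = total` exactly.
- **Metagene profiles and heatmaps.** For oriented anchors (TSS, TES or
  region centres) with flank `F`, the sliding-window matrix holds the mean
  per-base signal in windows of width *w* = 100 bp every *s* = 20 bp across
  `[−F, +F)` — 296 windows for `F` = 3 kb. The average profile is the
  per-window **median** across regions. Heatmap row order comes from
  Euclidean k-means on a reference matrix (clusters by descending mean
  signal, rows within a cluster likewise) and is applied verbatim to
  companion samples.
- **Density comparisons.** Per-region mean signal over the full interval,
  compared between groups with a two-tailed unpaired Wilcoxon rank-sum
  test: exact enumeration of the U distribution for `min(n, m) ≤ 8` without
  ties, normal approximation with tie and continuity correction otherwise.
- **Differential expression.** Stranded union-mode counting over exon
  unions (ambiguous, antisense and feature-free fragments tallied
  separately), median-of-ratios size factors
  `ŝ_j = median_g k_gj / (∏_j k_gj)^{1/m}`, per-gene method-of-moments
  negative-binomial dispersion shrunk toward a fitted mean–dispersion trend
  `α(μ) = a₀ + a₁/μ`, a two-sided conditional NB test on the per-condition
  count totals, Benjamini–Hochberg adjustment, and the classification
  filters `padj < 0.05`, fold change ≥ 2.5, base mean ≥ 200, plus
  length-corrected top-active-gene ranking.
- **qPCR arithmetic.** ChIP-qPCR fold enrichment
  `(IP_t/Input_t)/(IP_c/Input_c)`, spike-in (ERCC-00074) absolute
  quantification expressed as fold induction over a baseline sample, and
  splicing-product fractions against a 3'-UTR total — all invariant to
  per-sample global scale factors by construction.

## Worked example

Run the full synthetic study (simulate → coverage → metagene → DE →
antisense → qPCR) from the library:

```python
from anchorprof import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(out_dir="demo_out", seed=11))
print(report["stages"]["de"])
print(report["stages"]["antisense"][1])
```

which prints (seed 11, default configuration):

```
{'n_tested': 200, 'n_up': 40, 'n_down': 25, 'n_low_expression': 0, 'sensitivity_up': 1.0}
{'strandedness': 'antisense', 'n_a': 40, 'n_b': 40, 'U': 16.0,
 'p_value': 4.717863132115632e-14, 'method': 'approx'}
```

All 40 simulated treatment-induced genes and all 25 repressed genes are
recovered by the DE filters with nothing spurious, and the antisense TSS
density of induced genes is far higher in the Cfp1-null genotype
(rank-sum p ≈ 5 × 10⁻¹⁴) while sense densities do not differ
(p ≈ 0.25 in the companion row) — the hallmark contrast the pipeline is
built to measure. Outputs land under `demo_out/{tracks,matrices,profiles,
stats,de,report}` as bedGraph/TSV/JSON, each stamped with the config hash
and seed; rerunning the same config and seed reproduces every file byte
for byte.

The same stages are available from a shell via the `anchorprof` CLI
(`run-all`, `simulate`, `coverage`, `profile`, `heatmap`, `density`,
`density-compare`, `counts`, `de`, `antisense`, `qpcr`).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its limits, parameter defaults, and numerical choices.
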