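# Methods

This note documents the models, conventions and design choices behind
`anchorprof`: what each stage computes, what the synthetic-data generator
does and does not emulate, and where the design was genuinely open.

## Coordinates and fragment model

All internal coordinates are 0-based, half-open; conversion to 1-based,
inclusive happens only when reading or writing GTF. A *fragment* is a
deduplicated paired-end sequencing fragment reduced to an interval plus a
strand: the strand is the transcribed strand inferred from mate
orientation (first-mate convention), which is what makes sense/antisense
assignment possible for stranded RNA-seq. Mapping artifacts (soft
clipping, multimapping resolution, MAPQ models) are upstream of this
package: inputs are already-aligned fragments, with `unique` and
`duplicate` flags carried as booleans.

Filtering keeps uniquely aligned fragments and removes duplicates keyed on
`(chrom, start, end, strand)` — fragment-level deduplication that needs no
sequence access. Replicate merging is concatenation; library sizes add.

## Coverage and normalization

Coverage at base *b* is the number of fragments whose interval contains
*b*, computed by difference-array accumulation. Normalization multiplies
the track by `10^6 / library_size` (reads per million). The constant is a
convention: any positive constant yields identical comparative statistics
downstream, because every downstream quantity (window means, profiles,
densities) is linear in the track. The factor actually applied is recorded
in the track metadata. ChIP fragments are covered over their whole
interval; an alternative fixed-extension mode was considered and rejected
as the simulator emits fragments of known length, making extension a
no-op; the fragment length is a config field wherever it matters.

## Metagene geometry

Anchors are oriented positions: for a `+` gene TSS = `start` and
TES = `end − 1`; for a `−` gene TSS = `end − 1` and TES = `start`.
Orientation is the gene strand; region-centre anchors get orientation `+`.
The oriented per-base vector of a region assigns relative coordinate
`r ∈ [−flank, +flank)` to genomic base `anchor + r` on `+` regions and
`anchor − r` on `−` regions, so index `flank` is always the anchor itself
and mirroring the genome (reversing coordinates and strands) leaves every
oriented vector — hence every profile and matrix — unchanged. This
convention fixes the one free off-by-one in flipping minus-strand regions
and is enforced by a mirror-symmetry test.

Windows of width `window` (default 100 bp) start at `−flank` and advance
by `slide` (default 20 bp) while the full window fits; there are no
partial windows, giving `(2·flank − window)/slide + 1` columns (296 at
flank 3 kb). Matrix cells are mean per-base signal; on integer-valued raw
coverage the cumulative-sum evaluation is exact (integer sums in float64),
which is why oracle tests can demand bit equality. Regions whose flank
leaves the chromosome are dropped, not zero-padded — padding would dilute
signal with fabricated zeros — and the count of exclusions is logged.

The average profile is the per-window median across regions, robust to a
few extreme regions. Box-plot-style densities are the mean per-base signal
over the full interval (equivalent up to an edge constant to averaging the
window grid). Heatmap ordering: Euclidean k-means (scikit-learn, fixed
`random_state`, `n_init=10`) on one reference sample; clusters are
displayed by descending mean signal, rows within clusters by descending
row mean; companion samples are reordered with the reference permutation
so visual comparisons share a row order. `k` defaults to 5 and is a config
field — there is no principled value, so it is surfaced, not inferred.

## Rank-sum test

Group comparisons use the two-tailed unpaired Wilcoxon rank-sum
(Mann–Whitney) test. For `min(n, m) ≤ 8` and tie-free data the null
distribution of U is enumerated exactly by dynamic programming and the
two-sided p is the doubled smaller tail (capped at 1), which matches
scipy's exact method. Otherwise the normal approximation is used with the
standard tie correction and a continuity correction that shrinks
`|U − μ|` by ½ toward zero — so identical groups give p = 1 exactly, and
a fully tied pooled sample (variance 0) is reported as p = 1 rather than
a division by zero.

## Counting and differential expression

Union-mode stranded counting assigns a fragment to a gene iff it overlaps
that gene's exon union on the same strand and no other gene's; fragments
overlapping exons of two or more genes are `ambiguous`, same-locus
opposite-strand fragments `wrong_strand`, the rest `no_feature`. The four
tallies always sum to the input count. Fragments are counted once (one
count per fragment, not per mate).

The differential test is an original, self-contained reimplementation of
the classical count-based approach:

1. **Size factors** by median-of-ratios over genes with nonzero counts in
   every sample.
2. **Dispersion**: per-gene method-of-moments from pooled within-condition
   variance of normalized counts, `α̂ = (v − μ·ξ)/μ²` with
   `ξ = mean(1/ŝ_j)` the shot-noise scale. These estimates are unbiased
   but heavily right-skewed at 2 replicates, so the mean–dispersion trend
   `α(μ) = a₀ + a₁/μ` is fitted to *bin means* over mean-expression bins
   (local averaging); a robust/trimmed fit would chase the median and
   underestimate dispersion by ~30% at 2 degrees of freedom, inflating
   false positives. Gene estimates are then shrunk toward the trend with
   weight `prior_df/(prior_df + residual_df)` (prior strength 10), floored
   at 1e-8.
3. **Test**: conditional on the total of the two per-condition count sums,
   the two-sided p is the summed probability of all splits at most as
   likely as the observed one, under independent NB models for the two
   sums (means `q̂·Σŝ`, variances `μ + α q̂² Σŝ²`). The support is scanned
   fully for totals ≤ 5000 and windowed at ±40 SD (always including the
   observation) beyond that; log-space accumulation keeps tiny tails
   stable. On nulls with known dispersion this test is calibrated to ~5%
   at the 0.05 level by construction and verified by simulation.
4. **BH adjustment** (statsmodels) and classification: `up` if
   `padj < α`, FC ≥ 2.5 and base mean ≥ 200; `down` symmetric with
   FC ≤ 1/2.5; genes below base mean 200 are `low_expression` regardless of
   significance; everything else `unchanged` — a partition of the gene
   set. Fold changes are ratios of size-factor-normalized condition means
   with a pseudo-count of 1 (zero handling is otherwise undefined), and
   the threshold applies to these raw ratios, not shrunken ones.

Top-active ranking divides normalized counts by exon-union gene length and
sorts descending, with gene-identifier tie-breaks for determinism.

Caveat: median-of-ratios factors assume most genes unchanged; strongly
unbalanced differential expression (many changes in one direction) shifts
the median and biases fold changes toward the majority — visible in
simulations that plant one-directional changes in ≥20% of genes.

## qPCR arithmetic

Inputs are linear-scale relative abundances (a helper converts Ct assuming
amplification efficiency 2, `abundance = 2^−Ct`; efficiency calibration is
out of scope). Fold enrichment is the double ratio
`(IP_t/Input_t)/(IP_c/Input_c)` — the standard reading of "fold enrichment
relative to input DNA and a control region". Spike-in quantification
divides by the exogenous standard (default ERCC-00074) and is reported as
fold induction relative to a named baseline sample, which is 1 by
construction. Splice-product fractions divide by the 3'-UTR total proxy.
All three are exactly invariant to per-sample global multiplicative
factors — the property their references exist to provide — and replicate
rows sharing labels are summarized as mean ± sd.

## Synthetic-data generator

The generator emulates the *structure* of a two-genotype × two-treatment
promoter-chromatin study, not any particular dataset:

- **Annotation**: genes laid left-to-right with uniform random lengths
  (default 2–10 kb) and intergenic gaps (1–8 kb), random strand, 1–5 exons
  with a 50 bp minimum segment; first and last segments are exons so TSS
  and TES are exonic. Overflow raises an explicit placement error.
- **ChIP fragments**: a mixture of genome-wide uniform background and one
  symmetric triangular peak per gene centred on the anchor with half-width
  `peak_shape` (default 500 bp). The triangle is the simplest integrable
  shape with a single mode; peak mass is `amplitude × half-width` in
  background-rate units, so `amplitude` reads directly as apex fold
  enrichment over background. Input controls are the same model with
  amplitude 0. Default amplitudes (8 at active promoters, 20 after
  induction, × 0.25 without Cfp1, background 0.01 fragments/bp) are
  calibration choices in the realistic range of strong promoter-mark
  enrichment; no published effect sizes are encoded, which is why they are
  config fields rather than constants.
- **RNA fragments**: per-gene expected masses (expression × condition fold
  change) split into sense mass placed uniformly within exons on the gene
  strand, and divergent antisense mass placed on the opposite strand in a
  1 kb span immediately upstream of the TSS / downstream of the TES —
  fractions default to 2% per boundary in wild-type and 6% without Cfp1,
  low-abundance by design. Counts are multinomial in the masses, so
  requested totals are conserved exactly.
- **qPCR panels**: truth tables with multiplicative lognormal noise of
  unit mean (`σ² = ln(1 + cv²)`, `μ = −σ²/2`) and spike-in rows constant
  across samples by construction.

Everything is driven by `numpy.random.default_rng` seeds; identical
configs and seeds give byte-identical fragment frames and output files.
Sub-seeds for pipeline stages are derived by hashing the config hash with
a stage tag and XORing the user seed, so stages are independent but fully
reproducible.

What the generator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: sequence content and base qualities
(no FASTQ), alignment and mapping errors, splice-junction reads, GC or
fragment-length biases, chromatin-accessibility background structure,
overdispersion between biological replicates beyond the NB count model,
and gene-density/overlap patterns of real genomes (simulated genes never
overlap). Results on this generator validate the *arithmetic and
statistics* of the pipeline, not the biology of any particular dataset.

## Pipeline and problem sizes

The default synthetic configuration uses a 2 × 1 Mb genome, 200 genes
(40 induced at fold 6, 25 repressed at fold 0.2), 100k ChIP fragments per
replicate × 2 replicates per sample, 120k RNA fragments per replicate × 2
replicates per condition, flank 3 kb, and the 100/20 window grid — sizes
chosen so a full run completes in seconds while every stage operates far
from small-sample edge cases. Calibration studies use 5,000-gene nulls
over five seeds and 2,200-gene planted-change tables at NB dispersion 0.1
and mean 500, the regime where the filters (base mean 200, FC 2.5) are
active but not saturating. Stage outputs embed the configuration hash and
seed on a comment line; the JSON report omits wall-clock time so reruns
are byte-identical.

## Known limitations

- The conditional NB test assumes the dispersion is known when conditioning;
  with 2 replicates the shrinkage carries most of the information, so
  strongly gene-specific dispersions are under-served (a limitation shared
  by trend-based small-sample methods).
- The exact rank-sum path refuses ties rather than enumerating the
  permutation distribution with ties; tied data take the corrected
  approximation regardless of sample size.
- bedGraph round-trips quantize values through decimal formatting (`%.8g`);
  byte-exact workflows should stay with the in-memory tracks.
- Simulated ChIP fragments can collide by chance at realistic depths, so
  deduplicated library sizes fall slightly below requested totals — the
  same behaviour real deduplication has.
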