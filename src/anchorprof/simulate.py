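"""Synthetic study-design generator.

Emulates the data layout of a two-genotype (wild-type vs Cfp1-null) x
two-treatment (untreated vs doxorubicin) ES-cell experiment: a small
annotated genome, ChIP-seq fragment sets with TSS-centred promoter-mark
enrichment plus an input control, stranded paired-end RNA-seq fragments
with low-abundance divergent antisense transcription at TSS and TES, and
qPCR abundance panels with spike-in rows.

Everything is driven by ``numpy.random.default_rng`` seeds: the same
configuration and seed reproduce byte-identical outputs, and requested
fragment totals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import Gene, GeneAnnotation
from .fragments import make_fragments

__all__ = [
    "SimulationConfig",
    "ChipEnrichmentSpec",
    "RnaExpressionSpec",
    "PlacementError",
    "simulate_annotation",
    "simulate_chip_fragments",
    "simulate_rna_fragments",
    "simulate_qpcr_panel",
]

MIN_SEGMENT = 50  # smallest exon or intron, bp


class PlacementError(ValueError):
    """Raised when the genome cannot hold the requested genes and gaps."""


@dataclass(frozen=True)
class SimulationConfig:
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    intergenic_gap_range: tuple[int, int] = (1_000, 8_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        for lo, hi in (self.gene_length_range, self.intergenic_gap_range):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")


@dataclass(frozen=True)
class ChipEnrichmentSpec:
    """TSS-centred immunoprecipitation enrichment model.

    Fragment start positions are a mixture of a genome-wide uniform
    background and one symmetric triangular peak per gene, centred on the
    anchor with the given half-width; ``peak_amplitude`` is the fold
    enrichment of peak apex density over background, so each peak carries
    mass amplitude x half_width (in background-rate units).  Amplitude may
    be a scalar or a per-gene mapping; an input control is the same spec
    with amplitude 0.
    """

    background_rate: float = 0.01  # fragments per bp, genome-wide uniform
    peak_amplitude: float | Mapping[str, float] = 10.0
    peak_shape: int = 500  # half-width, bp
    anchor: str = "TSS"  # "TSS" or "TES"
    fragment_length: int = 200

    def __post_init__(self) -> None:
        amps = (
            self.peak_amplitude.values()
            if isinstance(self.peak_amplitude, Mapping)
            else [self.peak_amplitude]
        )
        if any(a < 0 for a in amps):
            raise ValueError("peak_amplitude must be >= 0")
        if self.peak_shape <= 0:
            raise ValueError("peak_shape (half-width) must be positive")
        if self.fragment_length <= 0 or self.background_rate <= 0:
            raise ValueError("fragment_length and background_rate must be positive")

    def amplitude_for(self, gene_id: str) -> float:
        if isinstance(self.peak_amplitude, Mapping):
            return float(self.peak_amplitude.get(gene_id, 0.0))
        return float(self.peak_amplitude)


@dataclass(frozen=True)
class RnaExpressionSpec:
    """Per-gene expression with divergent antisense emission.

    ``expression`` gives each gene's expected sense fragment mass (scalar
    applies to all genes).  A fraction ``antisense_fraction_tss`` of each
    gene's mass is emitted as short fragments on the opposite strand in the
    ``antisense_span`` immediately upstream of the TSS, and
    ``antisense_fraction_tes`` likewise downstream of the TES.
    ``fold_changes`` maps condition label -> per-gene multiplicative effect
    (genes absent from the mapping keep factor 1).
    """

    expression: float | Mapping[str, float] = 100.0
    antisense_fraction_tss: float = 0.02
    antisense_fraction_tes: float = 0.02
    antisense_span: int = 1_000
    fold_changes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    fragment_length: int = 200

    def __post_init__(self) -> None:
        for f in (self.antisense_fraction_tss, self.antisense_fraction_tes):
            if not 0.0 <= f <= 1.0:
                raise ValueError("antisense fractions must be in [0, 1]")
        if self.antisense_fraction_tss + self.antisense_fraction_tes > 1.0:
            raise ValueError("antisense fractions must sum to <= 1")
        if self.antisense_span <= 0:
            raise ValueError("antisense_span must be positive")
        for cond, fcs in self.fold_changes.items():
            if any(v <= 0 for v in fcs.values()):
                raise ValueError(f"fold changes for {cond!r} must be > 0")

    def expression_for(self, gene_id: str) -> float:
        if isinstance(self.expression, Mapping):
            return float(self.expression.get(gene_id, 0.0))
        return float(self.expression)

    def fold_change_for(self, gene_id: str, condition: str) -> float:
        return float(self.fold_changes.get(condition, {}).get(gene_id, 1.0))


def _draw_exons(rng: np.random.Generator, start: int, end: int) -> tuple[tuple[int, int], ...]:
    """1-5 exons: alternate exon/intron segments with a minimum size, the
    first and last segments being exons (TSS and TES are exonic)."""
    length = end - start
    n_exons = int(rng.integers(1, 6))
    while n_exons > 1 and (2 * n_exons - 1) * MIN_SEGMENT > length:
        n_exons -= 1
    if n_exons == 1:
        return ((start, end),)
    n_seg = 2 * n_exons - 1
    extra = length - n_seg * MIN_SEGMENT
    extras = rng.multinomial(extra, np.full(n_seg, 1.0 / n_seg))
    seg_lengths = MIN_SEGMENT + extras
    bounds = start + np.concatenate(([0], np.cumsum(seg_lengths)))
    return tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, n_seg, 2))


def simulate_annotation(config: SimulationConfig) -> GeneAnnotation:
    """Place non-overlapping genes with random strand and 1-5 exons.

    Genes are laid down left to right with random intergenic gaps, spilling
    onto the next chromosome when one fills up; running out of genome raises
    :class:`PlacementError`.
    """
    rng = np.random.default_rng(config.seed)
    chroms = list(config.chrom_sizes)
    genes: list[Gene] = []
    ci = 0
    cursor = 0
    i = 0
    while i < config.n_genes:
        gap = int(rng.integers(config.intergenic_gap_range[0], config.intergenic_gap_range[1] + 1))
        length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
        start = cursor + gap
        end = start + length
        if ci >= len(chroms):
            raise PlacementError(
                f"genome too small: placed {i} of {config.n_genes} genes"
            )
        if end > config.chrom_sizes[chroms[ci]]:
            ci += 1
            cursor = 0
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _draw_exons(rng, start, end)
        genes.append(Gene(f"gene{i:05d}", chroms[ci], start, end, strand, exons))
        cursor = end
        i += 1
    return GeneAnnotation(genes, dict(config.chrom_sizes))


def _uniform_background(rng, chrom_sizes, n, fragment_length):
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    idx = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    starts = np.empty(n, dtype=np.int64)
    for k, c in enumerate(chroms):
        m = idx == k
        hi = max(chrom_sizes[c] - fragment_length, 1)
        starts[m] = rng.integers(0, hi, size=int(m.sum()))
    return np.array(chroms, dtype=object)[idx], starts


def simulate_chip_fragments(
    annotation: GeneAnnotation,
    spec: ChipEnrichmentSpec,
    total_fragments: int,
    seed: int,
) -> pd.DataFrame:
    """Draw ChIP fragments from the background + per-anchor peak mixture."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    rng = np.random.default_rng(seed)
    genome_len = sum(annotation.chrom_sizes.values())
    genes = annotation.genes
    weights = np.empty(len(genes) + 1, dtype=np.float64)
    weights[0] = genome_len  # background mass, in background-rate units
    for j, g in enumerate(genes):
        weights[j + 1] = spec.amplitude_for(g.gene_id) * spec.peak_shape
    counts = rng.multinomial(total_fragments, weights / weights.sum())

    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    bg_chrom, bg_start = _uniform_background(
        rng, annotation.chrom_sizes, counts[0], spec.fragment_length
    )
    chroms.append(bg_chrom)
    starts.append(bg_start)
    half = spec.fragment_length // 2
    for j, g in enumerate(genes):
        n = counts[j + 1]
        if n == 0:
            continue
        anchor = g.tss if spec.anchor == "TSS" else g.tes
        centers = rng.triangular(anchor - spec.peak_shape, anchor, anchor + spec.peak_shape, size=n)
        s = np.rint(centers).astype(np.int64) - half
        s = np.clip(s, 0, annotation.chrom_sizes[g.chrom] - spec.fragment_length)
        chroms.append(np.full(n, g.chrom, dtype=object))
        starts.append(s)
    chrom = np.concatenate(chroms)
    start = np.concatenate(starts)
    strand = np.where(rng.random(total_fragments) < 0.5, "+", "-")
    return make_fragments(chrom, start, start + spec.fragment_length, strand)


def simulate_rna_fragments(
    annotation: GeneAnnotation,
    spec: RnaExpressionSpec,
    condition: str,
    total_fragments: int,
    seed: int,
) -> pd.DataFrame:
    """Draw stranded RNA fragments: sense mass within exons on the gene
    strand, divergent antisense mass upstream of the TSS and downstream of
    the TES on the opposite strand; per-gene counts are multinomial in the
    expected masses."""
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    rng = np.random.default_rng(seed)
    genes = annotation.genes
    f_tss, f_tes = spec.antisense_fraction_tss, spec.antisense_fraction_tes
    mass = np.array(
        [spec.expression_for(g.gene_id) * spec.fold_change_for(g.gene_id, condition) for g in genes]
    )
    if mass.sum() <= 0:
        raise ValueError("total expression mass must be positive")
    # component layout: per gene (sense, antisense-TSS, antisense-TES)
    comp = np.concatenate([mass * (1 - f_tss - f_tes), mass * f_tss, mass * f_tes])
    counts = rng.multinomial(total_fragments, comp / comp.sum())
    n_genes = len(genes)
    fl = spec.fragment_length
    opposite = {"+": "-", "-": "+"}

    chroms, starts, ends, strands = [], [], [], []

    def emit(chrom, s, e, strand, n):
        chroms.append(np.full(n, chrom, dtype=object))
        starts.append(s)
        ends.append(e)
        strands.append(np.full(n, strand, dtype=object))

    for j, g in enumerate(genes):
        n_sense = counts[j]
        if n_sense:
            exons = g.exons or ((g.start, g.end),)
            ex_len = np.array([e - s for s, e in exons], dtype=np.float64)
            pick = rng.choice(len(exons), size=n_sense, p=ex_len / ex_len.sum())
            s = np.empty(n_sense, dtype=np.int64)
            e = np.empty(n_sense, dtype=np.int64)
            for k, (xs, xe) in enumerate(exons):
                m = pick == k
                nm = int(m.sum())
                if not nm:
                    continue
                hi = max(xe - fl, xs + 1)
                s[m] = rng.integers(xs, hi, size=nm)
                e[m] = np.minimum(s[m] + fl, xe)
            emit(g.chrom, s, e, g.strand, n_sense)
        for comp_idx, at_tss in ((n_genes + j, True), (2 * n_genes + j, False)):
            n_anti = counts[comp_idx]
            if not n_anti:
                continue
            # divergent window: upstream of TSS / downstream of TES
            if at_tss:
                win = (g.tss - spec.antisense_span, g.tss) if g.strand == "+" else (
                    g.tss + 1, g.tss + 1 + spec.antisense_span)
            else:
                win = (g.tes + 1, g.tes + 1 + spec.antisense_span) if g.strand == "+" else (
                    g.tes - spec.antisense_span, g.tes)
            lo = max(win[0], 0)
            hi = min(win[1], annotation.chrom_sizes[g.chrom])
            s_hi = max(hi - fl, lo + 1)
            s = rng.integers(lo, s_hi, size=n_anti)
            e = np.minimum(s + fl, hi)
            emit(g.chrom, s, e, opposite[g.strand], n_anti)

    return make_fragments(
        np.concatenate(chroms), np.concatenate(starts), np.concatenate(ends),
        np.concatenate(strands),
    )


def simulate_qpcr_panel(
    true_abundances: pd.DataFrame,
    spikein_copies: Mapping[str, float] | float = 1000.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """qPCR abundance table with spike-in rows and per-well lognormal noise.

    ``true_abundances``: targets x samples frame of linear-scale copies.
    Spike-ins are constant across samples by construction.  Noise is
    multiplicative lognormal with unit mean and coefficient of variation
    ``noise_cv`` (``noise_cv=0`` returns the truth exactly).
    """
    if (true_abundances.to_numpy() <= 0).any():
        raise ValueError("abundances must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    if not isinstance(spikein_copies, Mapping):
        spikein_copies = {"ERCC-00074": float(spikein_copies)}
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    mu = -(sigma**2) / 2  # unit-mean lognormal

    def well(value: float) -> float:
        if noise_cv == 0:
            return float(value)
        return float(value * rng.lognormal(mu, sigma))

    for rep in range(1, n_replicates + 1):
        for sample in true_abundances.columns:
            for target in true_abundances.index:
                rows.append((target, sample, "target", well(true_abundances.at[target, sample]), rep))
            for name, copies in spikein_copies.items():
                rows.append((name, sample, "spikein", well(copies), rep))
    return pd.DataFrame(rows, columns=["target", "sample", "role", "abundance", "replicate"])
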