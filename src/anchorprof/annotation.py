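"""Gene models and GTF input/output.

Internal coordinates are 0-based, half-open everywhere; conversion to the
1-based, inclusive GTF convention happens only at the file boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Gene", "GeneAnnotation", "read_gtf", "write_gtf"]


@dataclass(frozen=True)
class Gene:
    """One gene model.

    ``start``/``end`` span the full transcription unit (0-based, half-open);
    ``exons`` is a sorted, non-overlapping list of (start, end) intervals
    covering at least the first and last base of the unit.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: last transcribed base (strand-aware)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def exon_union_length(self) -> int:
        """Total exonic bases (exons are stored disjoint)."""
        if not self.exons:
            return self.length
        return sum(e - s for s, e in self.exons)


class GeneAnnotation:
    """A set of gene models over a genome of known chromosome sizes."""

    def __init__(self, genes: list[Gene], chrom_sizes: dict[str, int]):
        for g in genes:
            if g.chrom not in chrom_sizes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > chrom_sizes[g.chrom]:
                raise ValueError(f"{g.gene_id}: extends past end of {g.chrom}")
        self.genes = list(genes)
        self.chrom_sizes = dict(chrom_sizes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "n_exons": [len(g.exons) for g in self.genes],
                "exon_union_length": [g.exon_union_length for g in self.genes],
            }
        )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Write gene and exon features as GTF (1-based, inclusive)."""
    rows = []
    for g in annotation:
        attrs = f'gene_id "{g.gene_id}";'
        rows.append((g.chrom, "anchorprof", "gene", g.start + 1, g.end, ".", g.strand, ".", attrs))
        exons = g.exons or ((g.start, g.end),)
        for i, (s, e) in enumerate(exons, 1):
            ex_attrs = f'gene_id "{g.gene_id}"; exon_number "{i}";'
            rows.append((g.chrom, "anchorprof", "exon", s + 1, e, ".", g.strand, ".", ex_attrs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False, quoting=3)


def read_gtf(path, chrom_sizes: dict[str, int] | None = None) -> GeneAnnotation:
    """Read gene/exon features from a GTF file into a :class:`GeneAnnotation`.

    If ``chrom_sizes`` is omitted, each chromosome's size is taken as the
    rightmost feature end (sufficient for round-tripping simulated files).
    """
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attrs"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df["gene_id"] = df["attrs"].map(lambda a: dict(_ATTR_RE.findall(a)).get("gene_id", ""))
    genes: list[Gene] = []
    exon_rows = df[df["feature"] == "exon"]
    for _, row in df[df["feature"] == "gene"].iterrows():
        ex = exon_rows[exon_rows["gene_id"] == row["gene_id"]]
        exons = tuple(sorted((int(s) - 1, int(e)) for s, e in zip(ex["start"], ex["end"])))
        genes.append(
            Gene(
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                start=int(row["start"]) - 1,
                end=int(row["end"]),
                strand=row["strand"],
                exons=exons,
            )
        )
    if chrom_sizes is None:
        chrom_sizes = df.groupby("chrom")["end"].max().astype(int).to_dict()
    return GeneAnnotation(genes, chrom_sizes)
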