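"""Fragment filtering, replicate merging and normalized coverage tracks.

The filtering/merging policy mirrors a standard ChIP-seq preprocessing
chain: keep uniquely aligned fragments, optionally collapse duplicates,
pool biological replicates into one fragment set, then normalize per-base
coverage to library size on a reads-per-million scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import validate_fragments

__all__ = [
    "CoverageTrack",
    "FilterReport",
    "filter_fragments",
    "merge_replicates",
    "compute_coverage",
    "normalize_track",
    "split_by_strand",
    "write_bedgraph",
    "read_bedgraph",
]

RPM_SCALE = 1e6  # reads-per-million normalization constant


@dataclass
class CoverageTrack:
    """Per-base signal per chromosome.

    ``values[chrom][b]`` is the signal at base ``b``.  ``normalization_factor``
    is 1.0 for raw fragment-depth tracks and ``1e6 / library_size`` after
    :func:`normalize_track`; ``library_size`` is the number of fragments the
    track was built from.
    """

    values: dict[str, np.ndarray]
    normalization_factor: float = 1.0
    library_size: int | None = None

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def total(self) -> float:
        """Genome-wide sum of signal."""
        return float(sum(v.sum() for v in self.values.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            values={c: v * factor for c, v in self.values.items()},
            normalization_factor=self.normalization_factor * factor,
            library_size=self.library_size,
        )


@dataclass
class FilterReport:
    n_input: int
    n_nonunique_removed: int
    n_duplicates_removed: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_nonunique_removed - self.n_duplicates_removed


def filter_fragments(
    records: pd.DataFrame,
    require_unique: bool = True,
    remove_duplicates: bool = True,
) -> tuple[pd.DataFrame, FilterReport]:
    """Select uniquely aligned fragments and optionally collapse duplicates.

    Duplicates are keyed on (chrom, start, end, strand): fragment-level
    deduplication without sequence access.  Returns the surviving records
    and a report of how many were removed at each step.
    """
    n_input = len(records)
    out = records
    n_nonunique = 0
    if require_unique:
        mask = out["unique"].to_numpy(dtype=bool)
        n_nonunique = int((~mask).sum())
        out = out[mask]
    n_dup = 0
    if remove_duplicates:
        before = len(out)
        out = out.drop_duplicates(subset=["chrom", "start", "end", "strand"], keep="first")
        n_dup = before - len(out)
    if not remove_duplicates and not require_unique:
        return records, FilterReport(n_input, 0, 0)
    return out.reset_index(drop=True), FilterReport(n_input, n_nonunique, n_dup)


def merge_replicates(recordsets: list[pd.DataFrame], chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Pool replicate fragment sets into one (library sizes add).

    With ``chrom_sizes`` given, every set is validated against the same
    chromosome universe; a fragment on an unknown chromosome is an error.
    """
    nonempty = [r for r in recordsets if len(r)]
    if chrom_sizes is not None:
        for r in nonempty:
            validate_fragments(r, chrom_sizes)
    else:
        universe = set()
        for r in nonempty:
            universe |= set(r["chrom"].unique())
        for i, r in enumerate(nonempty):
            extra = set(r["chrom"].unique()) - universe
            if extra:
                raise ValueError(f"replicate {i}: chromosomes outside universe: {sorted(extra)}")
    if not nonempty:
        return recordsets[0].copy() if recordsets else pd.DataFrame()
    return pd.concat(nonempty, ignore_index=True)


def compute_coverage(records: pd.DataFrame, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Unnormalized fragment-depth track: value at base b = number of
    fragments whose interval contains b.

    Computed per chromosome by difference-array accumulation (+1 at each
    fragment start, -1 at each end) followed by a cumulative sum.
    """
    validate_fragments(records, chrom_sizes)
    values = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    for chrom, sub in records.groupby("chrom", sort=False):
        diff = np.zeros(chrom_sizes[chrom] + 1, dtype=np.float64)
        np.add.at(diff, sub["start"].to_numpy(), 1.0)
        np.add.at(diff, sub["end"].to_numpy(), -1.0)
        values[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(values=values, normalization_factor=1.0, library_size=len(records))


def normalize_track(track: CoverageTrack, library_size: int | None = None) -> CoverageTrack:
    """Rescale a raw track to reads-per-million: scale = 1e6 / library_size.

    The constant is a convention (any constant yields identical comparative
    statistics downstream); it is recorded in ``normalization_factor``.
    """
    if library_size is None:
        library_size = track.library_size
    if not library_size or library_size <= 0:
        raise ValueError("library_size must be positive for normalization")
    scale = RPM_SCALE / library_size
    out = track.scaled(scale)
    out.normalization_factor = scale
    out.library_size = library_size
    return out


def split_by_strand(
    records: pd.DataFrame, chrom_sizes: dict[str, int]
) -> tuple[CoverageTrack, CoverageTrack]:
    """Coverage per fragment strand; plus + minus equals the unsplit track.

    Both returned tracks carry the *combined* library size so that a shared
    normalization keeps the two strands on one scale.
    """
    strands = records["strand"].to_numpy()
    bad = ~np.isin(strands, ["+", "-"])
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(f"unstranded fragment at row {records.index[i]} (strand={strands[i]!r})")
    plus = compute_coverage(records[strands == "+"], chrom_sizes)
    minus = compute_coverage(records[strands == "-"], chrom_sizes)
    plus.library_size = minus.library_size = len(records)
    return plus, minus


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as bedGraph (0-based, half-open), run-length collapsed;
    zero runs are omitted."""
    rows = []
    for chrom in track.values:
        v = track.values[chrom]
        if len(v) == 0:
            continue
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        for s, e in zip(starts, ends):
            if v[s] != 0:
                rows.append((chrom, int(s), int(e), float(v[s])))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.8g"
    )


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str}, comment="#")
    values = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in values:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in chrom_sizes")
        arr = values[chrom]
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[s:e] = v
    return CoverageTrack(values=values)
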