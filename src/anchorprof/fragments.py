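"""Fragment records and BED6 input/output.

A fragment set is a :class:`pandas.DataFrame` with columns

    chrom (str), start (int), end (int), strand ('+'/'-'),
    duplicate (bool), unique (bool)

in 0-based, half-open coordinates.  Optional extra columns (e.g. ``sample``)
are carried through untouched.  This mirrors deduplicated paired-end
fragments after alignment; the strand is the transcribed strand inferred
from mate orientation, so it defines sense vs antisense relative to a gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "FRAGMENT_COLUMNS",
    "empty_fragments",
    "make_fragments",
    "validate_fragments",
    "read_bed6",
    "write_bed6",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "duplicate", "unique"]


def empty_fragments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "duplicate": pd.Series(dtype=bool),
            "unique": pd.Series(dtype=bool),
        }
    )


def make_fragments(chrom, start, end, strand, duplicate=False, unique=True, **extra) -> pd.DataFrame:
    """Assemble a fragment frame from column vectors (scalars broadcast)."""
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end, "strand": strand})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["duplicate"] = duplicate
    df["strand"] = df["strand"].astype(str)
    df["unique"] = unique
    for k, v in extra.items():
        df[k] = v
    return df


def validate_fragments(df: pd.DataFrame, chrom_sizes: dict[str, int] | None = None) -> None:
    """Raise ``ValueError`` on malformed records; name the first offender."""
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fragment frame missing columns: {missing}")
    bad = df.index[df["start"].to_numpy() >= df["end"].to_numpy()]
    if len(bad):
        r = df.loc[bad[0]]
        raise ValueError(f"fragment {r.chrom}:{r.start}-{r.end} has start >= end")
    if chrom_sizes is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"fragment on unknown chromosome {chrom!r}")
            over = sub.index[sub["end"].to_numpy() > chrom_sizes[chrom]]
            if len(over):
                r = df.loc[over[0]]
                raise ValueError(
                    f"fragment {r.chrom}:{r.start}-{r.end} extends past chromosome end "
                    f"({chrom_sizes[chrom]})"
                )
            under = sub.index[sub["start"].to_numpy() < 0]
            if len(under):
                r = df.loc[under[0]]
                raise ValueError(f"fragment {r.chrom}:{r.start}-{r.end} has negative start")


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write fragments as 6-column BED (0-based, half-open, strand in col 6)."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "name": df.get("sample", pd.Series(["frag"] * len(df), index=df.index)),
            "score": 0,
            "strand": df["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    bed = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str},
                      comment="#")
    return make_fragments(bed["chrom"], bed["start"], bed["end"], bed["strand"], sample=bed["name"])
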