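"""qPCR normalization arithmetic for validation assays.

Three small-number schemes, all scale-invariant to per-sample global
multiplicative factors (which is exactly what their internal references
exist to provide):

* ChIP-qPCR fold enrichment: (IP/input at the target) over (IP/input at a
  control intergenic region).
* Spike-in absolute quantification: abundance over an exogenous spike-in
  standard (default ERCC-00074), expressed as fold induction relative to a
  baseline sample.
* Splicing-product fractions: each product over a total-RNA proxy measured
  on the 3' UTR.

Tables are tidy frames with columns (target, sample, role, abundance) on a
linear scale; replicate rows sharing (target, sample, role) are averaged
and results carry mean +- sd.  A helper converts Ct values assuming
amplification efficiency 2 (abundance = 2**-Ct).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ct_to_abundance",
    "chip_fold_enrichment",
    "spikein_fold_induction",
    "splice_product_fraction",
    "summarize_replicates",
]


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of abundance over replicate rows sharing
    (target, sample, role)."""
    grouped = table.groupby(["target", "sample", "role"])["abundance"]
    return grouped.agg(mean="mean", sd="std", n="count").reset_index()


def ct_to_abundance(ct) -> np.ndarray:
    """Linear-scale relative abundance from Ct at efficiency 2."""
    return np.power(2.0, -np.asarray(ct, dtype=np.float64))


def _lookup(table: pd.DataFrame, target: str, sample: str, role: str | None = None) -> float:
    sel = (table["target"] == target) & (table["sample"] == sample)
    if role is not None and "role" in table.columns:
        sel &= table["role"] == role
    vals = table.loc[sel, "abundance"]
    if vals.empty:
        where = f" with role {role!r}" if role else ""
        raise KeyError(f"missing abundance row: target {target!r}, sample {sample!r}{where}")
    v = float(vals.mean())
    if v <= 0:
        raise ValueError(f"non-positive abundance for target {target!r}, sample {sample!r}")
    return v


def _samples(table: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(table["sample"]))


def chip_fold_enrichment(
    table: pd.DataFrame, target: str, control_region: str
) -> pd.Series:
    """Fold enrichment relative to input DNA and a control region.

    Per sample: (IP_target / Input_target) / (IP_control / Input_control).
    Expects, for each of ``target`` and ``control_region``, one row with
    role ``target``/``control_region`` (the IP measurement) and one with
    role ``input``.
    """
    out = {}
    for sample in _samples(table):
        ip_t = _lookup(table, target, sample, "target")
        in_t = _lookup(table, target, sample, "input")
        ip_c = _lookup(table, control_region, sample, "control_region")
        in_c = _lookup(table, control_region, sample, "input")
        out[sample] = (ip_t / in_t) / (ip_c / in_c)
    return pd.Series(out, name=f"fold_enrichment[{target}]")


def spikein_fold_induction(
    table: pd.DataFrame,
    gene: str,
    baseline_sample: str,
    reference: str = "ERCC-00074",
) -> pd.Series:
    """Spike-in-normalized abundance as fold induction over a baseline.

    Per sample: normalized = abundance(gene)/abundance(reference); fold
    induction = normalized(sample)/normalized(baseline).  The baseline
    sample maps to 1 by construction.
    """
    samples = _samples(table)
    if baseline_sample not in samples:
        raise KeyError(f"baseline sample {baseline_sample!r} not in table")
    normalized = {}
    for sample in samples:
        ref = _lookup(table, reference, sample)
        normalized[sample] = _lookup(table, gene, sample) / ref
    base = normalized[baseline_sample]
    return pd.Series(
        {s: v / base for s, v in normalized.items()}, name=f"fold_induction[{gene}]"
    )


def splice_product_fraction(
    table: pd.DataFrame, product: str, total: str = "total_3utr"
) -> pd.Series:
    """Fraction of a splicing product relative to the total-RNA proxy."""
    out = {}
    for sample in _samples(table):
        tot = _lookup(table, total, sample)
        out[sample] = _lookup(table, product, sample) / tot
    return pd.Series(out, name=f"splice_fraction[{product}]")
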