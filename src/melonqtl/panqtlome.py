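"""Multi-study QTL integration: genome binning and hotspot classification.

QTL intervals from many mapping studies, aligned to common assembly
coordinates, are validated, binned into fixed-width genomic bins (default
5 Mb), and summarized as a bin x study support matrix.  Oversized intervals
(default > 15 Mb), whose positional information is too diffuse, are
excluded.  Bins are classified by the number of distinct supporting studies
(hotspot default: 6 or more).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinMatrix",
    "load_qtl_table",
    "validate_qtl_records",
    "bin_counts",
    "classify_bins",
    "study_summary",
    "make_bins",
]

QTL_COLUMNS = ["study", "chrom", "start", "end"]


@dataclass
class BinMatrix:
    """Bin x study QTL-record counts with per-bin distinct-study support.

    ``bins`` tiles each chromosome with fixed-width bins (terminal bins
    truncated at the chromosome end); ``matrix`` holds QTL-record counts per
    bin x study; ``support`` counts distinct studies with at least one
    assigned QTL per bin (a study with two QTLs in one bin contributes 1).
    """

    bins: pd.DataFrame
    matrix: pd.DataFrame
    support: pd.Series
    bin_size: int
    max_interval: int
    assign: str


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> pd.DataFrame:
    """Fixed-width genome partition; the last bin of each chromosome is
    truncated at the chromosome end.  Coordinates 1-based inclusive."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, length in chrom_sizes.items():
        starts = np.arange(1, length + 1, bin_size, dtype=np.int64)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + bin_size - 1, length))))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end"])


def validate_qtl_records(
    qtls: pd.DataFrame, chrom_sizes: dict[str, int]
) -> pd.DataFrame:
    """Validate and clip QTL records against the chromosome-sizes table.

    Rows with end < start or non-numeric coordinates are rejected with a
    logged warning carrying their row numbers; intervals extending past the
    chromosome end are clipped with a warning.  An unknown chromosome is an
    error.
    """
    missing = set(QTL_COLUMNS) - set(qtls.columns)
    if missing:
        raise ValueError(f"QTL table missing columns: {sorted(missing)}")
    unknown = set(qtls["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"unknown chromosomes in QTL table: {sorted(unknown)}")

    out = qtls.copy()
    out["start"] = pd.to_numeric(out["start"], errors="coerce")
    out["end"] = pd.to_numeric(out["end"], errors="coerce")
    bad = out["start"].isna() | out["end"].isna() | (out["end"] < out["start"]) | (out["start"] < 1)
    if bad.any():
        logger.warning(
            "rejecting %d malformed QTL rows (row numbers %s)",
            int(bad.sum()),
            list(out.index[bad]),
        )
        out = out.loc[~bad]
    out = out.astype({"start": np.int64, "end": np.int64})
    limits = out["chrom"].map(chrom_sizes)
    over = out["end"] > limits
    if over.any():
        logger.warning("clipping %d QTL intervals at chromosome ends", int(over.sum()))
        out.loc[over, "end"] = limits[over]
    if "donor" not in out.columns:
        out["donor"] = "unknown"
    return out.reset_index(drop=True)


def load_qtl_table(path, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Read a per-study QTL interval TSV (study, [trait,] chrom, start, end,
    [donor]) and validate it against the chromosome sizes."""
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str, "study": str})
    return validate_qtl_records(raw, chrom_sizes)


def _interval_length(qtls: pd.DataFrame) -> pd.Series:
    return qtls["end"] - qtls["start"] + 1  # 1-based inclusive


def bin_counts(
    qtls: pd.DataFrame,
    chrom_sizes: dict[str, int],
    bin_size: int = 5_000_000,
    max_interval: int = 15_000_000,
    assign: str = "overlap",
) -> BinMatrix:
    """Bin QTL intervals into the genome partition and count study support.

    Intervals longer than ``max_interval`` are excluded.  With
    ``assign="overlap"`` (default) a QTL is assigned to every bin its
    interval overlaps; with ``assign="midpoint"`` to exactly the bin holding
    its midpoint.
    """
    if assign not in ("overlap", "midpoint"):
        raise ValueError("assign must be 'overlap' or 'midpoint'")
    if max_interval <= 0:
        raise ValueError("max_interval must be positive")
    bins = make_bins(chrom_sizes, bin_size)
    studies = sorted(qtls["study"].unique()) if len(qtls) else []
    matrix = pd.DataFrame(0, index=bins.index, columns=studies, dtype=int)

    kept = qtls.loc[_interval_length(qtls) <= max_interval] if len(qtls) else qtls
    for _, q in kept.iterrows():
        sub = bins[bins["chrom"] == q["chrom"]]
        if assign == "midpoint":
            mid = (q["start"] + q["end"]) // 2
            hit = sub[(sub["bin_start"] <= mid) & (mid <= sub["bin_end"])]
        else:
            hit = sub[(sub["bin_start"] <= q["end"]) & (q["start"] <= sub["bin_end"])]
        matrix.loc[hit.index, q["study"]] += 1

    support = (matrix > 0).sum(axis=1)
    support.name = "n_studies"
    return BinMatrix(bins, matrix, support, int(bin_size), int(max_interval), assign)


def classify_bins(bm: BinMatrix, hotspot_min_studies: int = 6) -> tuple[pd.DataFrame, dict]:
    """Classify bins as empty / rare / hotspot by distinct-study support.

    hotspot <=> support >= ``hotspot_min_studies``.  The genome summary
    reports the bin count, the number of empty bins, and the number of bins
    with support >= k for every k up to the maximum observed.
    """
    support = bm.support
    cls = pd.Series("rare", index=support.index)
    cls[support == 0] = "empty"
    cls[support >= hotspot_min_studies] = "hotspot"
    table = bm.bins.copy()
    table["n_studies"] = support
    table["class"] = cls
    kmax = int(support.max()) if len(support) else 0
    summary = {
        "n_bins": int(len(support)),
        "n_empty": int((support == 0).sum()),
        "n_with_k_or_more": {k: int((support >= k).sum()) for k in range(1, kmax + 1)},
    }
    return table, summary


def study_summary(
    qtls: pd.DataFrame, max_interval: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-study QTL counts with overall mean and range.

    With ``max_interval`` set, oversized intervals are excluded first (the
    same rule as :func:`bin_counts`); by default all records are counted.
    """
    if qtls.empty:
        raise ValueError("QTL table is empty")
    kept = qtls if max_interval is None else qtls.loc[_interval_length(qtls) <= max_interval]
    counts = kept.groupby("study").size().rename("n_qtls").reset_index()
    overall = {
        "mean": float(counts["n_qtls"].mean()),
        "min": int(counts["n_qtls"].min()),
        "max": int(counts["n_qtls"].max()),
        "n_studies": int(len(counts)),
        "n_qtls": int(counts["n_qtls"].sum()),
    }
    return counts, overall
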