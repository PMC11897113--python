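"""SNP-index / delta-SNP-index bulk-segregant (QTL-seq) genome scanning.

Input is a per-site table of reference and total read counts for a
high-phenotype and a low-phenotype bulk.  The SNP-index of a site within a
bulk is the fraction of reads carrying the reference allele; the
delta-SNP-index is high minus low.  A sliding-window mean draws the trend
line, and maximal runs of windows whose |delta| exceeds a calling threshold
(default 0.4) with consistent sign become candidate QTL regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScanConfig",
    "QTLRegion",
    "filter_sites",
    "compute_snp_index",
    "sliding_window",
    "call_qtl_regions",
    "scan",
]

SITE_COLUMNS = ["chrom", "pos", "ref_high", "total_high", "ref_low", "total_low"]


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the whole-genome delta-SNP-index scan.

    ``min_depth``: each bulk must exceed this read depth at a site (per-bulk
    rule, stricter than a summed-depth filter).  ``window_size``/``step``
    control the sliding mean; ``threshold`` is applied to windowed |delta|;
    runs separated by at most ``merge_gap`` windows are merged.
    """

    min_depth: int = 20
    window_size: int = 1_000_000
    step: int = 100_000
    threshold: float = 0.4
    min_windows: int = 1
    merge_gap: int = 2


@dataclass(frozen=True)
class QTLRegion:
    """A called QTL region: 1-based inclusive bounds, the peak window and
    its windowed delta, and the sign of delta (+1 = reference-allele excess
    in the high bulk)."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    peak_delta: float
    sign: int


def _validate_sites(sites: pd.DataFrame) -> None:
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    for bulk in ("high", "low"):
        if (sites[f"ref_{bulk}"] > sites[f"total_{bulk}"]).any():
            raise ValueError(f"ref_{bulk} exceeds total_{bulk} at some site")
        if (sites[f"ref_{bulk}"] < 0).any():
            raise ValueError("negative read counts")


def filter_sites(sites: pd.DataFrame, min_depth: int = 20) -> pd.DataFrame:
    """Retain sites with total depth > ``min_depth`` in both bulks.

    Ordering is preserved; the result may be empty.
    """
    _validate_sites(sites)
    keep = (sites["total_high"] > min_depth) & (sites["total_low"] > min_depth)
    return sites.loc[keep].reset_index(drop=True)


def compute_snp_index(sites: pd.DataFrame) -> pd.DataFrame:
    """Add per-site SNP-index columns: idx_high, idx_low and delta.

    idx = ref/total per bulk; delta = idx_high - idx_low.  Sites with zero
    total depth in either bulk must have been filtered out beforehand.
    """
    _validate_sites(sites)
    if (sites["total_high"] == 0).any() or (sites["total_low"] == 0).any():
        raise ValueError("zero-depth sites present; run filter_sites first")
    out = sites.copy()
    out["idx_high"] = out["ref_high"] / out["total_high"]
    out["idx_low"] = out["ref_low"] / out["total_low"]
    out["delta"] = out["idx_high"] - out["idx_low"]
    return out


def sliding_window(
    track: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_size: int = 1_000_000,
    step: int = 100_000,
) -> pd.DataFrame:
    """Sliding-window means of the SNP-index track.

    Windows are tiled per chromosome at the given step, half-open
    [start, start + window_size) internally and reported 1-based inclusive.
    Only full-width windows are emitted (the trend line stops half a window
    short of the chromosome end), so every window mean rests on a comparable
    number of sites; a chromosome shorter than one window gets a single
    truncated window.  Each window's value is the arithmetic mean over its
    member sites; windows with no sites carry NaN and n_sites = 0.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    out = []
    for chrom, length in chrom_sizes.items():
        last_start = max(length - window_size + 1, 1)
        starts = np.arange(1, last_start + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window_size - 1, length)
        sub = track[track["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        win = pd.DataFrame({"chrom": chrom, "win_start": starts, "win_end": ends})
        win["mid"] = (win["win_start"] + win["win_end"]) // 2
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        n = hi - lo
        for col in ("idx_high", "idx_low", "delta"):
            if len(pos):
                csum = np.concatenate([[0.0], np.cumsum(sub[col].to_numpy())])
                with np.errstate(invalid="ignore"):
                    win[col] = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
            else:
                win[col] = np.nan
        win["n_sites"] = n
        out.append(win)
    return pd.concat(out, ignore_index=True)


def call_qtl_regions(
    windows: pd.DataFrame,
    threshold: float = 0.4,
    min_windows: int = 1,
    merge_gap: int = 2,
    sites: pd.DataFrame | None = None,
) -> list[QTLRegion]:
    """Call QTL regions from a windowed delta-SNP-index track.

    Maximal runs of consecutive non-missing windows with |delta| >=
    ``threshold`` and consistent sign become regions; qualifying runs of the
    same sign separated by at most ``merge_gap`` windows are merged, and
    runs shorter than ``min_windows`` are dropped.  Region bounds are the
    outermost window bounds, intersected with the covered sites when the
    site table is supplied; the peak is the window with maximal |delta|
    (leftmost on ties).
    """
    regions: list[QTLRegion] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("win_start").reset_index(drop=True)
        delta = sub["delta"].to_numpy()
        qual = np.zeros(len(sub), dtype=int)
        ok = ~np.isnan(delta) & (np.abs(delta) >= threshold)
        qual[ok] = np.sign(delta[ok]).astype(int)
        # runs of identical non-zero sign
        runs: list[tuple[int, int, int]] = []  # (first, last, sign)
        i = 0
        while i < len(qual):
            if qual[i] != 0:
                j = i
                while j + 1 < len(qual) and qual[j + 1] == qual[i]:
                    j += 1
                runs.append((i, j, int(qual[i])))
                i = j + 1
            else:
                i += 1
        # merge same-sign runs separated by <= merge_gap windows
        merged: list[tuple[int, int, int]] = []
        for run in runs:
            if merged and run[2] == merged[-1][2] and run[0] - merged[-1][1] - 1 <= merge_gap:
                merged[-1] = (merged[-1][0], run[1], run[2])
            else:
                merged.append(run)
        for first, last, sign in merged:
            if int(np.sum(qual[first : last + 1] == sign)) < min_windows:
                continue
            seg = sub.iloc[first : last + 1]
            start = int(seg["win_start"].min())
            end = int(seg["win_end"].max())
            if sites is not None:
                spos = sites.loc[
                    (sites["chrom"] == chrom)
                    & (sites["pos"] >= start)
                    & (sites["pos"] <= end),
                    "pos",
                ]
                if len(spos):
                    start, end = int(spos.min()), int(spos.max())
            absd = np.abs(seg["delta"].to_numpy())
            absd = np.where(np.isnan(absd), -np.inf, absd)
            peak_row = seg.iloc[int(np.argmax(absd))]
            regions.append(
                QTLRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    peak_pos=int(peak_row["mid"]),
                    peak_delta=float(peak_row["delta"]),
                    sign=sign,
                )
            )
    return regions


def scan(
    sites: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: ScanConfig = ScanConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[QTLRegion]]:
    """Whole-genome delta-SNP-index scan.

    Composition of depth filtering, per-site SNP-index computation, sliding
    windows, and region calling; fully deterministic.  Returns the site
    track, the window track, and the called regions.
    """
    if sites.empty:
        return sites, pd.DataFrame(), []
    kept = filter_sites(sites, config.min_depth)
    track = compute_snp_index(kept) if not kept.empty else kept
    if track.empty:
        return track, pd.DataFrame(), []
    windows = sliding_window(track, chrom_sizes, config.window_size, config.step)
    regions = call_qtl_regions(
        windows, config.threshold, config.min_windows, config.merge_gap, sites=track
    )
    return track, windows, regions
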