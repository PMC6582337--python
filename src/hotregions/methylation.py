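"""Methylation dynamics over region sets.

Per region and cell type, methylation is the unweighted mean of the per-CpG
methylated fractions inside the region (whole-genome bisulfite style input).
Per cell type, a region set is summarised by the median and interquartile
range of its region means; comparing the cross-cell-type IQR distributions
of HOT regions against CpG islands not touched by any HOT region quantifies
how stably hypomethylated HOT regions are.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import overlaps_any


def region_mean_methylation(
    calls: pd.DataFrame, regions: pd.DataFrame
) -> np.ndarray:
    """Unweighted mean methylated fraction of the CpGs in each region.

    ``calls`` has columns (chrom, pos, fraction); a CpG belongs to a region
    when start <= pos < end (half-open). Regions covering no CpG get NaN and
    are excluded from downstream summaries.
    """
    out = np.full(len(regions), np.nan)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy(), kind="mergesort")
        pos = sub["pos"].to_numpy(dtype=np.int64)[order]
        frac = sub["fraction"].to_numpy(dtype=float)[order]
        by_chrom[chrom] = (pos, np.concatenate([[0.0], np.cumsum(frac)]))
    rchrom = regions["chrom"].to_numpy()
    rstart = regions["start"].to_numpy(dtype=np.int64)
    rend = regions["end"].to_numpy(dtype=np.int64)
    for chrom in np.unique(rchrom):
        if chrom not in by_chrom:
            continue
        pos, csum = by_chrom[chrom]
        mask = rchrom == chrom
        lo = np.searchsorted(pos, rstart[mask], side="left")
        hi = np.searchsorted(pos, rend[mask], side="left")
        n = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        out[mask] = means
    return out


def dispersion_summary(region_means: Sequence[float]) -> tuple[float, float]:
    """(median, IQR) of a region set's mean methylation values.

    Quantiles are linear-interpolation (type 7); NaN (uncovered) regions are
    dropped first. Raises when nothing remains.
    """
    vals = np.asarray(region_means, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no regions with covered CpGs")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return float(med), float(q3 - q1)


def summarize_region_set(
    calls_by_cell_type: Mapping[str, pd.DataFrame], regions: pd.DataFrame
) -> pd.DataFrame:
    """Per-cell-type (median, IQR) of region mean methylation for one set."""
    rows = []
    for cell_type, calls in calls_by_cell_type.items():
        med, iqr = dispersion_summary(region_mean_methylation(calls, regions))
        rows.append({"cell_type": cell_type, "median": med, "iqr": iqr})
    return pd.DataFrame(rows)


def hot_vs_nonhot_cgi(
    hot_summary: pd.DataFrame, nonhot_cgi_summary: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Compare methylation dispersion of HOT regions vs non-HOT CpG islands.

    Both inputs are per-cell-type summaries (cell_type, median, iqr) over
    the same cell types. Returns the merged comparison table and the ratio
    median-over-cell-types(IQR nonHOT CGI) / median-over-cell-types(IQR HOT);
    the ratio is inf when the HOT IQRs are all 0.
    """
    a = hot_summary.set_index("cell_type")
    b = nonhot_cgi_summary.set_index("cell_type")
    if set(a.index) != set(b.index):
        raise ValueError(
            f"cell-type sets differ: {sorted(set(a.index) ^ set(b.index))}"
        )
    b = b.loc[a.index]
    table = pd.DataFrame(
        {
            "cell_type": a.index,
            "hot_median": a["median"].to_numpy(),
            "hot_iqr": a["iqr"].to_numpy(),
            "nonhot_cgi_median": b["median"].to_numpy(),
            "nonhot_cgi_iqr": b["iqr"].to_numpy(),
        }
    ).reset_index(drop=True)
    denom = float(np.median(table["hot_iqr"]))
    numer = float(np.median(table["nonhot_cgi_iqr"]))
    ratio = float("inf") if denom == 0 else numer / denom
    return table, ratio


def nonhot_cgis(cgi: pd.DataFrame, hot_regions: pd.DataFrame) -> pd.DataFrame:
    """CpG islands with zero overlap with any HOT region (1 bp excludes)."""
    keep = ~overlaps_any(cgi, hot_regions)
    return cgi[keep].reset_index(drop=True)
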