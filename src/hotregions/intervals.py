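"""Half-open genomic interval arithmetic.

All coordinates are 0-based half-open (BED convention). The two routines
here — overlap counting and any-overlap flags — are the only interval
primitives the package needs; both are O((n+m) log n) via sorted-array
bisection and are pinned bit-exactly against brute force in the tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def count_overlaps(intervals: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Count how many of `intervals` intersect each row of `regions`.

    Two half-open intervals [a, b) and [c, d) intersect iff a < d and c < b
    (>= 1 bp of shared span). Returns one count per region row, in region
    row order.

    Both frames need ``chrom``, ``start``, ``end`` columns.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        starts = np.sort(sub["start"].to_numpy(dtype=np.int64))
        ends = np.sort(sub["end"].to_numpy(dtype=np.int64))
        by_chrom[chrom] = (starts, ends)
    rchrom = regions["chrom"].to_numpy()
    rstart = regions["start"].to_numpy(dtype=np.int64)
    rend = regions["end"].to_numpy(dtype=np.int64)
    for chrom in np.unique(rchrom):
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        n = starts.size
        mask = rchrom == chrom
        # non-overlapping = intervals entirely right (start >= region end)
        # plus entirely left (end <= region start); the two sets are disjoint
        right = n - np.searchsorted(starts, rend[mask], side="left")
        left = np.searchsorted(ends, rstart[mask], side="right")
        counts[mask] = n - right - left
    return counts


def overlaps_any(regions: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per region row: does it intersect >= 1 interval of `targets`?"""
    return count_overlaps(targets, regions) > 0
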