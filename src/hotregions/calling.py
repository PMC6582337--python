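"""Calling HOT regions from peak-summit density.

The caller pools peak summits across many ChIP-seq experiments, computes
their density in sliding windows (default 500 bp, 50 bp step) per
chromosome, keeps local maxima of the density with non-maximum suppression
over a species-dependent span (2000 bp human, 1000 bp other species), ranks
the retained windows by summit count ("TF occupancy"), and labels windows
above the 99th occupancy percentile HOT. Windows between the 75th percentile
and the HOT threshold are MILD; the rest are COLD and serve as controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.stats import rankdata


@dataclass
class PeakRecord:
    """One narrowPeak line. Coordinates 0-based half-open.

    ``summit_offset`` is the summit position relative to ``start``, or -1
    when the input did not report one.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start ({self.start}) >= end ({self.end})")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.end - self.start})"
            )


@dataclass
class SummitSet:
    """Peak summits of one experiment: (chrom, 0-based position) pairs."""

    experiment_id: str
    summits: list[tuple[str, int]]


@dataclass
class DensityTrack:
    """Summit counts in sliding windows along one chromosome."""

    chrom: str
    window_size: int
    step: int
    window_starts: np.ndarray
    counts: np.ndarray


@dataclass
class CallerConfig:
    """Parameters of the HOT-region caller.

    window_size: sliding-window width in bp.
    step: window step in bp (10x oversampling of the window by default).
    suppression_span: total width in bp of the non-maximum-suppression
        neighbourhood (2000 for human, 1000 for other species); a retained
        maximum is the unique maximum within +/- span/2 of its window start.
    hot_percentile: occupancy percentile above which a region is HOT
        (99; 99.5 was used for human when training discriminative models).
    mild_percentile: lower edge of the MILD control bin.
    control_ceiling_percentile: ceiling for sampling model control regions.
    """

    window_size: int = 500
    step: int = 50
    suppression_span: int = 2000
    hot_percentile: float = 99.0
    mild_percentile: float = 75.0
    control_ceiling_percentile: float = 85.0

    def __post_init__(self) -> None:
        if self.suppression_span < self.window_size:
            raise ValueError("suppression_span must be >= window_size")
        if not 0 < self.hot_percentile < 100:
            raise ValueError("hot_percentile must be in (0, 100)")
        if self.step <= 0 or self.window_size <= 0:
            raise ValueError("window_size and step must be positive")


def peak_summit(record: PeakRecord) -> int:
    """Summit position of a peak; interval midpoint when no offset reported."""
    if record.summit_offset >= 0:
        return record.start + record.summit_offset
    return (record.start + record.end) // 2


def summits_from_peaks(records: Iterable[PeakRecord], experiment_id: str) -> SummitSet:
    return SummitSet(
        experiment_id=experiment_id,
        summits=[(r.chrom, peak_summit(r)) for r in records],
    )


def summit_density(
    summit_sets: Sequence[SummitSet],
    chrom_sizes: Mapping[str, int],
    config: CallerConfig | None = None,
) -> dict[str, DensityTrack]:
    """Pooled summit density in sliding windows, one track per chromosome.

    Window starts run 0, step, 2*step, ... while start < chromosome length;
    the last windows are truncated at the chromosome end. counts[i] is the
    number of summits (pooled over all experiments) in
    [window_starts[i], window_starts[i] + window_size).

    Raises ValueError naming the experiment if a summit lies on an unknown
    chromosome or beyond its length.
    """
    config = config or CallerConfig()
    w, s = config.window_size, config.step
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for ss in summit_sets:
        for chrom, pos in ss.summits:
            if chrom not in chrom_sizes:
                raise ValueError(
                    f"experiment {ss.experiment_id!r}: unknown chromosome {chrom!r}"
                )
            if not 0 <= pos < chrom_sizes[chrom]:
                raise ValueError(
                    f"experiment {ss.experiment_id!r}: summit {chrom}:{pos} outside "
                    f"chromosome of length {chrom_sizes[chrom]}"
                )
            per_chrom[chrom].append(pos)
    tracks: dict[str, DensityTrack] = {}
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, s, dtype=np.int64)
        pos = np.sort(np.asarray(per_chrom[chrom], dtype=np.int64))
        # count of summits in [start, start+w): searchsorted on sorted positions
        hi = np.searchsorted(pos, starts + w, side="left")
        lo = np.searchsorted(pos, starts, side="left")
        tracks[chrom] = DensityTrack(
            chrom=chrom,
            window_size=w,
            step=s,
            window_starts=starts,
            counts=(hi - lo).astype(np.int64),
        )
    return tracks


def local_maxima(
    track: DensityTrack, suppression_span: int
) -> list[tuple[int, int]]:
    """Non-maximum suppression of the density track.

    Returns (window_start, count) pairs such that each retained window's
    count is >= the count of every window whose start lies within
    +/- suppression_span/2 of its own, no two retained windows lie within
    that distance of each other, and zero-count windows are never returned.
    Ties inside one span keep the leftmost window. Candidates are first
    restricted to windows equal to their neighbourhood maximum (so a weak
    window in the gap between two suppressors can never survive), then
    selected greedily by descending count (ascending position on ties),
    which makes the result idempotent: suppressing the retained set again
    changes nothing.
    """
    if suppression_span < track.window_size:
        raise ValueError("suppression_span must be >= window_size")
    counts = track.counts
    starts = track.window_starts
    half = suppression_span / 2.0
    step = track.step
    reach = int(np.floor(half / step))  # windows within half-span, in index units
    neighbourhood_max = maximum_filter1d(
        counts, size=2 * reach + 1, mode="constant", cval=0
    )
    nz = np.flatnonzero((counts > 0) & (counts == neighbourhood_max))
    if nz.size == 0:
        return []
    # process by (-count, start): higher counts first, leftmost wins ties
    order = nz[np.lexsort((starts[nz], -counts[nz]))]
    suppressed = np.zeros(counts.size, dtype=bool)
    kept: list[tuple[int, int]] = []
    for i in order:
        if suppressed[i]:
            continue
        kept.append((int(starts[i]), int(counts[i])))
        lo = max(0, i - reach)
        hi = min(counts.size, i + reach + 1)
        suppressed[lo:hi] = True
    kept.sort()
    return kept


def call_regions(
    maxima_by_chrom: Mapping[str, Sequence[tuple[int, int]]],
    config: CallerConfig | None = None,
) -> pd.DataFrame:
    """Rank retained maxima genome-wide and label HOT / MILD / COLD.

    Occupancy percentile is the mean-rank percentile over all retained
    regions, scaled to [0, 100] (rank/n * 100 with mean rank for ties).
    A region is HOT iff its percentile is strictly above
    ``config.hot_percentile``, MILD iff above ``config.mild_percentile``
    but not HOT, COLD otherwise.

    Returns a DataFrame (chrom, start, end, occupancy, percentile, label)
    sorted by (chrom, start).
    """
    config = config or CallerConfig()
    rows = []
    for chrom in sorted(maxima_by_chrom):
        for start, count in maxima_by_chrom[chrom]:
            rows.append((chrom, start, start + config.window_size, count))
    if not rows:
        raise ValueError("no retained maxima: cannot call regions")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "occupancy"])
    ranks = rankdata(df["occupancy"].to_numpy(), method="average")
    df["percentile"] = ranks / len(df) * 100.0
    labels = np.where(
        df["percentile"] > config.hot_percentile,
        "HOT",
        np.where(df["percentile"] > config.mild_percentile, "MILD", "COLD"),
    )
    df["label"] = labels
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def bin_by_percentile(
    regions: pd.DataFrame, edges: Sequence[float]
) -> dict[str, pd.DataFrame]:
    """Partition regions into occupancy-percentile bins.

    ``edges`` are increasing interior percentile cut points in [0, 100];
    bins are half-open [lo, hi) except the last, which is closed at 100.
    Keys are "lo-hi" strings. The bins partition the input.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    if edges and (edges[0] < 0 or edges[-1] > 100):
        raise ValueError("bin edges must lie in [0, 100]")
    bounds = [0.0] + [float(e) for e in edges] + [100.0]
    out: dict[str, pd.DataFrame] = {}
    pct = regions["percentile"].to_numpy()
    for lo, hi in zip(bounds, bounds[1:]):
        if hi < 100.0:
            mask = (pct >= lo) & (pct < hi)
        else:
            mask = (pct >= lo) & (pct <= hi)
        out[f"{lo:g}-{hi:g}"] = regions[mask].reset_index(drop=True)
    return out


def call_hot_regions(
    summit_sets: Sequence[SummitSet],
    chrom_sizes: Mapping[str, int],
    config: CallerConfig | None = None,
) -> pd.DataFrame:
    """End-to-end caller: density -> local maxima -> ranked, labelled regions."""
    config = config or CallerConfig()
    tracks = summit_density(summit_sets, chrom_sizes, config)
    maxima = {
        chrom: local_maxima(track, config.suppression_span)
        for chrom, track in tracks.items()
    }
    return call_regions(maxima, config)
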