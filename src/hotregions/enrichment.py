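"""IP-vs-control signal enrichment over occupancy-binned regions.

Region-level enrichment is log2 of the CPM-normalized IP read count over the
CPM-normalized control count (a pseudocount keeps zero-control regions
finite); per-bp enrichment tracks feed 50-bin metaregion profile matrices
winsorized at their own 0.5th/99th percentiles, with windows stratified by
occupancy percentile (3000 per stratum by default). This is the arithmetic
used to show knockout ChIP-seq, DRIP-seq (R-loop) and G4 ChIP-seq signal
concentrating on HOT regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .intervals import count_overlaps


@dataclass
class ReadSet:
    """Aligned-read intervals of one library.

    reads: DataFrame(chrom, start, end, strand); library_size defaults to
    the number of reads and is the CPM denominator.
    """

    library_id: str
    reads: pd.DataFrame
    library_size: int | None = None

    def __post_init__(self) -> None:
        if self.library_size is None:
            self.library_size = len(self.reads)
        if (self.reads["start"] >= self.reads["end"]).any():
            raise ValueError(f"library {self.library_id!r}: read with start >= end")


@dataclass
class EnrichmentResult:
    """Per-region CPM pair and log2 ratio, plus the normalization metadata."""

    table: pd.DataFrame  # columns: ip_cpm, control_cpm, log2_ratio
    pseudocount: float
    control_kind: str = "input"


def region_log2_enrichment(
    ip: ReadSet,
    control: ReadSet,
    regions: pd.DataFrame,
    epsilon: float | None = None,
    control_kind: str = "input",
) -> EnrichmentResult:
    """log2(ip_cpm + eps) - log2(control_cpm + eps) per region.

    A read overlaps a region on any (>= 1 bp) intersection. CPM =
    overlap count / library size * 1e6. ``epsilon`` defaults to the mean of
    one read's CPM in each library, so zero-control regions stay finite and
    the ratio is monotone in the IP count. ``control_kind`` records what
    served as control (input, IgG, or an RNaseH-treated IP when no input
    exists).
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    if not ip.library_size or not control.library_size:
        raise ValueError("library sizes must be positive")
    ip_n = count_overlaps(ip.reads, regions)
    ct_n = count_overlaps(control.reads, regions)
    ip_cpm = ip_n / ip.library_size * 1e6
    ct_cpm = ct_n / control.library_size * 1e6
    if epsilon is None:
        epsilon = (1e6 / ip.library_size + 1e6 / control.library_size) / 2.0
    table = pd.DataFrame(
        {
            "ip_cpm": ip_cpm,
            "control_cpm": ct_cpm,
            "log2_ratio": np.log2((ip_cpm + epsilon) / (ct_cpm + epsilon)),
        },
        index=regions.index,
    )
    return EnrichmentResult(table=table, pseudocount=epsilon, control_kind=control_kind)


def per_bp_log2_track(
    ip_coverage: np.ndarray, control_coverage: np.ndarray, epsilon: float = 1.0
) -> np.ndarray:
    """Elementwise log2((ip + eps) / (control + eps)) on CPM-scaled coverages."""
    ip_coverage = np.asarray(ip_coverage, dtype=float)
    control_coverage = np.asarray(control_coverage, dtype=float)
    if ip_coverage.shape != control_coverage.shape:
        raise ValueError(
            f"coverage grids differ: {ip_coverage.shape} vs {control_coverage.shape}"
        )
    return np.log2((ip_coverage + epsilon) / (control_coverage + epsilon))


def coverage_track(
    reads: ReadSet, chrom_sizes: Mapping[str, int], cpm: bool = True
) -> dict[str, np.ndarray]:
    """Per-bp read coverage per chromosome (CPM-scaled by default).

    Difference-array accumulation: O(reads + genome).
    """
    scale = 1e6 / reads.library_size if cpm else 1.0
    tracks = {c: np.zeros(l + 1) for c, l in chrom_sizes.items()}
    for chrom, sub in reads.reads.groupby("chrom", sort=False):
        if chrom not in tracks:
            raise ValueError(f"reads on unknown chromosome {chrom!r}")
        L = chrom_sizes[chrom]
        s = np.clip(sub["start"].to_numpy(dtype=np.int64), 0, L)
        e = np.clip(sub["end"].to_numpy(dtype=np.int64), 0, L)
        np.add.at(tracks[chrom], s, scale)
        np.add.at(tracks[chrom], e, -scale)
    return {c: np.cumsum(t[:-1]) for c, t in tracks.items()}


def stratified_window_sample(
    regions: pd.DataFrame,
    strata: Sequence[tuple[float, float, int]] = (
        (0.0, 75.0, 3000),
        (75.0, 99.0, 3000),
        (99.0, 100.0, 3000),
    ),
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample regions per occupancy-percentile stratum for profile heatmaps.

    Each stratum (lo, hi, n) draws n regions uniformly without replacement
    from percentile in (lo, hi] (lo >= its value for the first stratum);
    a stratum smaller than n contributes everything and its shortfall is
    recorded. Returns (sampled regions with a ``stratum`` column, shortfalls).
    """
    rng = np.random.default_rng(seed)
    pct = regions["percentile"].to_numpy()
    parts = []
    shortfall: dict[str, int] = {}
    for lo, hi, n in strata:
        mask = (pct > lo) & (pct <= hi) if lo > 0 else (pct >= lo) & (pct <= hi)
        pool = regions[mask]
        key = f"{lo:g}-{hi:g}"
        if len(pool) <= n:
            take = pool
            if len(pool) < n:
                shortfall[key] = n - len(pool)
        else:
            idx = np.sort(rng.choice(len(pool), size=n, replace=False))
            take = pool.iloc[idx]
        take = take.copy()
        take["stratum"] = key
        parts.append(take)
    return pd.concat(parts).reset_index(drop=True), shortfall


@dataclass
class ProfileMatrix:
    """50-bin metaregion matrix of a per-bp enrichment track."""

    values: np.ndarray  # windows x nbins, winsorized
    raw: np.ndarray  # pre-winsorization
    windows: pd.DataFrame  # rows aligned with the matrix, descending occupancy
    winsor_bounds: tuple[float, float]


def _bin_means(values: np.ndarray, nbins: int) -> np.ndarray:
    """Mean of equal-width bins; pads symmetrically with NaN when the width
    is not divisible by nbins (NaN-aware means)."""
    L = values.size
    per = int(np.ceil(L / nbins))
    padded = np.full(per * nbins, np.nan)
    off = (per * nbins - L) // 2
    padded[off : off + L] = values
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        return np.nanmean(padded.reshape(nbins, per), axis=1)


def profile_matrix(
    track: Mapping[str, np.ndarray],
    windows: pd.DataFrame,
    nbins: int = 50,
    winsor: tuple[float, float] = (0.5, 99.0),
) -> ProfileMatrix:
    """Bin a per-bp track into nbins per window and winsorize the matrix.

    Bin value = mean of the per-bp values in the bin (windows padded
    symmetrically when their width is not a multiple of nbins; parts of a
    window off the chromosome end are missing, i.e. NaN, bins). Rows are
    ordered by descending occupancy. After binning, the whole matrix is
    clipped at its own ``winsor`` percentiles (default 0.5 % and 99 %).
    """
    if "occupancy" in windows.columns:
        windows = windows.sort_values(
            "occupancy", ascending=False, kind="mergesort"
        ).reset_index(drop=True)
    rows = []
    for chrom, start, end in zip(windows["chrom"], windows["start"], windows["end"]):
        if chrom not in track:
            raise ValueError(f"window on chromosome {chrom!r} absent from track")
        arr = track[chrom]
        width = end - start
        vals = np.full(width, np.nan)
        lo = max(start, 0)
        hi = min(end, arr.size)
        if hi > lo:
            vals[lo - start : hi - start] = arr[lo:hi]
        rows.append(_bin_means(vals, nbins))
    raw = np.vstack(rows) if rows else np.empty((0, nbins))
    finite = raw[np.isfinite(raw)]
    if finite.size:
        lo_b, hi_b = np.percentile(finite, list(winsor))
        values = np.clip(raw, lo_b, hi_b)
    else:
        lo_b = hi_b = float("nan")
        values = raw.copy()
    return ProfileMatrix(
        values=values, raw=raw, windows=windows, winsor_bounds=(float(lo_b), float(hi_b))
    )


def extend_reads(
    reads: ReadSet,
    target_length: int = 200,
    chrom_sizes: Mapping[str, int] | None = None,
) -> ReadSet:
    """Extend reads to a fixed length in a stranded fashion.

    + reads become [start, start+L); - reads become [end-L, end); clipped at
    chromosome bounds when sizes are given. library_size is unchanged, so
    per-million normalization is unaffected. Raises on unstranded reads.
    """
    df = reads.reads
    strand = df["strand"].to_numpy()
    if (~np.isin(strand, ["+", "-"])).any():
        bad = df[~np.isin(strand, ["+", "-"])].iloc[0]
        raise ValueError(
            f"unstranded read {bad['chrom']}:{bad['start']}-{bad['end']} "
            f"(strand {bad['strand']!r}) cannot be extended"
        )
    start = df["start"].to_numpy(dtype=np.int64)
    end = df["end"].to_numpy(dtype=np.int64)
    plus = strand == "+"
    new_start = np.where(plus, start, end - target_length)
    new_end = np.where(plus, start + target_length, end)
    new_start = np.maximum(new_start, 0)
    if chrom_sizes is not None:
        limit = df["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
        new_end = np.minimum(new_end, limit)
    out = df.copy()
    out["start"] = new_start
    out["end"] = new_end
    return ReadSet(
        library_id=reads.library_id, reads=out, library_size=reads.library_size
    )


def score_correlation(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, bool]:
    """Spearman rank correlation (mid-rank ties) between paired region scores.

    Returns (rho, defined). A constant vector makes the correlation
    undefined: rho is NaN and ``defined`` is False.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return float("nan"), False
    rho = spearmanr(a, b).statistic
    return float(rho), True
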