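"""Readers and writers for the plain-text genomics formats the pipeline uses.

narrowPeak (ENCODE 10-column BED6+4), plain BED6, two-column chrom.sizes,
BED6 read files and bedGraph-like per-CpG methylation tables. Everything is
0-based half-open on disk and in memory.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .calling import PeakRecord


class ParseError(ValueError):
    """Raised for a malformed line; message names the file and line number."""


def read_narrowpeak(path: str | os.PathLike) -> list[PeakRecord]:
    """Parse a narrowPeak (10-column) or BED6 file into PeakRecords.

    BED6 lines get ``summit_offset=-1`` and ``signal_value=0``. Input order
    is preserved; coordinates stay 0-based half-open. Malformed lines
    (wrong column count, start >= end, out-of-range summit offset) raise
    :class:`ParseError` naming the line number.
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 10):
                raise ParseError(
                    f"{path}:{lineno}: expected 6 or 10 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                name = fields[3]
                score = int(float(fields[4]))
                strand = fields[5]
                if len(fields) == 10:
                    signal_value = float(fields[6])
                    p_value = float(fields[7])
                    q_value = float(fields[8])
                    summit_offset = int(fields[9])
                else:
                    signal_value, p_value, q_value, summit_offset = 0.0, -1.0, -1.0, -1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start ({start}) >= end ({end})")
            if summit_offset != -1 and not 0 <= summit_offset < end - start:
                raise ParseError(
                    f"{path}:{lineno}: summit offset {summit_offset} outside "
                    f"[0, {end - start})"
                )
            records.append(
                PeakRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=name,
                    score=score,
                    strand=strand,
                    signal_value=signal_value,
                    p_value=p_value,
                    q_value=q_value,
                    summit_offset=summit_offset,
                )
            )
    return records


def write_narrowpeak(records: Iterable[PeakRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\t"
                f"{r.signal_value:g}\t{r.p_value:g}\t{r.q_value:g}\t{r.summit_offset}\n"
            )


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Two-column <chrom>\\t<length> file -> {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED3/BED6(+extra) -> DataFrame with at least chrom/start/end.

    Strand column is kept when present (column 6). Extra columns are ignored.
    """
    rows = []
    has_strand = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
            row = {"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2])}
            if int(parts[1]) >= int(parts[2]):
                raise ParseError(f"{path}:{lineno}: start >= end")
            if len(parts) >= 6:
                row["strand"] = parts[5]
                has_strand = True
            rows.append(row)
    cols = ["chrom", "start", "end"] + (["strand"] if has_strand else [])
    return pd.DataFrame(rows, columns=cols)


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write chrom/start/end (+name/score/strand and extras when present)."""
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"] if c in df]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def write_regions_bed(regions: pd.DataFrame, path: str | os.PathLike) -> None:
    """Called regions as BED6+2: name=label, score=occupancy, +occupancy,percentile."""
    out = pd.DataFrame(
        {
            "chrom": regions["chrom"],
            "start": regions["start"],
            "end": regions["end"],
            "name": regions["label"],
            "score": regions["occupancy"],
            "strand": ".",
            "occupancy": regions["occupancy"],
            "percentile": regions["percentile"].map(lambda p: f"{p:.6g}"),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path: str | os.PathLike) -> pd.DataFrame:
    """BED6 aligned-read intervals -> DataFrame(chrom, start, end, strand)."""
    df = read_bed(path)
    if "strand" not in df.columns:
        df["strand"] = "."
    return df[["chrom", "start", "end", "strand"]]


def read_methylation_table(path: str | os.PathLike) -> pd.DataFrame:
    """bedGraph-like per-CpG table: chrom, start, (end,) fraction.

    Accepts 3 columns (chrom, pos, fraction) or 4 (chrom, start, end,
    fraction; position taken as start). Fractions must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        df.columns = ["chrom", "pos", "fraction"]
    elif df.shape[1] >= 4:
        df = df.iloc[:, :4]
        df.columns = ["chrom", "pos", "end", "fraction"]
        df = df[["chrom", "pos", "fraction"]]
    else:
        raise ParseError(f"{path}: expected >= 3 columns")
    frac = df["fraction"].to_numpy(dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ParseError(f"{path}: methylation fractions outside [0, 1]")
    return df
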