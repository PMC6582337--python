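"""Sequence featurization of genomic regions.

Each region is represented by 339 features computed on a fixed-width window
(default 2000 bp) centred on the region midpoint: all 2-, 3- and 4-mer
frequencies (16 + 64 + 256), CpG frequency (the (C+G)/window-length GC
content), the CpG observed/expected ratio N(CG)*L/(N(C)*N(G)) and GC skew
(G-C)/(G+C). k-mer windows containing N are skipped; N bases never enter
mono- or di-nucleotide counts. Features are computed on the reference (+)
strand only.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from sklearn.base import BaseEstimator, TransformerMixin

_BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

KMER_KS = (2, 3, 4)


def _kmer_names(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def feature_names() -> list[str]:
    """Deterministic order of the 339 feature names."""
    names: list[str] = []
    for k in KMER_KS:
        names.extend(f"kmer.{s}" for s in _kmer_names(k))
    names.extend(["cpg_freq", "cpg_oe", "gc_skew"])
    return names


FEATURE_NAMES = feature_names()


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Frequencies of all 4^k k-mers over the N-free length-k windows.

    Counts each k-mer over every window of length k that contains no N,
    divided by the number of such windows; the all-zero vector when no
    valid window exists.
    """
    if k not in KMER_KS:
        raise ValueError(f"k must be one of {KMER_KS}")
    n_kmers = 4**k
    if len(sequence) < k:
        return np.zeros(n_kmers)
    codes = _encode(sequence)
    valid = codes >= 0
    m = len(sequence) - k + 1
    vals = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        vals = vals * 4 + np.where(valid[j : j + m], codes[j : j + m], 0)
        ok &= valid[j : j + m]
    total = int(ok.sum())
    if total == 0:
        return np.zeros(n_kmers)
    counts = np.bincount(vals[ok], minlength=n_kmers)
    return counts / total


def cpg_frequency(sequence: str, length: int | None = None) -> float:
    """(count(C) + count(G)) / L — the GC-content-style 'CpG frequency'.

    L defaults to the actual sequence length; the feature-matrix builder
    passes the nominal window width so edge-clipped windows keep a common
    denominator.
    """
    if not sequence:
        raise ValueError("empty sequence")
    L = length if length is not None else len(sequence)
    codes = _encode(sequence)
    return float(((codes == 1) | (codes == 2)).sum() / L)


def gc_skew(sequence: str) -> float:
    """(G - C) / (G + C); 0 when the sequence has no G or C."""
    codes = _encode(sequence)
    g = int((codes == 2).sum())
    c = int((codes == 1).sum())
    if g + c == 0:
        return 0.0
    return (g - c) / (g + c)


def cpg_oe(sequence: str) -> float:
    """Observed/expected CpG ratio, N(CG) * L / (N(C) * N(G)).

    L is the actual sequence length. Returns 0 when the sequence contains
    no C or no G. Values >= ~0.6 typify CpG islands; bulk vertebrate genome
    sits far lower because methylated CpGs deaminate away.
    """
    if not sequence:
        raise ValueError("empty sequence")
    codes = _encode(sequence)
    c = int((codes == 1).sum())
    g = int((codes == 2).sum())
    if c == 0 or g == 0:
        return 0.0
    cg = int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())
    return cg * len(sequence) / (c * g)


def featurize_sequence(sequence: str, nominal_length: int | None = None) -> np.ndarray:
    """The full 339-feature vector for one sequence."""
    parts = [kmer_frequencies(sequence, k) for k in KMER_KS]
    parts.append(
        np.array(
            [
                cpg_frequency(sequence, nominal_length),
                cpg_oe(sequence),
                gc_skew(sequence),
            ]
        )
    )
    return np.concatenate(parts)


class SequenceFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping DNA sequences to the 339 named sequence features.

    Stateless (fit is a no-op), so it slots in front of a scaler or
    classifier in an sklearn pipeline.

    Parameters
    ----------
    nominal_length : int or None
        Denominator used for cpg_freq; None means each sequence's own length.
    """

    def __init__(self, nominal_length: int | None = None):
        self.nominal_length = nominal_length

    def fit(self, X: Sequence[str], y=None) -> "SequenceFeaturizer":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        return np.vstack([featurize_sequence(s, self.nominal_length) for s in X])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)


def region_windows(
    regions: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window: int = 2000,
) -> pd.DataFrame:
    """Fixed-width analysis windows centred on region midpoints, edge-clipped."""
    mid = (regions["start"].to_numpy() + regions["end"].to_numpy()) // 2
    start = mid - window // 2
    end = start + window
    lengths = regions["chrom"].map(chrom_sizes)
    if lengths.isna().any():
        bad = regions.loc[lengths.isna()].iloc[0]
        raise ValueError(
            f"region {bad['chrom']}:{bad['start']}-{bad['end']}: chromosome "
            f"{bad['chrom']!r} not in genome"
        )
    out = regions[["chrom"]].copy()
    out["start"] = np.maximum(start, 0)
    out["end"] = np.minimum(end, lengths.to_numpy(dtype=np.int64))
    return out


def build_feature_matrix(
    regions: pd.DataFrame,
    genome: str | Mapping[str, str],
    window: int = 2000,
) -> pd.DataFrame:
    """Feature matrix (rows = regions, 339 named columns) from a genome.

    ``genome`` is a FASTA path (indexed access through pyfaidx) or a
    {chrom: sequence} mapping. Windows of width ``window`` are centred on
    region midpoints and clipped at chromosome ends; cpg_freq keeps the
    nominal width as denominator while CpG O/E and GC skew use the actual
    (clipped) length. Raises ValueError naming the region if its chromosome
    is missing.
    """
    if isinstance(genome, (str, bytes)):
        fa = Fasta(str(genome))
        seqs = {name: None for name in fa.keys()}

        def get(chrom: str, s: int, e: int) -> str:
            return str(fa[chrom][s:e])

        known = set(fa.keys())
        sizes = {name: len(fa[name]) for name in fa.keys()}
    else:
        def get(chrom: str, s: int, e: int) -> str:
            return genome[chrom][s:e]

        known = set(genome)
        sizes = {c: len(s) for c, s in genome.items()}

    missing = set(regions["chrom"]) - known
    if missing:
        bad = regions[regions["chrom"].isin(missing)].iloc[0]
        raise ValueError(
            f"region {bad['chrom']}:{bad['start']}-{bad['end']}: chromosome "
            f"{bad['chrom']!r} not in genome"
        )
    win = region_windows(regions, sizes, window)
    rows = np.vstack(
        [
            featurize_sequence(get(c, s, e), nominal_length=window)
            for c, s, e in zip(win["chrom"], win["start"], win["end"])
        ]
    )
    return pd.DataFrame(rows, columns=FEATURE_NAMES, index=regions.index)


def standardize_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-standardize (population variance) a feature matrix.

    Zero-variance columns are left at 0 and returned as the second element.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    std = values.std(axis=0)  # ddof=0
    zero = std == 0
    scaled = np.where(zero, 0.0, (values - mean) / np.where(zero, 1.0, std))
    flagged = [c for c, z in zip(matrix.columns, zero) if z]
    return pd.DataFrame(scaled, columns=matrix.columns, index=matrix.index), flagged
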