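"""Seeded synthetic genomes, peak sets, reads and methylation tables.

Every generator emits its ground truth alongside output in the same formats
the analysis reads (FASTA, narrowPeak, BED6, bedGraph-like tables), so no
code path is synthetic-only and every pipeline stage has a parameter-recovery
test that runs without downloads.

What is emulated
----------------
* A CpG-depleted background genome (GC ~0.41, CpG observed/expected ~0.25,
  the bulk-vertebrate signature of methylation-driven CpG decay) with
  planted CpG-island-like loci: GC-rich, no CpG depletion, O/E ~0.8-1.
* Many peak experiments whose summits pile up on the planted HOT loci
  (probability p_hot per experiment, jittered summits) over a Poisson
  background of unrelated peaks. Additional CGI-like loci get a small
  summit probability so the genome also contains CpG islands that are NOT
  HOT — as real genomes do — which the control-sampling and methylation
  comparisons require.
* IP/control read pairs with an exact planted log2 CPM fold change on the
  HOT loci (control uniform; IP uniform plus a multinomial excess sized so
  the expected CPM ratio equals 2**log2_fc).
* Per-CpG methylation fractions per cell type: region means drawn from a
  Beta distribution numerically matched to a planted (median, IQR), with
  small per-CpG noise — stable hypomethylation at HOT loci, variable
  methylation at non-HOT CpG islands.

Not emulated: sequencing error, mappability, GC bias, fragment-length
distributions, or inter-experiment antibody quality differences.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import beta as beta_dist

from . import io as hio
from .calling import PeakRecord
from .enrichment import ReadSet
from .features import cpg_oe, kmer_frequencies, KMER_KS

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic bundle."""

    loci: pd.DataFrame  # chrom, start, end, kind in {hot, cgi}
    p_hot: float
    p_cgi: float
    log2_fc: float
    methylation: dict[str, tuple[float, float]]  # set name -> (median, IQR)
    enriched_kmers: list[str]
    seed: int

    @property
    def hot_loci(self) -> pd.DataFrame:
        return self.loci[self.loci["kind"] == "hot"].reset_index(drop=True)

    @property
    def cgi_loci(self) -> pd.DataFrame:
        return self.loci[self.loci["kind"] == "cgi"].reset_index(drop=True)

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "loci": self.loci.to_dict(orient="list"),
            "p_hot": self.p_hot,
            "p_cgi": self.p_cgi,
            "log2_fc": self.log2_fc,
            "methylation": {k: list(v) for k, v in self.methylation.items()},
            "enriched_kmers": self.enriched_kmers,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            loci=pd.DataFrame(payload["loci"]),
            p_hot=payload["p_hot"],
            p_cgi=payload["p_cgi"],
            log2_fc=payload["log2_fc"],
            methylation={k: tuple(v) for k, v in payload["methylation"].items()},
            enriched_kmers=payload["enriched_kmers"],
            seed=payload["seed"],
        )


def _background_sequence(
    rng: np.random.Generator, length: int, gc: float, cpg_keep: float
) -> np.ndarray:
    """i.i.d. bases at the given GC, then CpG depletion: each CG dinucleotide
    keeps its G with probability cpg_keep, otherwise the G becomes A or T."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
    drop = cg[rng.random(cg.size) >= cpg_keep]
    codes[drop + 1] = rng.choice([0, 3], size=drop.size)
    return codes


def _locus_sequence(
    rng: np.random.Generator, length: int, gc: float, cpg_keep: float = 1.0
) -> np.ndarray:
    """CpG-island-like locus: elevated GC with little or no CpG depletion."""
    return _background_sequence(rng, length, gc, cpg_keep)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def make_genome(
    n_chroms: int = 5,
    chrom_length: int = 1_000_000,
    background_gc: float = 0.41,
    cpg_keep: float = 0.25,
    n_hot_loci: int = 40,
    n_cgi_loci: int = 150,
    locus_length: int = 1500,
    hot_gc: float = 0.60,
    hot_cpg_keep: float = 1.0,
    cgi_gc: float = 0.50,
    cgi_cpg_keep: float = 0.55,
    edge_margin: int = 10_000,
    seed: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Synthetic genome with planted CpG-rich loci on a CpG-depleted background.

    Two locus classes are planted: "hot" loci (the strongest CpG islands:
    high GC, no CpG depletion — mirroring that real HOT regions are the most
    CpG-dense promoter islands) and ordinary "cgi" loci (moderately GC-rich,
    partly CpG-depleted). Returns ({chrom: sequence}, loci DataFrame with
    kind in {hot, cgi}). Loci are non-overlapping, kept away from chromosome
    ends, and deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_loci = n_hot_loci + n_cgi_loci
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    # lay loci on a jittered grid so they never overlap
    slots_per_chrom = int(np.ceil(n_loci / n_chroms))
    usable = chrom_length - 2 * edge_margin
    pitch = usable // slots_per_chrom
    if pitch < 2 * locus_length:
        raise ValueError("too many loci for the genome size: loci would overlap")
    slots = []
    for c in chroms:
        for j in range(slots_per_chrom):
            base = edge_margin + j * pitch
            start = base + int(rng.integers(0, pitch - locus_length))
            slots.append((c, start, start + locus_length))
    order = rng.permutation(len(slots))[:n_loci]
    kinds = ["hot"] * n_hot_loci + ["cgi"] * n_cgi_loci
    loci = pd.DataFrame(
        [
            {"chrom": slots[i][0], "start": slots[i][1], "end": slots[i][2], "kind": k}
            for i, k in zip(order, kinds)
        ]
    ).sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    genome: dict[str, str] = {}
    for c in chroms:
        codes = _background_sequence(rng, chrom_length, background_gc, cpg_keep)
        for _, row in loci[loci["chrom"] == c].iterrows():
            gc, keep = (hot_gc, hot_cpg_keep) if row["kind"] == "hot" else (
                cgi_gc, cgi_cpg_keep
            )
            codes[row["start"] : row["end"]] = _locus_sequence(
                rng, row["end"] - row["start"], gc, keep
            )
        genome[c] = _codes_to_str(codes)
    return genome, loci


def enriched_kmers(
    background_gc: float = 0.41,
    cpg_keep: float = 0.25,
    hot_gc: float = 0.60,
    hot_cpg_keep: float = 1.0,
    n_samples: int = 100,
    length: int = 2000,
    fold: float = 1.5,
    seed: int = 0,
) -> list[str]:
    """k-mers the hot-locus model enriches >= `fold` over the background model.

    Estimated empirically from the generators themselves, so the truth list
    always matches whatever sequence models are configured.
    """
    rng = np.random.default_rng(seed)
    bg = np.zeros(sum(4**k for k in KMER_KS))
    lc = np.zeros_like(bg)
    for _ in range(n_samples):
        b = _codes_to_str(_background_sequence(rng, length, background_gc, cpg_keep))
        l = _codes_to_str(_locus_sequence(rng, length, hot_gc, hot_cpg_keep))
        bg += np.concatenate([kmer_frequencies(b, k) for k in KMER_KS])
        lc += np.concatenate([kmer_frequencies(l, k) for k in KMER_KS])
    bg /= n_samples
    lc /= n_samples
    import itertools

    names = []
    for k in KMER_KS:
        names.extend("".join(p) for p in itertools.product("ACGT", repeat=k))
    out = [
        name
        for name, b, l in zip(names, bg, lc)
        if l > 1e-4 and l >= fold * max(b, 1e-12)
    ]
    return out


def make_peak_experiments(
    truth: SyntheticTruth,
    chrom_sizes: Mapping[str, int],
    n_experiments: int = 100,
    jitter_sd: float = 50.0,
    background_per_mb: float = 20.0,
    peak_halfwidth: int = 125,
    seed: int | None = None,
) -> list[list[PeakRecord]]:
    """Pseudo ChIP-seq experiments whose summits pile up on planted loci.

    Per experiment, each hot locus receives a summit with probability
    ``truth.p_hot`` (CGI-only loci with ``truth.p_cgi``), jittered around the
    locus centre by a normal truncated at +/- 3 SD; background summits follow
    a homogeneous Poisson process. Peaks are symmetric around their summit
    with the summit offset recorded, so files round-trip through the
    narrowPeak reader.
    """
    if n_experiments <= 0:
        raise ValueError("n_experiments must be positive")
    rng = np.random.default_rng(seed)
    loci = truth.loci
    centers = ((loci["start"] + loci["end"]) // 2).to_numpy()
    probs = np.where(loci["kind"] == "hot", truth.p_hot, truth.p_cgi)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    lam = lengths / 1e6 * background_per_mb
    experiments: list[list[PeakRecord]] = []
    for e in range(n_experiments):
        summits: list[tuple[str, int]] = []
        hit = rng.random(len(loci)) < probs
        jit = rng.normal(0, jitter_sd, size=int(hit.sum()))
        jit = np.clip(jit, -3 * jitter_sd, 3 * jitter_sd).astype(int)
        for (_, row), dj in zip(loci[hit].iterrows(), jit):
            pos = int(np.clip(
                centers[row.name] + dj, 0, chrom_sizes[row["chrom"]] - 1
            ))
            summits.append((row["chrom"], pos))
        for c, L, l in zip(chroms, lengths, lam):
            n_bg = rng.poisson(l)
            for pos in rng.integers(0, int(L), size=n_bg):
                summits.append((c, int(pos)))
        records = []
        for i, (chrom, pos) in enumerate(summits):
            start = max(0, pos - peak_halfwidth)
            end = min(chrom_sizes[chrom], pos + peak_halfwidth)
            records.append(
                PeakRecord(
                    chrom=chrom,
                    start=start,
                    end=end,
                    name=f"exp{e}_peak{i}",
                    score=0,
                    strand=".",
                    signal_value=1.0,
                    p_value=-1.0,
                    q_value=-1.0,
                    summit_offset=pos - start,
                )
            )
        experiments.append(records)
    return experiments


def _uniform_reads(
    rng: np.random.Generator,
    n: int,
    chroms: Sequence[str],
    lengths: np.ndarray,
    read_length: int,
) -> pd.DataFrame:
    total = lengths.sum()
    counts = rng.multinomial(n, lengths / total)
    parts = []
    for c, L, k in zip(chroms, lengths.astype(np.int64), counts):
        starts = rng.integers(0, L, size=k)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "start": starts,
                    "end": np.minimum(starts + read_length, L),
                    "strand": np.where(rng.random(k) < 0.5, "+", "-"),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def make_reads(
    regions: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    log2_fc: float = 2.0,
    library_size: int = 1_000_000,
    read_length: int = 100,
    seed: int | None = None,
) -> tuple[ReadSet, ReadSet]:
    """IP/control read pair with an exact planted log2 CPM fold change.

    Control reads are uniform over the genome. IP reads are uniform plus a
    multinomial excess over the planted regions sized so that the EXPECTED
    CPM ratio on each region equals 2**log2_fc exactly (the excess
    probability is corrected for the mass it removes from the background).
    Excess reads always intersect their region. Strands are Bernoulli(0.5).
    """
    if not np.isfinite(log2_fc):
        raise ValueError("log2_fc must be finite")
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    G = lengths.sum()
    control = _uniform_reads(rng, library_size, chroms, lengths, read_length)
    # probability that a uniform read intersects a region (any >= 1 bp)
    span = regions["end"].to_numpy() - regions["start"].to_numpy() + read_length - 1
    q = span / G
    fc = 2.0**log2_fc
    # excess mass x_r solves n_bg*q_r + e_r = lib*fc*q_r with
    # n_bg = lib*(1 - sum x); closed form x_r = q_r (fc-1) / (1 - sum q)
    sum_q = q.sum()
    if sum_q >= 1:
        raise ValueError("planted regions cover the whole genome")
    x = (fc - 1) * q / (1.0 - sum_q)
    probs = np.concatenate([x, [1.0 - x.sum()]])
    if probs[-1] <= 0:
        raise ValueError("planted fold change too large for genome/region sizes")
    counts = rng.multinomial(library_size, probs)
    parts = []
    for (_, row), k in zip(regions.iterrows(), counts[:-1]):
        lo = max(0, row["start"] - read_length + 1)
        hi = max(lo + 1, row["end"] - 1)
        starts = rng.integers(lo, hi, size=k)
        parts.append(
            pd.DataFrame(
                {
                    "chrom": row["chrom"],
                    "start": starts,
                    "end": np.minimum(
                        starts + read_length, chrom_sizes[row["chrom"]]
                    ),
                    "strand": np.where(rng.random(k) < 0.5, "+", "-"),
                }
            )
        )
    parts.append(_uniform_reads(rng, int(counts[-1]), chroms, lengths, read_length))
    ip = pd.concat(parts, ignore_index=True)
    return (
        ReadSet(library_id="ip", reads=ip, library_size=library_size),
        ReadSet(library_id="control", reads=control, library_size=library_size),
    )


def beta_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """Beta(a, b) parameters matching a target median and IQR numerically."""
    if not 0 < median < 1:
        raise ValueError("median must be in (0, 1)")
    sigma = max(iqr / 1.349, 1e-4)  # normal-equivalent spread for the init
    var = min(sigma**2, median * (1 - median) * 0.95)
    k = median * (1 - median) / var - 1
    a0, b0 = max(median * k, 0.05), max((1 - median) * k, 0.05)

    def resid(logab: np.ndarray) -> np.ndarray:
        a, b = np.exp(logab)
        q1, med, q3 = beta_dist.ppf([0.25, 0.5, 0.75], a, b)
        return np.array([med - median, (q3 - q1) - iqr])

    sol = least_squares(resid, np.log([a0, b0]), xtol=1e-12, ftol=1e-12)
    a, b = np.exp(sol.x)
    return float(a), float(b)


def make_methylation(
    region_sets: Mapping[str, pd.DataFrame],
    planted: Mapping[str, tuple[float, float]],
    n_cell_types: int = 20,
    cpgs_per_region: int = 10,
    noise_sd: float = 0.02,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-cell-type per-CpG methylation tables with planted (median, IQR).

    For each region set, the per-region per-cell-type mean is drawn from the
    Beta distribution matched to that set's planted median/IQR; per-CpG
    values add Gaussian noise around the region mean and are clipped to
    [0, 1]. CpG positions are evenly spaced inside each region and shared
    across cell types.
    """
    rng = np.random.default_rng(seed)
    params = {name: beta_from_median_iqr(*planted[name]) for name in region_sets}
    cell_types = [f"cell{j + 1}" for j in range(n_cell_types)]
    tables: dict[str, list[pd.DataFrame]] = {ct: [] for ct in cell_types}
    for name, regions in region_sets.items():
        a, b = params[name]
        for _, row in regions.iterrows():
            width = row["end"] - row["start"]
            k = min(cpgs_per_region, width)
            pos = row["start"] + (np.arange(k) * width) // k
            means = rng.beta(a, b, size=n_cell_types)
            for ct, mu in zip(cell_types, means):
                vals = mu + (rng.normal(0, noise_sd, size=k) if noise_sd > 0 else 0.0)
                tables[ct].append(
                    pd.DataFrame(
                        {
                            "chrom": row["chrom"],
                            "pos": pos,
                            "fraction": np.clip(vals, 0.0, 1.0),
                        }
                    )
                )
    out = {}
    for ct, parts in tables.items():
        df = pd.concat(parts, ignore_index=True)
        df = df.drop_duplicates(subset=["chrom", "pos"])
        out[ct] = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
    return out


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


@dataclass
class BundleParams:
    """Study conditions of the default synthetic bundle."""

    n_chroms: int = 5
    chrom_length: int = 1_000_000
    background_gc: float = 0.41
    cpg_keep: float = 0.25
    n_hot_loci: int = 40
    n_cgi_loci: int = 150
    locus_length: int = 1500
    hot_gc: float = 0.60
    hot_cpg_keep: float = 1.0
    cgi_gc: float = 0.50
    cgi_cpg_keep: float = 0.55
    n_experiments: int = 100
    p_hot: float = 0.6
    p_cgi: float = 0.03
    jitter_sd: float = 50.0
    background_per_mb: float = 20.0
    log2_fc: float = 2.0
    library_size: int = 1_000_000
    read_length: int = 100
    n_cell_types: int = 20
    hot_methylation: tuple[float, float] = (0.05, 0.05)
    nonhot_cgi_methylation: tuple[float, float] = (0.05, 0.18)
    noise_sd: float = 0.02


def make_bundle(
    outdir: str | os.PathLike,
    seed: int = 0,
    params: BundleParams | None = None,
) -> SyntheticTruth:
    """Generate a complete synthetic input bundle under ``outdir``.

    Writes genome.fa, chrom.sizes, peaks/*.narrowPeak, cgi.bed, ip.bed,
    control.bed, methylation/<cell>.tsv and truth.json. All randomness
    derives from one master seed; identical seeds give identical files.
    """
    params = params or BundleParams()
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_genome, s_peaks, s_reads, s_meth = [
        int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(4)
    ]
    genome, loci = make_genome(
        n_chroms=params.n_chroms,
        chrom_length=params.chrom_length,
        background_gc=params.background_gc,
        cpg_keep=params.cpg_keep,
        n_hot_loci=params.n_hot_loci,
        n_cgi_loci=params.n_cgi_loci,
        locus_length=params.locus_length,
        hot_gc=params.hot_gc,
        hot_cpg_keep=params.hot_cpg_keep,
        cgi_gc=params.cgi_gc,
        cgi_cpg_keep=params.cgi_cpg_keep,
        seed=s_genome,
    )
    chrom_sizes = {c: len(s) for c, s in genome.items()}
    truth = SyntheticTruth(
        loci=loci,
        p_hot=params.p_hot,
        p_cgi=params.p_cgi,
        log2_fc=params.log2_fc,
        methylation={
            "hot": params.hot_methylation,
            "nonhot_cgi": params.nonhot_cgi_methylation,
        },
        enriched_kmers=enriched_kmers(
            background_gc=params.background_gc,
            cpg_keep=params.cpg_keep,
            hot_gc=params.hot_gc,
            hot_cpg_keep=params.hot_cpg_keep,
            seed=s_genome,
        ),
        seed=seed,
    )
    write_fasta(genome, os.path.join(outdir, "genome.fa"))
    hio.write_chrom_sizes(chrom_sizes, os.path.join(outdir, "chrom.sizes"))
    peak_dir = os.path.join(outdir, "peaks")
    os.makedirs(peak_dir, exist_ok=True)
    experiments = make_peak_experiments(
        truth,
        chrom_sizes,
        n_experiments=params.n_experiments,
        jitter_sd=params.jitter_sd,
        background_per_mb=params.background_per_mb,
        seed=s_peaks,
    )
    for e, records in enumerate(experiments):
        hio.write_narrowpeak(
            records, os.path.join(peak_dir, f"exp{e:03d}.narrowPeak")
        )
    hio.write_bed(truth.loci[["chrom", "start", "end"]], os.path.join(outdir, "cgi.bed"))
    ip, control = make_reads(
        truth.hot_loci,
        chrom_sizes,
        log2_fc=params.log2_fc,
        library_size=params.library_size,
        read_length=params.read_length,
        seed=s_reads,
    )
    for rs, fname in ((ip, "ip.bed"), (control, "control.bed")):
        df = rs.reads.copy()
        df.insert(3, "name", ".")
        df.insert(4, "score", 0)
        df = df[["chrom", "start", "end", "name", "score", "strand"]]
        df.to_csv(os.path.join(outdir, fname), sep="\t", header=False, index=False)
    meth_dir = os.path.join(outdir, "methylation")
    os.makedirs(meth_dir, exist_ok=True)
    tables = make_methylation(
        {"hot": truth.hot_loci, "nonhot_cgi": truth.cgi_loci},
        truth.methylation,
        n_cell_types=params.n_cell_types,
        noise_sd=params.noise_sd,
        seed=s_meth,
    )
    for ct, df in tables.items():
        df.to_csv(
            os.path.join(meth_dir, f"{ct}.tsv"), sep="\t", header=False, index=False
        )
    truth.to_json(os.path.join(outdir, "truth.json"))
    return truth
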