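import json
import os

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist

from hotregions.calling import summits_from_peaks
from hotregions.features import cpg_oe
from hotregions.intervals import count_overlaps
from hotregions.io import read_bed, read_narrowpeak, write_narrowpeak
from hotregions.simulate import (
    BundleParams,
    SyntheticTruth,
    beta_from_median_iqr,
    enriched_kmers,
    make_bundle,
    make_genome,
    make_methylation,
    make_peak_experiments,
    make_reads,
    write_fasta,
)

SMALL = dict(n_chroms=1, chrom_length=200_000, n_hot_loci=5, n_cgi_loci=10)


class TestMakeGenome:
    def test_deterministic(self):
        g1, l1 = make_genome(**SMALL, seed=4)
        g2, l2 = make_genome(**SMALL, seed=4)
        assert g1 == g2
        assert l1.equals(l2)

    def test_loci_disjoint_and_counted(self):
        _, loci = make_genome(**SMALL, seed=1)
        assert (loci["kind"] == "hot").sum() == 5
        assert (loci["kind"] == "cgi").sum() == 10
        srt = loci.sort_values(["chrom", "start"])
        same = srt["chrom"].to_numpy()[1:] == srt["chrom"].to_numpy()[:-1]
        gaps = srt["start"].to_numpy()[1:] - srt["end"].to_numpy()[:-1]
        assert (gaps[same] >= 0).all()

    def test_planted_hot_oe_above_background(self):
        genome, loci = make_genome(**SMALL, seed=2)
        seq = genome["chr1"]
        hot_oe = [
            cpg_oe(seq[r.start : r.end]) for r in loci[loci.kind == "hot"].itertuples()
        ]
        rng = np.random.default_rng(0)
        occupied = loci[["start", "end"]].to_numpy()
        bg_oe = []
        while len(bg_oe) < 100:
            s = int(rng.integers(0, len(seq) - 1500))
            if ((s < occupied[:, 1]) & (s + 1500 > occupied[:, 0])).any():
                continue
            bg_oe.append(cpg_oe(seq[s : s + 1500]))
        assert min(hot_oe) > np.percentile(bg_oe, 95)

    def test_too_many_loci_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_genome(n_chroms=1, chrom_length=50_000, n_hot_loci=50, n_cgi_loci=50)


def test_enriched_kmers_deterministic_and_cpg_flavoured():
    a = enriched_kmers(n_samples=20, seed=0)
    b = enriched_kmers(n_samples=20, seed=0)
    assert a == b
    assert len(a) >= 3
    assert any("CG" in k for k in a)


class TestPeakExperiments:
    def _truth(self, seed=0):
        genome, loci = make_genome(**SMALL, seed=seed)
        sizes = {c: len(s) for c, s in genome.items()}
        truth = SyntheticTruth(
            loci=loci, p_hot=0.6, p_cgi=0.03, log2_fc=2.0,
            methylation={}, enriched_kmers=[], seed=seed,
        )
        return truth, sizes

    def test_summits_land_on_hot_loci(self):
        truth, sizes = self._truth()
        exps = make_peak_experiments(truth, sizes, n_experiments=100, seed=3)
        summits = pd.DataFrame(
            [(r.chrom, r.start + r.summit_offset) for recs in exps for r in recs],
            columns=["chrom", "pos"],
        )
        summits["start"], summits["end"] = summits["pos"], summits["pos"] + 1
        # occupancy of each hot locus (center +/- 3 SD of jitter) ~ Binomial(100, 0.6)
        hot = truth.hot_loci.copy()
        mid = (hot["start"] + hot["end"]) // 2
        windows = pd.DataFrame({"chrom": hot["chrom"], "start": mid - 160, "end": mid + 160})
        occ = count_overlaps(summits, windows)
        assert (occ >= 30).all() and (occ <= 90).all()

    def test_roundtrip_through_narrowpeak(self, tmp_path):
        truth, sizes = self._truth()
        exps = make_peak_experiments(truth, sizes, n_experiments=2, seed=5)
        p = tmp_path / "e0.narrowPeak"
        write_narrowpeak(exps[0], p)
        back = read_narrowpeak(p)
        assert back == exps[0]
        # summit extraction is lossless
        assert summits_from_peaks(back, "e").summits == summits_from_peaks(exps[0], "e").summits

    def test_deterministic(self):
        truth, sizes = self._truth()
        a = make_peak_experiments(truth, sizes, n_experiments=3, seed=9)
        b = make_peak_experiments(truth, sizes, n_experiments=3, seed=9)
        assert a == b


class TestMakeReads:
    REGIONS = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [50_000, 120_000], "end": [52_000, 122_000]}
    )
    SIZES = {"chr1": 400_000}

    def test_shapes_and_dtypes(self):
        ip, ctrl = make_reads(self.REGIONS, self.SIZES, library_size=20_000, seed=0)
        for rs in (ip, ctrl):
            assert len(rs.reads) == 20_000 and rs.library_size == 20_000
            assert rs.reads["start"].dtype.kind == "i"
            assert rs.reads["end"].dtype.kind == "i"
            assert (rs.reads["end"] > rs.reads["start"]).all()
            assert (rs.reads["end"] <= 400_000).all()
            assert set(rs.reads["strand"]) <= {"+", "-"}

    def test_zero_fold_change_centres_at_zero(self):
        from hotregions.enrichment import region_log2_enrichment

        vals = []
        for seed in range(5):
            ip, ctrl = make_reads(
                self.REGIONS, self.SIZES, log2_fc=0.0, library_size=50_000, seed=seed
            )
            res = region_log2_enrichment(ip, ctrl, self.REGIONS)
            vals.append(res.table["log2_ratio"].mean())
        assert abs(np.mean(vals)) < 0.1

    def test_excess_reads_hit_their_region(self):
        ip, ctrl = make_reads(self.REGIONS, self.SIZES, log2_fc=3.0, library_size=50_000, seed=1)
        ip_n = count_overlaps(ip.reads, self.REGIONS)
        ct_n = count_overlaps(ctrl.reads, self.REGIONS)
        assert (ip_n > 4 * ct_n * 0.6).all()

    def test_impossible_fold_change(self):
        big = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [399_000]})
        with pytest.raises(ValueError):
            make_reads(big, self.SIZES, log2_fc=4.0, library_size=1000, seed=0)


def test_beta_from_median_iqr_matches_targets():
    for med, iqr in [(0.05, 0.05), (0.05, 0.18), (0.5, 0.2)]:
        a, b = beta_from_median_iqr(med, iqr)
        q1, m, q3 = beta_dist.ppf([0.25, 0.5, 0.75], a, b)
        assert m == pytest.approx(med, abs=1e-6)
        assert q3 - q1 == pytest.approx(iqr, abs=1e-6)


class TestMakeMethylation:
    REGIONS = pd.DataFrame(
        {"chrom": ["chr1"] * 4, "start": [0, 1000, 2000, 3000], "end": [500, 1500, 2500, 3500]}
    )

    def test_fractions_valid_positions_unique(self):
        tables = make_methylation({"s": self.REGIONS}, {"s": (0.05, 0.05)}, n_cell_types=3, seed=0)
        assert len(tables) == 3
        for df in tables.values():
            assert ((df["fraction"] >= 0) & (df["fraction"] <= 1)).all()
            assert not df.duplicated(["chrom", "pos"]).any()

    def test_zero_noise_constant_within_region(self):
        tables = make_methylation(
            {"s": self.REGIONS}, {"s": (0.3, 0.2)}, n_cell_types=1, noise_sd=0.0, seed=1
        )
        df = next(iter(tables.values()))
        groups = df.groupby(df["pos"] // 1000)["fraction"].nunique()
        assert (groups == 1).all()

    def test_shared_positions_across_cell_types(self):
        tables = make_methylation({"s": self.REGIONS}, {"s": (0.05, 0.05)}, n_cell_types=2, seed=2)
        a, b = tables.values()
        assert a["pos"].tolist() == b["pos"].tolist()


class TestMakeBundle:
    def test_bundle_files_and_determinism(self, tmp_path):
        params = BundleParams(
            n_chroms=1, chrom_length=150_000, n_hot_loci=3, n_cgi_loci=6,
            n_experiments=5, library_size=5_000, n_cell_types=2,
        )
        t1 = make_bundle(tmp_path / "b1", seed=11, params=params)
        t2 = make_bundle(tmp_path / "b2", seed=11, params=params)
        for name in ("genome.fa", "chrom.sizes", "cgi.bed", "ip.bed", "control.bed", "truth.json"):
            a = (tmp_path / "b1" / name).read_bytes()
            b = (tmp_path / "b2" / name).read_bytes()
            assert a == b, name
        assert len(list((tmp_path / "b1" / "peaks").iterdir())) == 5
        assert len(list((tmp_path / "b1" / "methylation").iterdir())) == 2
        assert t1.loci.equals(t2.loci)
        # truth JSON round-trips
        back = SyntheticTruth.from_json(tmp_path / "b1" / "truth.json")
        assert back.loci.equals(t1.loci)
        assert back.methylation == t1.methylation
        assert back.enriched_kmers == t1.enriched_kmers
        # cgi.bed covers all planted loci
        cgi = read_bed(tmp_path / "b1" / "cgi.bed")
        assert len(cgi) == 9

    def test_different_seed_differs(self, tmp_path):
        params = BundleParams(
            n_chroms=1, chrom_length=150_000, n_hot_loci=3, n_cgi_loci=6,
            n_experiments=2, library_size=2_000, n_cell_types=1,
        )
        make_bundle(tmp_path / "b1", seed=1, params=params)
        make_bundle(tmp_path / "b2", seed=2, params=params)
        assert (tmp_path / "b1" / "genome.fa").read_bytes() != (tmp_path / "b2" / "genome.fa").read_bytes()


def test_write_fasta_wraps_lines(tmp_path):
    write_fasta({"chr1": "A" * 200}, tmp_path / "g.fa")
    lines = (tmp_path / "g.fa").read_text().splitlines()
    assert lines[0] == ">chr1"
    assert all(len(l) <= 80 for l in lines[1:])
    assert "".join(lines[1:]) == "A" * 200
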