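import numpy as np
import pandas as pd
import pytest

from hotregions.enrichment import (
    ProfileMatrix,
    ReadSet,
    coverage_track,
    extend_reads,
    per_bp_log2_track,
    profile_matrix,
    region_log2_enrichment,
    score_correlation,
    stratified_window_sample,
)


def _reads(intervals, library_size=None, strand="+"):
    df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    df["strand"] = strand
    return ReadSet("lib", df, library_size=library_size)


def _reads_in_region(n, chrom="chr1", start=1000, end=1100):
    return [(chrom, start + (i % (end - start - 1)), start + (i % (end - start - 1)) + 1) for i in range(n)]


REGION = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1100]})


class TestRegionLog2Enrichment:
    def test_arithmetic_oracle(self):
        ip = _reads(_reads_in_region(100), library_size=1_000_000)
        ctrl = _reads(_reads_in_region(25), library_size=1_000_000)
        res = region_log2_enrichment(ip, ctrl, REGION, epsilon=1e-12)
        assert res.table["log2_ratio"].iloc[0] == pytest.approx(2.0, abs=1e-6)

    def test_identical_libraries_zero(self):
        ip = _reads(_reads_in_region(40), library_size=1000)
        res = region_log2_enrichment(ip, ip, REGION)
        assert res.table["log2_ratio"].iloc[0] == 0.0

    def test_zero_control_finite_and_monotone(self):
        ctrl = _reads([("chr1", 0, 50)], library_size=1000)
        prev = -np.inf
        for n_ip in (1, 5, 20):
            ip = _reads(_reads_in_region(n_ip) + [("chr1", 0, 50)], library_size=1000)
            val = region_log2_enrichment(ip, ctrl, REGION).table["log2_ratio"].iloc[0]
            assert np.isfinite(val)
            assert val > prev
            prev = val

    def test_default_epsilon_is_mean_one_read_cpm(self):
        ip = _reads(_reads_in_region(10), library_size=2_000_000)
        ctrl = _reads(_reads_in_region(10), library_size=1_000_000)
        res = region_log2_enrichment(ip, ctrl, REGION)
        assert res.pseudocount == pytest.approx((0.5 + 1.0) / 2)

    def test_empty_regions_error(self):
        ip = _reads(_reads_in_region(2))
        with pytest.raises(ValueError, match="empty"):
            region_log2_enrichment(ip, ip, REGION.iloc[:0])

    def test_one_bp_overlap_counts(self):
        # read [999,1001) overlaps [1000,1100) by one bp; [900,1000) does not
        ip = _reads([("chr1", 999, 1001)], library_size=1000)
        ctrl = _reads([("chr1", 900, 1000)], library_size=1000)
        res = region_log2_enrichment(ip, ctrl, REGION)
        assert res.table["ip_cpm"].iloc[0] > 0
        assert res.table["control_cpm"].iloc[0] == 0

    def test_cpm_scale_invariance(self):
        ip_iv = _reads_in_region(30)
        ct_iv = _reads_in_region(10) + [("chr1", 0, 50)] * 20
        a = region_log2_enrichment(
            _reads(ip_iv, 1000), _reads(ct_iv, 1000), REGION, epsilon=1.0
        )
        k = 7
        b = region_log2_enrichment(
            _reads(ip_iv * k, 1000 * k), _reads(ct_iv * k, 1000 * k), REGION, epsilon=1.0
        )
        assert a.table.equals(b.table)


class TestPerBpTrack:
    def test_equal_tracks_zero(self):
        t = np.full(100, 3.0)
        assert (per_bp_log2_track(t, t) == 0).all()

    def test_double_is_one(self):
        ctrl = np.full(50, 8.0)
        out = per_bp_log2_track(2 * ctrl, ctrl, epsilon=1e-9)
        assert np.allclose(out, 1.0, atol=1e-6)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            per_bp_log2_track(np.zeros(5), np.zeros(6))


def test_coverage_track_brute_force():
    rng = np.random.default_rng(2)
    sizes = {"chr1": 500}
    starts = rng.integers(0, 450, size=100)
    df = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 25, "strand": "+"}
    )
    rs = ReadSet("x", df, library_size=100)
    track = coverage_track(rs, sizes, cpm=False)["chr1"]
    brute = np.zeros(500)
    for s in starts:
        brute[s : s + 25] += 1
    assert np.array_equal(track, brute)


class TestStratifiedSample:
    def _regions(self, n=1000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n), "end": np.arange(n) + 1,
             "percentile": rng.uniform(0, 100, n)}
        )

    def test_exact_sample_size(self):
        out, shortfall = stratified_window_sample(
            self._regions(), strata=[(0, 75, 100), (75, 99, 100), (99, 100, 5)], seed=0
        )
        counts = out["stratum"].value_counts()
        assert counts["0-75"] == 100 and counts["75-99"] == 100 and counts["99-100"] == 5
        assert shortfall == {}

    def test_shortfall_recorded(self):
        out, shortfall = stratified_window_sample(
            self._regions(100), strata=[(99, 100, 3000)], seed=0
        )
        assert len(out) < 3000
        assert shortfall["99-100"] == 3000 - len(out)

    def test_same_seed_identical(self):
        r = self._regions()
        a, _ = stratified_window_sample(r, seed=9)
        b, _ = stratified_window_sample(r, seed=9)
        assert a.equals(b)


class TestProfileMatrix:
    def test_constant_track(self):
        track = {"chr1": np.full(10_000, 2.5)}
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2000]})
        prof = profile_matrix(track, windows)
        assert prof.values.shape == (1, 50)
        assert np.allclose(prof.values, 2.5)

    def test_two_bp_bins_arithmetic(self):
        track = {"chr1": np.arange(1, 201, dtype=float)}
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        prof = profile_matrix(track, windows)
        expected = np.array([2 * i - 0.5 for i in range(1, 51)])
        assert np.array_equal(prof.raw[0], expected)

    def test_rows_sorted_by_descending_occupancy(self):
        track = {"chr1": np.arange(10_000, dtype=float)}
        windows = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 2000], "end": [1000, 3000], "occupancy": [1, 9]}
        )
        prof = profile_matrix(track, windows)
        assert prof.windows["occupancy"].tolist() == [9, 1]
        assert prof.raw[0, 0] > prof.raw[1, 0]

    def test_off_chromosome_is_nan(self):
        track = {"chr1": np.ones(500)}
        windows = pd.DataFrame({"chrom": ["chr1"], "start": [-100], "end": [100]})
        prof = profile_matrix(track, windows)
        assert np.isnan(prof.raw[0, 0])
        assert prof.raw[0, -1] == 1.0

    def test_unknown_chromosome(self):
        with pytest.raises(ValueError, match="chrZ"):
            profile_matrix({"chr1": np.ones(10)}, pd.DataFrame(
                {"chrom": ["chrZ"], "start": [0], "end": [10]}
            ))


class TestExtendReads:
    def test_plus_strand(self):
        rs = _reads([("chr1", 100, 136)], strand="+")
        out = extend_reads(rs, 200)
        assert out.reads[["start", "end"]].iloc[0].tolist() == [100, 300]

    def test_minus_strand_clipped(self):
        rs = _reads([("chr1", 100, 136)], strand="-")
        out = extend_reads(rs, 200)
        assert out.reads[["start", "end"]].iloc[0].tolist() == [0, 136]

    def test_already_target_length(self):
        rs = _reads([("chr1", 50, 250)], strand="+")
        out = extend_reads(rs, 200)
        assert out.reads[["start", "end"]].iloc[0].tolist() == [50, 250]

    def test_library_size_unchanged(self):
        rs = _reads([("chr1", 100, 136)], library_size=555, strand="+")
        assert extend_reads(rs, 200).library_size == 555

    def test_chrom_bound_clipping(self):
        rs = _reads([("chr1", 100, 136)], strand="+")
        out = extend_reads(rs, 200, chrom_sizes={"chr1": 150})
        assert out.reads["end"].iloc[0] == 150

    def test_unstranded_error(self):
        rs = _reads([("chr1", 100, 136)], strand=".")
        with pytest.raises(ValueError, match="unstranded"):
            extend_reads(rs, 200)


class TestScoreCorrelation:
    def test_identical(self):
        rho, ok = score_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert ok and rho == pytest.approx(1.0)

    def test_reversed(self):
        rho, ok = score_correlation([1, 2, 3, 4], [4, 3, 2, 1])
        assert ok and rho == pytest.approx(-1.0)

    def test_constant_undefined(self):
        rho, ok = score_correlation([1.0, 1.0, 1.0], [1, 2, 3])
        assert not ok and np.isnan(rho)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            a, b = rng.normal(size=1000), rng.normal(size=1000)
            rho, _ = score_correlation(a, b)
            hits += abs(rho) < 0.1
        assert hits >= 95

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            score_correlation([1, 2, 3], [1, 2])
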