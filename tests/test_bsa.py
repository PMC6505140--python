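"""Smoothed-G scan: G statistic, tricube smoothing, null model, FDR, peaks,
pool simulator, and VCF/TSV round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pshquant import bsa
from pshquant.bsa import GPrimeScan, GScanParams


SMALL_GENOME = [(f"c{i}", 400_000) for i in range(4)]

counts = st.integers(min_value=0, max_value=500)


def brute_force_bh(p):
    """Step-up BH by direct evaluation of q_i = min_{j: p(j)>=p(i)} m p(j)/j."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def brute_force_smooth(pos, g, window):
    """O(n^2) tricube smoothing within one chromosome."""
    half = window / 2.0
    out = np.empty_like(g, dtype=float)
    for i, p0 in enumerate(pos):
        w = np.zeros_like(g, dtype=float)
        for j, pj in enumerate(pos):
            d = abs(pj - p0)
            if d <= half:
                w[j] = (1 - (d / half) ** 3) ** 3
        out[i] = np.dot(w, g) / w.sum()
    return out


class TestGStatistic:
    def test_independence_gives_zero(self):
        assert bsa.g_statistic(10, 10, 10, 10) == 0.0

    def test_known_table_value(self):
        # 2x2 table (30,10 / 10,30): G = 4 (30 ln 1.5 - 10 ln 2) = 20.9299...
        assert bsa.g_statistic(30, 10, 10, 30) == pytest.approx(20.9299, abs=1e-3)

    def test_zero_cells_handled(self):
        g = bsa.g_statistic(20, 0, 0, 20)
        assert np.isfinite(g) and g > 0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bsa.g_statistic(0, 0, 0, 0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(counts, counts, counts, counts)
    def test_symmetry_and_nonnegativity(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        g = bsa.g_statistic(a, b, c, d)
        assert g >= 0
        assert bsa.g_statistic(c, d, a, b) == pytest.approx(g)   # bulk swap
        assert bsa.g_statistic(b, a, d, c) == pytest.approx(g)   # allele swap

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(2)
        t = rng.integers(0, 100, size=(50, 4)) + 1
        vec = bsa.g_statistic(t[:, 0], t[:, 1], t[:, 2], t[:, 3])
        scal = [bsa.g_statistic(*row) for row in t]
        np.testing.assert_allclose(vec, scal)


class TestDeltaSnp:
    @pytest.mark.parametrize("table, expected", [
        ((10, 10, 10, 10), 0.0),
        ((0, 20, 20, 0), 1.0),
        ((20, 0, 0, 20), -1.0),
    ])
    def test_known_values(self, table, expected):
        assert bsa.delta_snp_index(*table) == pytest.approx(expected)

    def test_zero_depth_bulk_gives_missing(self):
        assert np.isnan(bsa.delta_snp_index(0, 0, 10, 10))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(counts, counts, counts, counts)
    def test_always_bounded(self, a, b, c, d):
        delta = bsa.delta_snp_index(a, b, c, d)
        assert np.isnan(delta) or -1.0 <= delta <= 1.0


class TestSmoothG:
    def test_lone_snp_unchanged(self):
        gp = bsa.smooth_g(np.array(["c1"]), np.array([100]), np.array([7.0]),
                          window=20_000)
        assert gp[0] == 7.0

    def test_coincident_snps_average(self):
        gp = bsa.smooth_g(np.array(["c1", "c1"]), np.array([500, 500]),
                          np.array([2.0, 6.0]), window=20_000)
        np.testing.assert_allclose(gp, [4.0, 4.0])

    def test_chromosomes_do_not_leak(self):
        gp = bsa.smooth_g(np.array(["c1", "c2"]), np.array([100, 100]),
                          np.array([1.0, 9.0]), window=20_000)
        np.testing.assert_allclose(gp, [1.0, 9.0])

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="unsorted"):
            bsa.smooth_g(np.array(["c1", "c1"]), np.array([200, 100]),
                         np.array([1.0, 2.0]), window=1000)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(4)
        pos = np.sort(rng.integers(1, 500_000, size=1000))
        g = rng.gamma(2.0, 1.5, size=1000)
        chrom = np.repeat("c1", 1000)
        fast = bsa.smooth_g(chrom, pos, g, window=20_000)
        slow = brute_force_smooth(pos, g, window=20_000)
        np.testing.assert_allclose(fast, slow, atol=1e-9, rtol=0)


class TestNullPvalues:
    def test_iid_lognormal_calibration(self):
        gp = np.random.default_rng(0).lognormal(1.0, 0.7, 5000)
        p = bsa.null_pvalues(gp)
        assert abs((p < 0.05).mean() - 0.05) <= 0.02

    def test_extreme_value_gets_minimum_p(self):
        gp = np.concatenate([np.random.default_rng(1).lognormal(1, 0.5, 500),
                             [1e6]])
        p = bsa.null_pvalues(gp)
        assert p[-1] == p.min()

    def test_p_monotone_nonincreasing_in_gprime(self):
        gp = np.sort(np.random.default_rng(2).lognormal(1, 0.6, 2000))
        p = bsa.null_pvalues(gp)
        assert np.all(np.diff(p) <= 1e-15)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError, match="at least 50"):
            bsa.null_pvalues(np.ones(10) * 2.0)


class TestFdrAdjust:
    def test_stepup_example(self):
        q = bsa.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bsa.fdr_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bsa.fdr_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            p = rng.uniform(0, 1, size=rng.integers(1, 60))
            np.testing.assert_allclose(bsa.fdr_adjust(p), brute_force_bh(p),
                                       atol=1e-12)

    def test_q_at_least_p(self):
        p = np.random.default_rng(7).uniform(0, 1, 500)
        assert np.all(bsa.fdr_adjust(p) >= p - 1e-12)


class TestCallPeaks:
    def make_df(self, pos, q, gprime=None, chrom="c1"):
        n = len(pos)
        return pd.DataFrame({
            "chrom": [chrom] * n, "pos": pos,
            "G_prime": gprime if gprime is not None else np.linspace(1, 2, n),
            "q": q})

    def test_no_significant_snps_no_peaks(self):
        df = self.make_df([100, 200, 300], [0.5, 0.9, 0.2])
        assert len(bsa.call_peaks(df, GScanParams())) == 0

    def test_single_block_single_peak(self):
        df = self.make_df([100, 200, 300, 400], [0.5, 0.001, 0.002, 0.5],
                          gprime=[1, 5, 9, 1])
        peaks = bsa.call_peaks(df, GScanParams(window=60_000))
        assert len(peaks) == 1
        assert peaks.loc[0, "start"] == 200
        assert peaks.loc[0, "end"] == 300
        assert peaks.loc[0, "max_gprime_pos"] == 300

    def test_nearby_runs_merge_distant_runs_do_not(self):
        pos = [1000, 2000, 10_000, 20_000, 21_000, 100_000, 200_000, 201_000]
        q = [0.001, 0.001, 0.5, 0.001, 0.001, 0.5, 0.001, 0.001]
        df = self.make_df(pos, q)
        # run gaps: 18 kb < 30 kb (merged), 180 kb > 30 kb (separate peak)
        peaks = bsa.call_peaks(df, GScanParams(window=60_000))
        assert len(peaks) == 2
        assert peaks.loc[0, "n_snps"] == 4
        assert peaks.loc[0, "start"] == 1000 and peaks.loc[0, "end"] == 21_000


class TestSimulatePools:
    def test_deterministic_for_fixed_seed(self):
        df1, t1 = bsa.simulate_pools(genome=SMALL_GENOME,
                                     qtls=[("c1", 200_000, 2.0)], seed=5)
        df2, t2 = bsa.simulate_pools(genome=SMALL_GENOME,
                                     qtls=[("c1", 200_000, 2.0)], seed=5)
        pd.testing.assert_frame_equal(df1, df2)
        assert t1.to_dict() == t2.to_dict()

    def test_strong_qtl_with_tiny_noise_separates_pools(self):
        _, truth = bsa.simulate_pools(genome=SMALL_GENOME,
                                      qtls=[("c2", 200_000, 5.0)],
                                      noise_sd=1e-6, seed=3)
        q = truth.qtls[0]
        assert q["freq_high"] - q["freq_low"] >= 0.9

    def test_null_simulation_calls_almost_nothing(self):
        snps, _ = bsa.simulate_pools(qtls=[], seed=0)
        result = GPrimeScan(snps, GScanParams(window=60_000)).fit()
        assert abs(result.snps["delta_snp"].mean()) <= 0.05
        assert (result.snps["q"] <= 0.01).mean() <= 0.02

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="not in genome"):
            bsa.simulate_pools(genome=SMALL_GENOME,
                               qtls=[("nope", 100, 1.0)], seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            bsa.simulate_pools(genome=SMALL_GENOME, n_segregants=10,
                               k_per_pool=6, seed=0)

    def test_depth_matches_poisson_coverage(self):
        snps, _ = bsa.simulate_pools(genome=SMALL_GENOME, qtls=[],
                                     mean_depth=55.0, seed=9)
        depth = (snps["ref_high"] + snps["alt_high"]).to_numpy()
        assert abs(depth.mean() - 55.0) <= 1.0


class TestFilterSnps:
    def test_low_depth_removed(self):
        df = pd.DataFrame([("c1", 100, 3, 2, 30, 25, 60.0),
                           ("c1", 200, 30, 25, 30, 25, 60.0)],
                          columns=bsa.SNP_COLUMNS)
        out = bsa.filter_snps(df, GScanParams(filter_min_depth=10))
        assert list(out["pos"]) == [200]

    def test_all_passing_is_identity(self):
        df = pd.DataFrame([("c1", 100, 30, 25, 30, 25, 60.0)],
                          columns=bsa.SNP_COLUMNS)
        out = bsa.filter_snps(df, GScanParams())
        pd.testing.assert_frame_equal(out, df)

    def test_removal_fraction_matches_poisson_tail(self):
        # with mean depth 12 and min depth 10, the per-SNP removal
        # probability is 1 - P(10 <= X <= 200)^2 for X ~ Poisson(12)
        snps, _ = bsa.simulate_pools(genome=[("c1", 5_000_000)], qtls=[],
                                     mean_depth=12.0, snp_spacing=500, seed=4)
        params = GScanParams(filter_min_depth=10, filter_max_depth=200)
        kept = bsa.filter_snps(snps, params)
        n = len(snps)
        p_keep_one = stats.poisson.cdf(200, 12) - stats.poisson.cdf(9, 12)
        p_removed = 1.0 - p_keep_one ** 2
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p_removed)
        assert lo <= n - len(kept) <= hi


class TestIO:
    def make_snps(self):
        df, _ = bsa.simulate_pools(genome=SMALL_GENOME,
                                   qtls=[("c1", 200_000, 2.0)], seed=8)
        return df

    def test_tsv_round_trip(self, tmp_path):
        df = self.make_snps()
        path = tmp_path / "snps.tsv"
        bsa.write_snp_table(df, path, header_lines=["test"])
        back = bsa.read_snp_table(path, fmt="tsv")
        pd.testing.assert_frame_equal(back, df)

    def test_vcf_round_trip(self, tmp_path):
        df = self.make_snps()
        path = tmp_path / "pools.vcf"
        bsa.write_vcf(df, path, genome=SMALL_GENOME)
        back = bsa.read_snp_table(path, fmt="vcf",
                                  high_sample="HIGH", low_sample="LOW")
        pd.testing.assert_frame_equal(back, df)

    def test_vcf_swapped_samples_swap_bulks(self, tmp_path):
        df = self.make_snps()
        path = tmp_path / "pools.vcf"
        bsa.write_vcf(df, path, genome=SMALL_GENOME)
        back = bsa.read_snp_table(path, fmt="vcf",
                                  high_sample="LOW", low_sample="HIGH")
        np.testing.assert_array_equal(back["ref_high"], df["ref_low"])

    def test_multiallelic_and_indel_records_skipped(self, tmp_path):
        path = tmp_path / "mixed.vcf"
        header = ("##fileformat=VCFv4.2\n"
                  "##contig=<ID=c1,length=1000>\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
                  '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="d">\n'
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHIGH\tLOW\n")
        records = [
            "c1\t100\t.\tA\tT\t60\t.\t.\tGT:AD\t./.:10,20\t./.:20,10",
            "c1\t200\t.\tA\tT,G\t60\t.\t.\tGT:AD\t./.:10,20,1\t./.:20,10,1",
            "c1\t300\t.\tAT\tA\t60\t.\t.\tGT:AD\t./.:10,20\t./.:20,10",
            "c1\t400\t.\tA\tT\t60\t.\t.\tGT:AD\t./.:5,5\t./.:5,5",
        ]
        path.write_text(header + "\n".join(records) + "\n")
        df = bsa.read_snp_table(path, fmt="vcf")
        assert list(df["pos"]) == [100, 400]

    def test_missing_tsv_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\n" "c1\t100\n")
        with pytest.raises(ValueError, match="missing columns"):
            bsa.read_snp_table(path, fmt="tsv")


class TestGPrimeScan:
    def test_scan_recovers_planted_qtl(self):
        snps, truth = bsa.simulate_pools(qtls=[("chr05", 300_000, 3.0)],
                                         seed=1)
        result = GPrimeScan(snps, GScanParams(window=60_000)).fit()
        top = result.snps.loc[result.snps["G_prime"].idxmax()]
        assert top["chrom"] == "chr05"
        assert abs(top["pos"] - truth.qtls[0]["snp_pos"]) <= 30_000
        assert len(result.peaks) >= 1
        assert "peaks called" in result.summary()

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            GPrimeScan(pd.DataFrame({"chrom": [], "pos": []}))

    def test_result_invariants(self):
        snps, _ = bsa.simulate_pools(genome=SMALL_GENOME,
                                     qtls=[("c1", 200_000, 3.0)], seed=2)
        res = GPrimeScan(snps).fit()
        df = res.snps
        assert (df["G"] >= 0).all()
        assert df["p"].between(0, 1).all()
        assert df["q"].between(0, 1).all()
        assert (df["q"] >= df["p"] - 1e-12).all()
        assert df["delta_snp"].abs().max() <= 1.0
        # peaks non-overlapping within each chromosome
        for _, pk in res.peaks.groupby("chrom"):
            starts = pk["start"].to_numpy()
            ends = pk["end"].to_numpy()
            assert np.all(starts[1:] > ends[:-1])
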