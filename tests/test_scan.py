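"""Genome-scan pipeline: windows, jackknife, FDR, outliers."""

import numpy as np
import pandas as pd
import pytest

from distfrac.core_stats import POPULATIONS
from distfrac.io import HaplotypeMatrix
from distfrac.scan import (bh_fdr, call_outliers, jackknife_z, run_scan,
                           window_scan)
from distfrac.simulator import SimulationConfig, simulate_chromosome


def matrix_from_patterns(patterns, positions, length):
    """Fixed-pattern sites (strings like 'ABBA') -> HaplotypeMatrix."""
    pops = np.array([p for p in POPULATIONS for _ in range(4)], dtype=object)
    rows = []
    for pat in patterns:
        row = []
        for allele in pat:
            row.extend([1 if allele == "B" else 0] * 4)
        rows.append(row)
    return HaplotypeMatrix(np.array(rows, dtype=np.int8),
                           np.asarray(positions), pops, polarized=True,
                           length=length)


class TestWindowScan:
    def test_consecutive_tiling(self):
        m = matrix_from_patterns(["ABBA"] * 5, [100, 2100, 4100, 6100, 9900],
                                 length=10_500)
        scan = window_scan(m, 2000, smooth=False)
        assert len(scan) == 5  # floor(10500 / 2000)
        assert scan["start"].tolist() == [0, 2000, 4000, 6000, 8000]
        assert scan["n_snps"].tolist() == [1, 1, 1, 1, 1]

    def test_all_bbaa_windows_have_zero_df(self):
        m = matrix_from_patterns(["BBAA"] * 12, np.arange(12) * 800 + 10,
                                 length=9600)
        scan = window_scan(m, 3200, smooth=False)
        assert np.allclose(scan["d_f"], 0.0)
        assert scan["D"].isna().all()

    def test_empty_window_sentinel(self):
        m = matrix_from_patterns(["ABBA"], [100], length=4000)
        scan = window_scan(m, 1000, smooth=False)
        assert scan.loc[1, "n_snps"] == 0
        assert np.isnan(scan.loc[1, "d_f"])

    def test_width_step_validation(self):
        m = matrix_from_patterns(["ABBA"], [100], length=4000)
        with pytest.raises(ValueError):
            window_scan(m, 1000, 2000)


class TestJackknife:
    def _scan(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        num = rng.normal(0.5, 0.3, n)
        den = rng.uniform(1.0, 3.0, n)
        snps = rng.integers(20, 200, n)
        return pd.DataFrame({
            "start": np.arange(n) * 1000, "end": (np.arange(n) + 1) * 1000,
            "n_snps": snps, "num": num, "den_df": den, "d_f": num / den})

    @staticmethod
    def naive_delete_one(num, den, weights, theta_hat):
        """Brute-force weighted jackknife variance via explicit loops."""
        g = len(num)
        theta_del = np.array([
            (num.sum() - num[j]) / (den.sum() - den[j]) for j in range(g)])
        n = weights.sum()
        h = n / weights
        theta_j = g * theta_hat - np.sum((1 - weights / n) * theta_del)
        return np.sum((h * theta_hat - (h - 1) * theta_del - theta_j) ** 2
                      / (h - 1)) / g

    def test_matches_naive_delete_one_recomputation(self):
        scan = self._scan()
        out = jackknife_z(scan, "d_f", null_value=0.0)
        num = scan["num"].to_numpy()
        den = scan["den_df"].to_numpy()
        m = scan["n_snps"].to_numpy(dtype=float)
        theta_hat = num.sum() / den.sum()
        var = self.naive_delete_one(num, den, m, theta_hat)
        block_sd = np.sqrt(len(num) * var)
        se = block_sd * np.sqrt(m.mean() / m)
        expect_z = (scan["d_f"].to_numpy() - 0.0) / se
        np.testing.assert_allclose(out["z"].to_numpy(), expect_z, atol=1e-10)

    def test_equal_weights_reduce_to_textbook_jackknife(self):
        scan = self._scan(seed=3)
        out = jackknife_z(scan, "d_f", equal_weights=True)
        num, den = scan["num"].to_numpy(), scan["den_df"].to_numpy()
        g = len(num)
        theta_del = np.array([
            (num.sum() - num[j]) / (den.sum() - den[j]) for j in range(g)])
        var = (g - 1) / g * np.sum((theta_del - theta_del.mean()) ** 2)
        se = np.sqrt(g * var)
        np.testing.assert_allclose(out["z"], scan["d_f"] / se, atol=1e-10)

    def test_constant_statistic_gives_sentinel(self):
        n = 6
        scan = pd.DataFrame({
            "start": np.arange(n), "end": np.arange(n) + 1,
            "n_snps": np.full(n, 10), "num": np.full(n, 0.5),
            "den_df": np.ones(n), "d_f": np.full(n, 0.5)})
        out = jackknife_z(scan, "d_f")
        assert out["z"].isna().all()

    def test_too_few_blocks(self):
        scan = pd.DataFrame({"start": [0], "end": [1], "n_snps": [5],
                             "num": [0.5], "den_df": [1.0], "d_f": [0.5]})
        assert jackknife_z(scan, "d_f")["z"].isna().all()

    def test_block_size_aggregates_consecutive_windows(self):
        scan = self._scan(seed=6)
        out = jackknife_z(scan, "d_f", block_size_bp=2000)
        num = scan["num"].to_numpy()
        den = scan["den_df"].to_numpy()
        snps = scan["n_snps"].to_numpy(dtype=float)
        # manual aggregation: pairs of consecutive 1 kb windows
        nb = num.reshape(-1, 2).sum(1)
        db = den.reshape(-1, 2).sum(1)
        m = snps.reshape(-1, 2).sum(1)
        theta_hat = nb.sum() / db.sum()
        var = self.naive_delete_one(nb, db, m, theta_hat)
        se = np.sqrt(len(nb) * var) * np.sqrt(m.mean() / snps)
        np.testing.assert_allclose(out["z"], scan["d_f"] / se, atol=1e-10)

    def test_null_at_observed_estimate_gives_zero_z(self):
        scan = self._scan(seed=4)
        out = jackknife_z(scan, "d_f",
                          null_value=scan["d_f"].to_numpy())
        np.testing.assert_allclose(out["z"], 0.0, atol=1e-12)


class TestBhFdr:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q <= 1.0)

    def test_nan_aware(self):
        q = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestOutliers:
    def _frame(self, qs):
        n = len(qs)
        return pd.DataFrame({
            "start": np.arange(n) * 10, "end": (np.arange(n) + 1) * 10,
            "d_f": np.linspace(-1, 1, n), "z": np.linspace(-3, 3, n),
            "p": qs, "q": qs})

    def test_no_hits(self):
        assert len(call_outliers(self._frame([0.3, 0.8, 0.051]))) == 0

    def test_tiers_are_nested(self):
        hits = call_outliers(self._frame([0.001, 0.03, 0.2]))
        assert len(hits) == 2
        assert hits["alpha"].tolist() == [0.01, 0.05]
        strict = hits[hits["alpha"] == 0.01]
        assert set(strict["start"]) <= set(hits["start"])


class TestPlantedOutlierWindow:
    def test_single_extreme_window_is_the_strictest_tier_outlier(self):
        """A constructed chromosome of mildly fluctuating windows plus one
        ABBA-saturated window: that window alone reaches the 0.01 tier."""
        cycle = [(2, 1, 5), (1, 2, 5), (1, 1, 5)]  # (nABBA, nBABA, nBBAA)
        patterns, positions = [], []
        for w in range(100):
            nA, nB, nC = (8, 0, 2) if w == 50 else cycle[w % 3]
            pats = ["ABBA"] * nA + ["BABA"] * nB + ["BBAA"] * nC
            for i, pat in enumerate(pats):
                patterns.append(pat)
                positions.append(w * 1000 + 10 + i * 90)
        m = matrix_from_patterns(patterns, positions, length=100_000)
        scan, outliers = run_scan(m, width_bp=1000, smooth=False)
        strict = outliers[outliers["alpha"] == 0.01]
        assert strict["start"].tolist() == [50_000]
        assert outliers["start"].tolist() == [50_000]


class TestPlantedTractScan:
    def test_tract_windows_rank_highest(self):
        cfg = SimulationConfig(L=5000, rho=50.0)
        m = simulate_chromosome(cfg, total_length=200_000,
                                tract=(80_000, 100_000), tract_f=0.9, seed=31)
        scan, outliers = run_scan(m, width_bp=10_000, smooth=True)
        tract = set(range(80_000, 100_000, 10_000))
        top2 = set(scan.nlargest(2, "d_f")["start"])
        assert top2 == tract
        # the planted windows are also the significant ones
        assert set(outliers["start"]) >= tract

    def test_mean_null_inside_region(self):
        cfg = SimulationConfig(L=5000, rho=50.0)
        m = simulate_chromosome(cfg, total_length=60_000,
                                tract=(20_000, 40_000), tract_f=0.8, seed=32)
        scan, _ = run_scan(m, width_bp=10_000, null="mean",
                           region=(20_000, 40_000))
        inside = scan[(scan.start >= 20_000) & (scan.end <= 40_000)]
        # inside windows are tested against their own mean -> Z straddles 0
        assert abs(inside["z"].mean()) < abs(
            run_scan(m, width_bp=10_000)[0]
            [(scan.start >= 20_000) & (scan.end <= 40_000)]["z"].mean())
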