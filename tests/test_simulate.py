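"""Synthetic-data generators: determinism, conservation and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xover.pollen import classify_pairs, filter_crossover_pairs
from xover.simulate import (SimConfig, TrueRateMap, sample_crossover_positions,
                            simulate_backcross, simulate_clustered_genes,
                            simulate_pollen_counts, simulate_read_pairs,
                            simulate_titration, marker_map_for)


class TestTrueRateMap:
    def test_total_cm(self):
        rm = TrueRateMap.uniform(1, 1_000_000, 10, total_cm=10.0)
        assert rm.total_cm == pytest.approx(10.0)
        assert rm.lengths_bp.sum() == 1_000_000

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TrueRateMap(np.array([1, 150]), np.array([100, 200]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            TrueRateMap(np.array([1]), np.array([100]), np.array([-1.0]))
        with pytest.raises(ValueError):  # > 50 cM breaks the model
            TrueRateMap.uniform(1, 1_000_000, 4, total_cm=60.0)

    def test_hotspot_multiplier_keeps_total(self):
        rm = TrueRateMap.uniform(1, 1_000_000, 10, total_cm=10.0)
        hot = rm.with_multiplier(4, 5.0)
        assert hot.total_cm == pytest.approx(10.0)
        assert hot.rates[4] / hot.rates[0] > 4
        with pytest.raises(ValueError):  # a 30x interval would exceed the map total
            rm.with_multiplier(4, 30.0)


class TestBackcross:
    def test_seed_determinism(self, mrc_like):
        rate_map, mm = mrc_like
        g1, t1 = simulate_backcross(rate_map, mm, 2000, seed=9)
        g2, t2 = simulate_backcross(rate_map, mm, 2000, seed=9)
        assert g1.equals(g2)
        np.testing.assert_array_equal(t1.crossover_positions, t2.crossover_positions)

    def test_double_resistant_count_matches_screen(self, mrc_like):
        """22.8 cM over 9,016 progeny: ~1,028 double-resistant expected."""
        rate_map, mm = mrc_like
        _, truth = simulate_backcross(rate_map, mm, 9016, seed=1)
        expect = 9016 * rate_map.total_cm / 200
        se = np.sqrt(9016 * (expect / 9016) * (1 - expect / 9016))
        assert abs(truth.n_double_resistant - expect) < 4 * se
        assert expect == pytest.approx(1027.8, abs=0.1)

    def test_zero_rate_gives_no_recombinants(self):
        rm = TrueRateMap(np.array([1]), np.array([1_000_000]), np.array([0.0]))
        mm = marker_map_for(rm, 5)
        geno, truth = simulate_backcross(rm, mm, 5000, seed=0)
        assert truth.n_recombinant == 0
        assert len(geno) == 0

    def test_rejects_half_morgan_region(self):
        rm = TrueRateMap.uniform(1, 1_000_000, 4, total_cm=50.0)
        mm = marker_map_for(rm, 5)
        with pytest.raises(ValueError):
            simulate_backcross(rm, mm, 100, seed=0)

    def test_positions_follow_rate_map(self):
        """Crossover position histogram converges to the rate map
        (chi-square GOF not rejected at alpha=0.01, n=1e5)."""
        rng = np.random.default_rng(21)
        rm = TrueRateMap.uniform(1, 2_000_000, 20, total_cm=15.0).with_multiplier(3, 10.0)
        pos = sample_crossover_positions(rm, 100_000, rng)
        idx = rm.locate(pos)
        obs = np.bincount(idx, minlength=20)
        expected = 100_000 * rm.interval_cm / rm.total_cm
        p = stats.chisquare(obs, expected).pvalue
        assert p > 0.01

    def test_uniform_positions_match_length_fractions(self):
        """Uniform map: per-interval fractions within 3 binomial SE of the
        length fractions."""
        rng = np.random.default_rng(8)
        rm = TrueRateMap.uniform(1, 1_000_000, 10, total_cm=20.0)
        n = 100_000
        pos = sample_crossover_positions(rm, n, rng)
        frac = np.bincount(rm.locate(pos), minlength=10) / n
        f_len = rm.lengths_bp / rm.lengths_bp.sum()
        se = np.sqrt(f_len * (1 - f_len) / n)
        assert np.all(np.abs(frac - f_len) <= 3 * se)


class TestReadPairs:
    def test_noiseless_pair_brackets_crossover(self, amplicon):
        """Zero error: retained pairs classify cleanly and the true
        breakpoint lies inside the SNP-bounded uncertainty region."""
        snps = amplicon.snp_positions
        xo = np.array([int(snps[18]) + 5])
        cfg = SimConfig(n_read_pairs=200)
        pairs, truth = simulate_read_pairs(amplicon, xo, cfg, seed=4)
        records = classify_pairs(pairs, amplicon)
        retained, _ = filter_crossover_pairs(records)
        assert len(retained) > 0
        for rec in retained:
            ler, col = rec.haplotype_end("Ler"), rec.haplotype_end("Col")
            last_ler = snps[(snps >= ler.start) & (snps <= ler.end)].max()
            first_col = snps[(snps >= col.start) & (snps <= col.end)].min()
            assert last_ler <= xo[0] < first_col

    def test_hotspot_bracketing(self, amplicon):
        """Pairs simulated from one interval overwhelmingly bracket it."""
        snps = amplicon.snp_positions
        rng = np.random.default_rng(3)
        b = 20
        xo = rng.integers(snps[b], snps[b + 1], size=50)
        pairs, _ = simulate_read_pairs(amplicon, xo, SimConfig(n_read_pairs=2000), seed=6)
        retained, _ = filter_crossover_pairs(classify_pairs(pairs, amplicon))
        ok = 0
        for rec in retained:
            ler, col = rec.haplotype_end("Ler"), rec.haplotype_end("Col")
            if ler.start <= snps[b] and col.end >= snps[b + 1]:
                ok += 1
        assert ok / len(retained) >= 0.99

    def test_errors_cause_unmapped_never_wrong_configuration(self, amplicon):
        """1% substitution error: reads drop out under exact matching, but no
        retained pair reports the anti-crossover configuration."""
        snps = amplicon.snp_positions
        rng = np.random.default_rng(13)
        xo = rng.integers(snps[10], snps[11], size=30)
        cfg = SimConfig(n_read_pairs=1500, per_base_error=0.01)
        pairs, truth = simulate_read_pairs(amplicon, xo, cfg, seed=14)
        records = classify_pairs(pairs, amplicon)
        n_unmapped = sum("unmapped" in (r.end1.haplotype, r.end2.haplotype)
                         for r in records)
        assert n_unmapped > 0.2 * len(records)  # measurable attrition
        retained, _ = filter_crossover_pairs(records)
        for rec in retained:
            ler, col = rec.haplotype_end("Ler"), rec.haplotype_end("Col")
            assert ler.start < col.start  # never Col-left under this library

    def test_determinism_and_truth_table(self, amplicon):
        snps = amplicon.snp_positions
        xo = [int(snps[5]) + 10, int(snps[30]) + 3]
        p1, t1 = simulate_read_pairs(amplicon, xo, SimConfig(n_read_pairs=50), seed=2)
        p2, t2 = simulate_read_pairs(amplicon, xo, SimConfig(n_read_pairs=50), seed=2)
        assert [p.seq1 for p in p1] == [p.seq1 for p in p2]
        assert t1.equals(t2)
        assert set(t1["crossover_bp"]) <= set(xo)

    def test_rejects_out_of_range_crossovers(self, amplicon):
        with pytest.raises(ValueError):
            simulate_read_pairs(amplicon, [5], SimConfig(n_read_pairs=10), seed=0)


class TestClusteredGenes:
    def test_singleton(self):
        g = simulate_clustered_genes(1_000_000, 1, 1, None, seed=0)
        assert len(g) == 1
        assert (g["end"] > g["start"]).all()

    def test_no_overlaps_within_group(self):
        g = simulate_clustered_genes(20_000_000, 15, 8, None, seed=5, n_background=100)
        for _, sub in g.groupby("group"):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_replicate_draws_have_similar_distributions(self):
        """KS distance between independent draws with identical parameters is
        small (mean D < 0.15 at n = 200 over 100 replicate pairs)."""
        ds = []
        for k in range(100):
            a = simulate_clustered_genes(30_000_000, 25, 8, None, seed=2 * k)
            b = simulate_clustered_genes(30_000_000, 25, 8, None, seed=2 * k + 1)
            d = stats.ks_2samp(np.diff(np.sort(a["start"])),
                               np.diff(np.sort(b["start"]))).statistic
            ds.append(d)
        assert np.mean(ds) < 0.15

    def test_clustered_differs_from_uniform_background(self):
        g = simulate_clustered_genes(30_000_000, 25, 8, None, seed=3, n_background=200)
        cl = g[g["group"] == "clustered"]
        bg = g[g["group"] == "background"]
        d_cl = np.diff(np.sort(cl["start"]))
        d_bg = np.diff(np.sort(bg["start"]))
        assert stats.ks_2samp(d_cl, d_bg).pvalue < 0.01


class TestPollenCounts:
    def test_zero_cm_has_no_recombinant_classes(self):
        c = simulate_pollen_counts(0.0, 10_000, seed=1)
        assert c["yellow_only"] == 0 and c["red_only"] == 0

    def test_counts_sum_to_n(self):
        c = simulate_pollen_counts(17.0, 12_345, seed=2)
        assert sum(c.values()) == 12_345

    def test_recovery_within_3_se(self):
        from xover.ftl import ftl_cm
        c = simulate_pollen_counts(20.0, 30_000, seed=3)
        cm, se = ftl_cm(c["yellow_only"], c["red_and_yellow"])
        assert abs(cm - 20.0) <= 3 * se

    def test_range_validated(self):
        with pytest.raises(ValueError):
            simulate_pollen_counts(60.0, 100, seed=0)


class TestTitration:
    def test_half_positive_at_ln2(self):
        tab = simulate_titration(np.log(2), [1.0], 2000, seed=6)
        assert tab.loc[0, "n_positive"] == pytest.approx(1000, abs=3 * np.sqrt(500))

    def test_saturation_limit(self):
        tab = simulate_titration(1e6, [1.0], 96, seed=0)
        assert tab.loc[0, "n_positive"] == 96

    def test_recovery_within_20_percent(self):
        from xover.pollen import poisson_concentration
        tab = simulate_titration(1.5, [1.0], 96, seed=8)
        lam, _ = poisson_concentration(int(tab.loc[0, "n_positive"]), 96, 1.0)
        assert abs(lam - 1.5) / 1.5 < 0.2
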