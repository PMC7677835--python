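"""Hotspot calling: binomial test vs a direct pmf-summation oracle,
cis/trans classification, binning/merging, regulator assignment, and
end-to-end recovery of planted hotspots."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtlhot import SimConfig, simulate_dataset
from eqtlhot.association import ScanConfig, run_scan
from eqtlhot.datatypes import GeneInfo, PvalueMatrix, SnpInfo
from eqtlhot.hotspot import (
    HotspotParams,
    binomial_hotspot_test,
    call_eqtls,
    classify_cis_trans,
    define_bins,
    merge_hotspot_bins,
    min_significant_count,
    run_hotspot_analysis,
)


def binom_sf_oracle(k, n, m):
    """P(X >= k) for X ~ Binomial(n, 1/m) by direct pmf summation in
    exact rational arithmetic (truncated once the remaining geometric
    tail is provably below 1e-25 of the running total)."""
    from fractions import Fraction

    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    p = Fraction(1, m)
    q = 1 - p
    term = Fraction(math.comb(n, k)) * p**k * q ** (n - k)
    total = term
    for j in range(k, n):
        term = term * (n - j) * p / ((j + 1) * q)
        total += term
        ratio = (n - j - 1) * p / ((j + 2) * q)
        if ratio < Fraction(1, 2) and term < total * Fraction(1, 10**25):
            break
    return float(total)


def snp(pos, chrom="chr1", sid=None):
    return SnpInfo(id=sid or f"s{chrom}:{pos}", chrom=chrom, pos=pos, ref_allele="A", alt_allele="G")


def gene(start, end, chrom="chr1", gid=None):
    return GeneInfo(id=gid or f"g{chrom}:{start}", chrom=chrom, start=start, end=end)


class TestCisTrans:
    @pytest.mark.parametrize(
        "s, g, window, expected",
        [
            (snp(50_000, "chr1"), gene(55_000, 57_000, "chr2"), 10_000, False),
            (snp(50_000), gene(55_000, 57_000), 10_000, True),  # gap 5 kb
            (snp(45_000), gene(55_000, 57_000), 10_000, True),  # gap exactly 10 kb
            (snp(44_999), gene(55_000, 57_000), 10_000, False),  # gap 10,001
            (snp(56_000), gene(55_000, 57_000), 10_000, True),  # inside gene body
            (snp(67_001), gene(55_000, 57_000), 10_000, False),  # past downstream edge
        ],
    )
    def test_distance_rule(self, s, g, window, expected):
        assert classify_cis_trans(s, g, window) is expected


class TestCallEqtls:
    def _pm(self, values):
        values = np.asarray(values, float)
        snps = [snp(1_000 * (i + 1)) for i in range(values.shape[0])]
        genes = [gene(10**6 + 50_000 * j, 10**6 + 50_000 * j + 500, "chr9", f"g{j}") for j in range(values.shape[1])]
        return PvalueMatrix(snps=snps, genes=genes, pvalues=values)

    def test_all_ones_yields_nothing(self):
        assert call_eqtls(self._pm(np.ones((3, 4))), HotspotParams()) == []

    def test_threshold_is_strict(self):
        pm = self._pm([[5e-5, 4.9e-5]])
        calls = call_eqtls(pm, HotspotParams())
        assert len(calls) == 1 and calls[0].gene_index == 1

    def test_cis_flagging(self):
        pm = PvalueMatrix(
            snps=[snp(100_000)],
            genes=[gene(105_000, 106_000, gid="near"), gene(500_000, 501_000, gid="far")],
            pvalues=np.array([[1e-9, 1e-9]]),
        )
        calls = call_eqtls(pm, HotspotParams())
        assert [c.is_cis for c in calls] == [True, False]


class TestBinomialTest:
    def test_zero_count_gives_p_one(self):
        stats = binomial_hotspot_test([0, 5], m=10, alpha=0.05)
        assert stats[0].binomial_p == 1.0

    def test_matches_summation_oracle_exactly(self):
        stats = binomial_hotspot_test([25], m=100, alpha=0.05)
        # n = 25 (single SNP carries all events)
        oracle = binom_sf_oracle(25, 25, 100)
        assert abs(stats[0].binomial_p - oracle) <= 1e-12 * oracle

    def test_oracle_agreement_mean_ten_case(self):
        counts = np.zeros(100, dtype=int)
        counts[0] = 25
        counts[1:76] = 13  # n = 1000
        stats = binomial_hotspot_test(counts, m=100, alpha=0.05)
        assert sum(s.trans_count for s in stats) == 1000
        oracle = binom_sf_oracle(25, 1000, 100)
        assert abs(stats[0].binomial_p - oracle) <= 1e-12 * oracle

    def test_extreme_concentration(self):
        counts = np.zeros(10, dtype=int)
        counts[3] = 50
        stats = binomial_hotspot_test(counts, m=10, alpha=0.05)
        assert stats[3].significant and stats[3].binomial_p < 0.05 / 10
        assert all(s.binomial_p == 1.0 for i, s in enumerate(stats) if i != 3)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(1, 2000),
        m=st.integers(2, 50_000),
        frac=st.floats(0.0, 1.0),
    )
    def test_oracle_agreement_property(self, n, m, frac):
        mean = n / m
        k = int(frac * min(n, 5 * mean + 40))
        counts = np.zeros(3, dtype=int)
        counts[1] = k
        counts[0] = n - k
        stats = binomial_hotspot_test(counts, m=m, alpha=0.05)
        oracle = binom_sf_oracle(k, n, m)
        if oracle > 1e-280:
            assert abs(stats[1].binomial_p - oracle) <= 1e-12 * oracle

    def test_monotone_in_alpha(self):
        counts = np.random.default_rng(0).poisson(2, size=200)
        sig_loose = sum(s.significant for s in binomial_hotspot_test(counts, 200, 0.05))
        sig_tight = sum(s.significant for s in binomial_hotspot_test(counts, 200, 0.005))
        assert sig_tight <= sig_loose

    def test_min_significant_count_consistency(self):
        n, m, alpha = 500, 300, 0.05
        kstar = min_significant_count(n, m, alpha)
        from scipy.stats import binom

        assert binom.sf(kstar - 1, n, 1 / m) < alpha / m
        assert not binom.sf(kstar - 2, n, 1 / m) < alpha / m


class TestBins:
    def test_truncated_last_bin(self):
        bins = define_bins({"chr1": 45_000}, 20_000)
        assert [(b.start, b.end) for b in bins] == [(1, 20_000), (20_001, 40_000), (40_001, 45_000)]

    def test_exact_extent_single_bin(self):
        assert len(define_bins({"chr1": 20_000}, 20_000)) == 1

    def test_two_chromosomes_local_numbering(self):
        bins = define_bins({"chrA": 25_000, "chrB": 5_000}, 20_000)
        assert len(bins) == 3
        assert [b.index_in_chrom for b in bins] == [0, 1, 0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(extent=st.integers(1, 10**6), width=st.integers(1, 10**5))
    def test_bins_tile_the_chromosome(self, extent, width):
        bins = define_bins({"c": extent}, width)
        assert bins[0].start == 1 and bins[-1].end == extent
        for a, b in zip(bins, bins[1:]):
            assert b.start == a.end + 1


class TestMergeAndRegulators:
    def _stats(self, positions, counts, m=50):
        from eqtlhot.hotspot import SnpHotspotStat

        snps = [snp(p) for p in positions]
        stats = [
            SnpHotspotStat(snp_index=i, trans_count=c, binomial_p=1e-9 if c else 1.0,
                           significant=bool(c))
            for i, c in enumerate(counts)
        ]
        return stats, snps

    def test_adjacent_bins_merge(self):
        stats, snps = self._stats([90_000, 110_000], [5, 7])  # bins 4 and 5 (w=20k)
        bins = define_bins({"chr1": 200_000}, 20_000)
        calls = merge_hotspot_bins(stats, bins, snps)
        assert len(calls) == 1
        assert calls[0].bins_merged == 2
        assert calls[0].region == ("chr1", 80_001, 120_000)
        assert calls[0].total_trans_eqtls == 12
        assert calls[0].peak_snp.pos == 110_000  # larger count wins

    def test_non_adjacent_bins_stay_separate(self):
        stats, snps = self._stats([90_000, 150_000], [5, 7])
        bins = define_bins({"chr1": 200_000}, 20_000)
        assert len(merge_hotspot_bins(stats, bins, snps)) == 2

    def test_no_merge_across_chromosomes(self):
        from eqtlhot.hotspot import SnpHotspotStat

        snps = [snp(19_000, "chrA"), snp(1_000, "chrB")]
        stats = [
            SnpHotspotStat(0, 5, 1e-9, True),
            SnpHotspotStat(1, 5, 1e-9, True),
        ]
        bins = define_bins({"chrA": 20_000, "chrB": 20_000}, 20_000)
        assert len(merge_hotspot_bins(stats, bins, snps)) == 2

    def test_peak_tie_breaks_to_smaller_position(self):
        stats, snps = self._stats([90_000, 95_000], [5, 5])
        bins = define_bins({"chr1": 200_000}, 20_000)
        calls = merge_hotspot_bins(stats, bins, snps)
        assert calls[0].peak_snp.pos == 90_000

    def test_regulator_assignment_and_label_format(self):
        from eqtlhot.hotspot import EqtlCall, HotspotCall, assign_regulators

        snps = [
            SnpInfo(id="peak", chrom="chrII", pos=117_298, ref_allele="A", alt_allele="G"),
            SnpInfo(id="outside", chrom="chrII", pos=900_000, ref_allele="C", alt_allele="T"),
        ]
        genes = [gene(110_000, 112_000, "chrII", "PIN4"), gene(120_000, 121_000, "chrII", "SAS3"),
                 gene(905_000, 906_000, "chrII", "FAR")]
        eqtls = [
            EqtlCall(0, 0, 1e-9, True),
            EqtlCall(0, 1, 1e-8, True),
            EqtlCall(1, 2, 1e-9, True),  # cis, but its SNP is outside the region
            EqtlCall(0, 2, 1e-9, False),  # trans: never a regulator
        ]
        call = HotspotCall(region=("chrII", 100_001, 140_000), bins_merged=2,
                           peak_snp=snps[0], total_trans_eqtls=1)
        regs = assign_regulators(call, eqtls, snps, genes)
        assert regs == ["PIN4", "SAS3"]
        assert call.peak_label == "chrII:117298_A/G"

    def test_empty_regulators_allowed(self):
        from eqtlhot.hotspot import HotspotCall, assign_regulators

        call = HotspotCall(region=("chr1", 1, 20_000), bins_merged=1,
                           peak_snp=snp(5_000), total_trans_eqtls=3)
        assert assign_regulators(call, [], [snp(5_000)], []) == []


class TestEndToEnd:
    def test_all_null_matrix_yields_no_hotspots(self):
        snps = [snp(1_000 * (i + 1)) for i in range(20)]
        genes = [gene(5_000 * (j + 1), 5_000 * (j + 1) + 400, "chr2") for j in range(10)]
        pm = PvalueMatrix(snps=snps, genes=genes, pvalues=np.ones((20, 10)))
        stats, calls, summary = run_hotspot_analysis(pm)
        assert summary["n_trans_eqtls"] == 0 and calls == []

    def test_trans_count_conservation(self, planted_cohort):
        cfg, (geno, expr, truth) = planted_cohort
        pm = run_scan(geno, expr, ScanConfig(method="ols"))
        eqtls = call_eqtls(pm, HotspotParams())
        stats, calls, summary = run_hotspot_analysis(pm)
        assert sum(s.trans_count for s in stats) == sum(not c.is_cis for c in eqtls)

    def test_planted_hotspot_recovered_and_only_it(self, planted_cohort):
        cfg, (geno, expr, truth) = planted_cohort
        pm = run_scan(geno, expr, ScanConfig(method="ols"))
        stats, calls, summary = run_hotspot_analysis(pm)
        planted_snp = geno.snps[truth.hotspots[0][0]]
        assert len(calls) == 1
        chrom, start, end = calls[0].region
        assert chrom == planted_snp.chrom and start <= planted_snp.pos <= end

    def test_removing_planted_effects_removes_hotspots(self, planted_cohort):
        cfg, _ = planted_cohort
        null_cfg = SimConfig(**{**vars(cfg), "hotspot_spec": [], "cis_spec": []})
        geno, expr, _ = simulate_dataset(null_cfg)
        pm = run_scan(geno, expr, ScanConfig(method="ols"))
        _, calls, _ = run_hotspot_analysis(pm)
        assert calls == []

    def test_monotone_in_eqtl_threshold(self, planted_cohort):
        cfg, (geno, expr, truth) = planted_cohort
        pm = run_scan(geno, expr, ScanConfig(method="ols"))
        counts = {}
        for thr in (1e-6, 5e-5, 1e-3):
            eqtls = call_eqtls(pm, HotspotParams(eqtl_threshold=thr))
            counts[thr] = sum(not c.is_cis for c in eqtls)
        assert counts[1e-6] <= counts[5e-5] <= counts[1e-3]

    def test_hotspot_regions_disjoint_and_sorted(self, planted_cohort):
        cfg, (geno, expr, truth) = planted_cohort
        pm = run_scan(geno, expr, ScanConfig(method="ols"))
        _, calls, _ = run_hotspot_analysis(
            pm, HotspotParams(eqtl_threshold=1e-3, alpha=0.5)
        )
        regions = [c.region for c in calls]
        for (c1, s1, e1), (c2, s2, e2) in zip(regions, regions[1:]):
            if c1 == c2:
                assert e1 < s2
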