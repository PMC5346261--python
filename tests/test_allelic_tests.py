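"""Exact allelic tests against brute-force enumeration oracles, and the
behaviour of the selection-corrected imbalance test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hapmeth as h
from hapmeth.allelic_tests import git_sample_null

from conftest import make_phased
from oracles import (
    binom_two_sided_oracle,
    fisher_two_sided_oracle,
    git_table_oracle,
)


class TestFisherTwoSided:
    @pytest.mark.parametrize("table,expected", [
        ((5, 5, 5, 5), 1.0),
        ((10, 0, 0, 10), 2 / 184756),   # full enumeration, margins 10/10
        ((0, 0, 3, 4), 1.0),            # degenerate margin
    ])
    def test_worked_examples(self, table, expected):
        assert h.fisher_two_sided(*table) == pytest.approx(expected, rel=1e-9)

    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12)))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, table):
        assert h.fisher_two_sided(*table) == pytest.approx(
            fisher_two_sided_oracle(*table), abs=1e-10)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            h.fisher_two_sided(-1, 1, 1, 1)

    @given(st.tuples(st.integers(0, 25), st.integers(0, 25),
                     st.integers(0, 25), st.integers(0, 25)))
    @settings(max_examples=150, deadline=None)
    def test_agrees_with_scipy(self, table):
        """Independent cross-check against scipy's implementation."""
        from scipy.stats import fisher_exact
        want = fisher_exact([[table[0], table[1]],
                             [table[2], table[3]]]).pvalue
        assert h.fisher_two_sided(*table) == pytest.approx(want, abs=1e-9)


class TestAshBinomial:
    @pytest.mark.parametrize("a,b,expected", [
        (10, 0, 2 * 0.5 ** 10),
        (5, 5, 1.0),
        (0, 1, 1.0),   # both tails cover the whole support
    ])
    def test_worked_examples(self, a, b, expected):
        assert h.ash_binomial_test(a, b) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_gives_no_test(self):
        assert h.ash_binomial_test(0, 0) is None

    @given(st.integers(1, 30), st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_enumeration_oracle(self, n, data):
        k = data.draw(st.integers(0, n))
        assert h.ash_binomial_test(k, n - k) == pytest.approx(
            binom_two_sided_oracle(k, n), abs=1e-12)


class TestHistoneRatio:
    @pytest.mark.parametrize("high,low,expected", [
        (25, 75, 0.25), (50, 50, 0.0), (100, 0, -0.5),
    ])
    def test_formula(self, high, low, expected):
        assert h.allelic_histone_ratio(high, low) == pytest.approx(expected)

    def test_zero_total_skipped(self):
        assert h.allelic_histone_ratio(0, 0) is None


class TestAssignHighLow:
    def test_clear_winners(self, rng):
        df = make_phased([
            (100, "snp0", 0, 9, 1, 2, 8),   # A high
            (100, "snp0", 1, 0, 10, 10, 0),  # B high
        ])
        out = h.assign_high_low(df, rng)
        assert list(out["high_allele"]) == ["A", "B"]
        assert not out["tie"].any()
        assert list(out["m_high"]) == [9, 10]
        assert list(out["m_low"]) == [2, 0]

    def test_tie_is_flagged_and_seeded(self):
        df = make_phased([(100, "snp0", i, 5, 5, 5, 5) for i in range(40)])
        out1 = h.assign_high_low(df, np.random.default_rng(7))
        out2 = h.assign_high_low(df, np.random.default_rng(7))
        assert out1["tie"].all()
        assert list(out1["high_allele"]) == list(out2["high_allele"])
        assert set(out1["high_allele"]) == {"A", "B"}  # coin is fair-ish


class TestGitPool:
    def test_per_sample_sorting_before_pooling(self, rng):
        df = make_phased([
            (100, "snp0", 0, 9, 1, 2, 8),
            (100, "snp0", 1, 1, 9, 8, 2),
        ])
        out = h.assign_high_low(df, rng)
        assert h.git_pool(out) == (17, 3, 3, 17)

    def test_single_sample(self, rng):
        df = make_phased([(100, "snp0", 0, 9, 1, 2, 8)])
        assert h.git_pool(h.assign_high_low(df, rng)) == (9, 1, 2, 8)


class TestGitTableTest:
    def test_worked_example_three_three(self):
        # support {0..3}, pmf (1,9,9,1)/20; E = {2,3} with mass 1/2;
        # numerator P(X=3) = 1/20 -> corrected p = 0.1
        assert h.git_table_test(3, 0, 0, 3) == pytest.approx(0.1, abs=1e-12)

    def test_observed_table_outside_selection_event(self):
        # [[5,5],[5,5]]: x_obs = 5 is a tie, E = {6..10};
        # P(X>=5 and E)/P(E) = P(X>=6)/P(X>=6) = 1
        assert h.git_table_test(5, 5, 5, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [(0, 0, 3, 4), (3, 4, 0, 0),
                                       (0, 3, 0, 4), (3, 0, 4, 0)])
    def test_degenerate_margins(self, table):
        assert h.git_table_test(*table) == 1.0

    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)))
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, table):
        assert h.git_table_test(*table) == pytest.approx(
            git_table_oracle(*table), abs=1e-10)

    @given(st.tuples(st.integers(0, 15), st.integers(0, 15),
                     st.integers(0, 15), st.integers(0, 15)))
    @settings(max_examples=100, deadline=None)
    def test_p_at_most_one(self, table):
        assert 0.0 <= h.git_table_test(*table) <= 1.0


class TestGitCohortTest:
    def test_single_sample_reduces_to_table_test(self, rng):
        df = make_phased([(100, "snp0", 0, 3, 0, 0, 3)])
        p, _ = h.git_test(h.assign_high_low(df, rng))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_tied_sample_contributes_no_bias(self, rng):
        # a single all-tie sample: conditional law is symmetric, p large
        df = make_phased([(100, "snp0", 0, 5, 5, 5, 5)])
        p, _ = h.git_test(h.assign_high_low(df, rng))
        assert p > 0.4

    def test_corrected_le_naive_on_strong_signal(self, rng):
        rows = [(100, "snp0", i, 28, 2, 3, 27) for i in range(20)]
        out = h.assign_high_low(make_phased(rows), rng)
        p, naive = h.git_test(out)
        assert p < 1e-10
        assert naive < 1e-10

    def test_null_calibration_small(self, rng):
        """Corrected p is roughly uniform while the naive tail on the
        sorted pooled table rejects nearly always (300 null CpGs)."""
        n_cpgs, n_samples, depth = 300, 30, 30
        rej_corr = rej_naive = 0
        for _ in range(n_cpgs):
            d = rng.poisson(depth, (n_samples, 2))
            m = rng.binomial(d, 0.5)
            df = make_phased([
                (100, "snp0", s, m[s, 0], d[s, 0] - m[s, 0],
                 m[s, 1], d[s, 1] - m[s, 1])
                for s in range(n_samples)
            ])
            p, naive = h.git_test(h.assign_high_low(df, rng))
            rej_corr += p < 0.05
            rej_naive += naive < 0.05
        assert rej_naive / n_cpgs > 0.5
        assert 0.01 <= rej_corr / n_cpgs <= 0.09


class TestGitSampleNull:
    def test_distribution_is_normalised_and_supported_in_event(self):
        out = git_sample_null(8, 2, 3, 7)
        assert out is not None
        lo, pmf = out
        assert pmf.sum() == pytest.approx(1.0)
        xs = np.arange(lo, lo + len(pmf))
        support = xs[pmf > 0]
        # all supported tables satisfy the strict selection inequality
        assert all(x * 10 > (11 - x) * 10 for x in support)

    def test_zero_depth_allele_uninformative(self):
        assert git_sample_null(0, 0, 3, 7) is None


class TestAsmPool:
    @staticmethod
    def haplotypes(haps):
        from hapmeth.phased_data import HaplotypeMatrix
        haps = np.asarray(haps, dtype=np.int8)
        return HaplotypeMatrix(
            samples=[f"S{i}" for i in range(haps.shape[0])],
            snp_ids=["snp0"], chroms=["chr1"], positions=[150], haps=haps)

    def test_orients_by_ref_alt_and_sums(self):
        # sample S0 hapA carries ref, S1 hapA carries alt
        hap = self.haplotypes([[[0, 1]], [[1, 0]]])
        df = make_phased([
            (100, "snp0", 0, 8, 2, 1, 9),
            (100, "snp0", 1, 2, 8, 7, 3),
        ])
        assert h.asm_pool(df, hap) == (15, 5, 3, 17)

    def test_single_sample(self):
        hap = self.haplotypes([[[0, 1]]])
        df = make_phased([(100, "snp0", 0, 5, 0, 0, 5)])
        assert h.asm_pool(df, hap) == (5, 0, 0, 5)

    def test_non_het_samples_excluded(self):
        hap = self.haplotypes([[[0, 0]], [[-1, -1]]])
        df = make_phased([
            (100, "snp0", 0, 8, 2, 1, 9),
            (100, "snp0", 1, 2, 8, 7, 3),
        ])
        assert h.asm_pool(df, hap) is None


class TestScans:
    def test_asm_scan_depth_filter_excludes_shallow_samples(self):
        hap = TestAsmPool.haplotypes([[[0, 1]], [[0, 1]]])
        df = make_phased([
            (100, "snp0", 0, 8, 2, 1, 9),
            (100, "snp0", 1, 3, 1, 10, 10),   # allele A has 4 reads
        ])
        res = h.asm_scan(df, hap, min_per_allele=5)
        assert len(res) == 1
        assert res["n_samples"].iloc[0] == 1
        assert (res["meth_ref"] + res["unmeth_ref"]).iloc[0] == 10

    def test_git_scan_empty_input(self):
        res = h.git_scan(make_phased([]).reindex(
            columns=["chrom", "pos", "strand", "context", "sample",
                     "snp_id", "methA", "unmethA", "methB", "unmethB"]))
        assert len(res) == 0

    def test_ash_scan_pools_samples_and_adjusts_within_mark(self):
        histone = pd.DataFrame({
            "mark": ["M1"] * 4 + ["M2"] * 2,
            "mark_type": ["activating"] * 4 + ["repressive"] * 2,
            "snp_id": ["snp0", "snp0", "snp1", "snp1", "snp0", "snp0"],
            "chrom": "chr1", "pos": 150,
            "sample": ["S0", "S1"] * 3,
            "readsA": [10, 10, 5, 5, 0, 0],
            "readsB": [0, 0, 5, 5, 10, 10],
        })
        res = h.ash_scan(histone)
        m1_snp0 = res[(res["mark"] == "M1") & (res["snp_id"] == "snp0")]
        assert m1_snp0["p"].iloc[0] == pytest.approx(2 * 0.5 ** 20, rel=1e-9)
        assert (res.groupby("mark")["q"].max() <= 1.0).all()


class TestMapHistoneToCpg:
    snp_positions = pd.DataFrame({
        "snp_id": ["snp0", "snp1", "snp2"],
        "pos": [1100, 1450, 2000],
    })

    histone = pd.DataFrame({
        "mark": "M1", "mark_type": "activating",
        "snp_id": ["snp0", "snp1", "snp2"],
        "chrom": "chr1", "pos": [1100, 1450, 2000],
        "sample": "S0",
        "readsA": [10, 5, 99], "readsB": [2, 3, 99],
    })

    def test_git_mode_sums_snps_within_window(self):
        out = h.map_histone_to_cpg(self.histone, cpg_pos=1000,
                                   phasing_snp="snp0",
                                   snp_positions=self.snp_positions,
                                   mode="GIT", window=500)
        assert out == (15, 5)

    def test_asm_mode_uses_only_phasing_snp(self):
        out = h.map_histone_to_cpg(self.histone, cpg_pos=1000,
                                   phasing_snp="snp0",
                                   snp_positions=self.snp_positions,
                                   mode="ASM", window=500)
        assert out == (10, 2)

    def test_no_snp_in_window(self):
        out = h.map_histone_to_cpg(self.histone, cpg_pos=5000,
                                   phasing_snp="snpX",
                                   snp_positions=self.snp_positions,
                                   mode="GIT", window=500)
        assert out is None
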