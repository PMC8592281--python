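"""Instrument selection, LD pruning, allele harmonization, F-statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dietmr.harmonize import f_statistic, harmonize, ld_prune, select_significant
from dietmr.sumstats import LdTable

from conftest import make_instrument_set, make_sumstats


class TestSelectSignificant:
    def test_strict_threshold(self):
        ss = make_sumstats(
            [
                {"snp_id": "rs1", "pvalue": 1e-9},
                {"snp_id": "rs2", "pvalue": 4e-8},
                {"snp_id": "rs3", "pvalue": 6e-8},
            ]
        )
        assert select_significant(ss, 5e-8) == ["rs1", "rs2"]

    def test_no_hits_gives_empty_list(self):
        ss = make_sumstats([{"snp_id": f"rs{i}", "pvalue": 0.5} for i in range(3)])
        assert select_significant(ss) == []

    def test_ties_broken_lexicographically(self):
        ss = make_sumstats(
            [{"snp_id": "rsB", "pvalue": 1e-9}, {"snp_id": "rsA", "pvalue": 1e-9}]
        )
        assert select_significant(ss) == ["rsA", "rsB"]

    def test_relaxing_threshold_is_monotone(self):
        ss = make_sumstats(
            [{"snp_id": f"rs{i}", "pvalue": p}
             for i, p in enumerate([1e-12, 1e-9, 1e-7, 1e-4, 0.3])]
        )
        tight = set(select_significant(ss, 5e-8))
        loose = set(select_significant(ss, 1e-4))
        assert tight <= loose


class TestLdPrune:
    def test_correlated_pair_keeps_lower_p(self):
        ld = LdTable()
        ld.set("rs1", "rs2", 0.5)
        kept = ld_prune(["rs1", "rs2"], {"rs1": 1e-10, "rs2": 1e-9}, ld, 0.001)
        assert kept == ["rs1"]

    def test_empty_ld_table_keeps_all(self):
        kept = ld_prune(["rs1", "rs2", "rs3"], {"rs1": 1e-10, "rs2": 1e-9, "rs3": 1e-8},
                        LdTable(), 0.001)
        assert kept == ["rs1", "rs2", "rs3"]

    def test_perfect_ld_block_keeps_exactly_one(self):
        ld = LdTable()
        for a, b in [("rs1", "rs2"), ("rs1", "rs3"), ("rs2", "rs3")]:
            ld.set(a, b, 1.0)
        kept = ld_prune(["rs1", "rs2", "rs3"], {"rs1": 1e-8, "rs2": 1e-12, "rs3": 1e-9},
                        ld, 0.001)
        assert kept == ["rs2"]

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_output_is_independent_set(self, data):
        n = data.draw(st.integers(2, 10))
        snps = [f"rs{i}" for i in range(n)]
        pvals = {s: data.draw(st.floats(1e-12, 1e-6), label=s) for s in snps}
        ld = LdTable()
        for i in range(n):
            for j in range(i + 1, n):
                r2 = data.draw(st.sampled_from([0.0, 0.0005, 0.01, 0.5, 1.0]))
                if r2 > 0:
                    ld.set(snps[i], snps[j], r2)
        kept = ld_prune(snps, pvals, ld, 0.001)
        assert len(kept) >= 1
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert ld.r2(a, b) < 0.001


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_sign(self):
        exp = make_sumstats([{"snp_id": "rs1", "effect_allele": "A",
                              "other_allele": "G", "beta": 0.10}])
        out = make_sumstats([{"snp_id": "rs1", "effect_allele": "G",
                              "other_allele": "A", "beta": -0.05, "eaf": 0.7}])
        iset = harmonize(exp, out, ["rs1"])
        assert iset.beta_outcome[0] == pytest.approx(0.05)
        assert iset.counts["sign_flipped"] == 1

    def test_ambiguous_palindrome_dropped(self):
        exp = make_sumstats([{"snp_id": "rs1", "effect_allele": "A",
                              "other_allele": "T", "eaf": 0.50}])
        out = make_sumstats([{"snp_id": "rs1", "effect_allele": "A",
                              "other_allele": "T", "eaf": 0.50}])
        iset = harmonize(exp, out, ["rs1"])
        assert len(iset) == 0
        assert iset.counts["palindromic_dropped"] == 1

    def test_resolvable_palindrome_kept_when_frequencies_agree(self):
        exp = make_sumstats([{"snp_id": "rs1", "effect_allele": "C",
                              "other_allele": "G", "eaf": 0.10}])
        out = make_sumstats([{"snp_id": "rs1", "effect_allele": "C",
                              "other_allele": "G", "eaf": 0.12}])
        assert len(harmonize(exp, out, ["rs1"])) == 1

    def test_palindrome_on_opposite_frequency_sides_dropped(self):
        exp = make_sumstats([{"snp_id": "rs1", "effect_allele": "C",
                              "other_allele": "G", "eaf": 0.10}])
        out = make_sumstats([{"snp_id": "rs1", "effect_allele": "C",
                              "other_allele": "G", "eaf": 0.90}])
        iset = harmonize(exp, out, ["rs1"])
        assert len(iset) == 0

    def test_allele_mismatch_dropped_and_counted(self):
        exp = make_sumstats([{"snp_id": "rs1", "effect_allele": "A", "other_allele": "G"}])
        out = make_sumstats([{"snp_id": "rs1", "effect_allele": "A", "other_allele": "C"}])
        iset = harmonize(exp, out, ["rs1"])
        assert len(iset) == 0
        assert iset.counts["allele_mismatch"] == 1

    def test_strand_flip_resolved_for_non_palindrome(self):
        # outcome reported on the other strand: A/G vs T/C
        exp = make_sumstats([{"snp_id": "rs1", "effect_allele": "A",
                              "other_allele": "G", "beta": 0.10}])
        out = make_sumstats([{"snp_id": "rs1", "effect_allele": "T",
                              "other_allele": "C", "beta": 0.07}])
        iset = harmonize(exp, out, ["rs1"])
        assert iset.beta_outcome[0] == pytest.approx(0.07)
        assert iset.counts["strand_flipped"] == 1

    def test_missing_in_outcome_dropped(self):
        exp = make_sumstats([{"snp_id": "rs1"}, {"snp_id": "rs2"}])
        out = make_sumstats([{"snp_id": "rs1"}])
        iset = harmonize(exp, out, ["rs1", "rs2"])
        assert list(iset.snp_ids) == ["rs1"]
        assert iset.counts["missing_in_outcome"] == 1

    def test_idempotent_on_aligned_pair(self):
        exp = make_sumstats(
            [{"snp_id": "rs1", "beta": 0.1}, {"snp_id": "rs2", "beta": -0.2,
                                              "effect_allele": "C", "other_allele": "T"}]
        )
        out = make_sumstats(
            [{"snp_id": "rs1", "beta": 0.05}, {"snp_id": "rs2", "beta": 0.02,
                                               "effect_allele": "C", "other_allele": "T"}]
        )
        first = harmonize(exp, out, ["rs1", "rs2"])
        again = harmonize(exp, out, ["rs1", "rs2"])
        np.testing.assert_array_equal(first.beta_outcome, again.beta_outcome)
        assert first.counts["sign_flipped"] == 0


class TestFStatistic:
    def test_single_snp_value(self):
        iset = make_instrument_set([0.02], [0.0], [0.1], sx=[0.002])
        f, mean = f_statistic(iset)
        assert f[0] == pytest.approx(100.0)
        assert mean == pytest.approx(100.0)

    def test_zero_beta_gives_zero_f(self):
        iset = make_instrument_set([0.0], [0.0], [0.1], sx=[0.002])
        f, _ = f_statistic(iset)
        assert f[0] == 0.0

    def test_mean_over_instruments(self):
        iset = make_instrument_set([0.02, 0.008], [0, 0], [0.1, 0.1], sx=[0.002, 0.002])
        _, mean = f_statistic(iset)
        assert mean == pytest.approx((100 + 16) / 2)
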