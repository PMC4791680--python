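"""Heterozygosity estimators, exact HWE test and null-allele estimation."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest

from mapsat.io_formats import GenotypeTable
from mapsat.fixtures import make_genotypes
from mapsat.marker_qc import (
    allele_stats,
    hwe_exact_enumeration,
    hwe_monte_carlo,
    hwe_test,
    null_allele_estimates,
    observed_het,
    summarize_panel,
    unbiased_expected_het,
)


def _table(calls, locus="L1"):
    return GenotypeTable.from_records(
        [(f"s{i}", locus, a, b) for i, (a, b) in enumerate(calls)]
    )


class TestAlleleStats:
    def test_counting(self):
        n, freqs, size_range, na = allele_stats(_table([(120, 124), (120, 120)]), "L1")
        assert n == 2 and na == 2
        assert freqs == {120: Fraction(3, 4), 124: Fraction(1, 4)}
        assert size_range == (120, 124)

    def test_single_genotype(self):
        n, freqs, size_range, na = allele_stats(_table([(100, 100)]), "L1")
        assert (n, na) == (1, 1) and freqs == {100: Fraction(1)}

    def test_all_missing_raises(self):
        table = GenotypeTable.from_records([("s1", "L1", None, None)])
        with pytest.raises(ValueError, match="L1"):
            allele_stats(table, "L1")

    def test_frequencies_sum_to_one_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            calls = [tuple(sorted(rng.integers(100, 110, size=2).tolist())) for _ in range(n)]
            _, freqs, _, _ = allele_stats(_table(calls), "L1")
            assert sum(freqs.values()) == Fraction(1)


class TestHeterozygosity:
    def test_observed_het_fraction(self):
        calls = [(1, 2)] * 10 + [(1, 1)] * 14
        assert observed_het(_table(calls), "L1") == pytest.approx(10 / 24)

    def test_observed_het_extremes(self):
        assert observed_het(_table([(1, 1), (2, 2)]), "L1") == 0.0
        assert observed_het(_table([(1, 2), (3, 4)]), "L1") == 1.0

    def test_unbiased_closed_form(self):
        he = unbiased_expected_het({1: 0.5, 2: 0.5}, n=24)
        assert he == pytest.approx(48 / 47 * 0.5)

    def test_single_allele_zero(self):
        assert unbiased_expected_het({1: 1.0}, n=10) == 0.0

    def test_n1_falls_back_uncorrected(self):
        with pytest.warns(UserWarning):
            he = unbiased_expected_het({1: 0.5, 2: 0.5}, n=1)
        assert he == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        """H_E equals the brute-force sum over unordered allele pairs."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            k = int(rng.integers(2, 8))
            raw = rng.dirichlet(np.ones(k))
            freqs = {i: float(p) for i, p in enumerate(raw)}
            n = int(rng.integers(2, 50))
            brute = sum(
                2 * freqs[i] * freqs[j]
                for i, j in itertools.combinations(range(k), 2)
            ) * (2 * n) / (2 * n - 1)
            assert unbiased_expected_het(freqs, n) == pytest.approx(brute, rel=1e-10)

    def test_invariant_to_label_permutation(self):
        freqs = {1: 0.2, 2: 0.3, 3: 0.5}
        permuted = {10: 0.5, 20: 0.2, 30: 0.3}
        assert unbiased_expected_het(freqs, 12) == pytest.approx(
            unbiased_expected_het(permuted, 12)
        )


class TestHweTest:
    def test_two_homozygotes_exact_third(self):
        """Config {AA,BB} has Levene probability 1/3; {AB,AB} has 2/3."""
        assert hwe_exact_enumeration([(1, 1), (2, 2)]) == pytest.approx(1 / 3)

    def test_single_allele_degenerate(self):
        result = hwe_test(_table([(1, 1), (1, 1)]), "L1")
        assert result.p_value == 1.0 and result.method == "degenerate"

    def test_probabilities_sum_to_one(self):
        """The Levene distribution over all configurations is normalized."""
        from mapsat.marker_qc import (
            _enumerate_configs, _log_levene_const, _log_prob_config,
        )
        calls = [(1, 2), (1, 1), (2, 3), (3, 3), (1, 3)]
        counts = {}
        for a, b in calls:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        allele_counts = [counts[k] for k in sorted(counts)]
        const = _log_levene_const(allele_counts, len(calls))
        total = sum(
            math.exp(_log_prob_config(c, const))
            for c in _enumerate_configs(allele_counts, None)
        )
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_enumeration_vs_monte_carlo(self):
        """Both routes agree within 3 Monte-Carlo standard errors (tiny cases)."""
        rng = np.random.default_rng(21)
        reps = 20_000
        for trial in range(8):
            n = int(rng.integers(3, 9))
            n_alleles = int(rng.integers(2, 4))
            calls = [tuple(sorted(rng.integers(1, n_alleles + 1, size=2).tolist()))
                     for _ in range(n)]
            if len({a for g in calls for a in g}) < 2:
                continue
            p_enum = hwe_exact_enumeration(calls)
            p_mc = hwe_monte_carlo(calls, reps=reps, seed=int(rng.integers(2**31)))
            se = math.sqrt(p_enum * (1 - p_enum) / reps) + 1 / reps
            assert abs(p_mc - p_enum) <= 3 * se + 1e-12

    def test_monte_carlo_path_taken_when_capped(self, hw_table):
        result = hwe_test(hw_table, "locA", reps=5_000, seed=4, enumeration_cap=2)
        assert result.method == "monte_carlo"
        exact = hwe_test(hw_table, "locA")
        assert exact.method == "enumeration"
        assert result.p_value == pytest.approx(exact.p_value, abs=0.03)

    def test_hw_proportions_not_rejected(self):
        """Genotypes laid out exactly at HW proportions give a large p."""
        # p=0.5: 6 AA, 12 AB, 6 BB
        calls = [(1, 1)] * 6 + [(1, 2)] * 12 + [(2, 2)] * 6
        result = hwe_test(_table(calls), "L1")
        assert result.p_value > 0.5

    def test_extreme_heterozygote_deficit_rejected(self):
        calls = [(1, 1)] * 12 + [(2, 2)] * 12
        result = hwe_test(_table(calls), "L1")
        assert result.p_value < 1e-4


class TestNullAlleles:
    def test_formula_arithmetic(self):
        est = null_allele_estimates(0.6, 0.4)
        assert est.chakraborty == pytest.approx(0.2)
        assert est.brookfield1 == pytest.approx(0.125)

    def test_equal_heterozygosities_zero(self):
        est = null_allele_estimates(0.5, 0.5)
        assert est.chakraborty == 0.0 and est.brookfield1 == 0.0

    def test_negative_floored_with_raw_kept(self):
        est = null_allele_estimates(0.4, 0.6)
        assert est.chakraborty == 0.0 and est.brookfield1 == 0.0
        assert est.chakraborty_raw == pytest.approx(-0.2)
        assert est.brookfield1_raw == pytest.approx(-1 / 7)

    def test_both_zero_undefined_chakraborty(self):
        est = null_allele_estimates(0.0, 0.0)
        assert est.chakraborty is None and est.brookfield1 == 0.0


class TestParameterRecovery:
    def test_he_recovery_large_sample(self):
        freqs = {100 + 4 * i: 0.2 for i in range(5)}
        table, truth = make_genotypes(500, [(freqs, 0.0, 0.0)], seed=8)
        n, est_freqs, _, _ = allele_stats(table, "locus_1")
        he = unbiased_expected_het(est_freqs, n)
        assert abs(he - truth[0].expected_het) < 0.03

    def test_chakraborty_recovers_null_frequency(self):
        """Mean Chakraborty estimate near the simulated null frequency."""
        r_true = 0.2
        freqs = {100 + 4 * i: 0.16 for i in range(5)}
        estimates = []
        for rep in range(200):
            table, _ = make_genotypes(100, [(freqs, r_true, 0.0)], seed=1000 + rep)
            n, est_freqs, _, _ = allele_stats(table, "locus_1")
            he = unbiased_expected_het(est_freqs, n)
            ho = observed_het(table, "locus_1")
            est = null_allele_estimates(he, ho).chakraborty
            if est is not None:
                estimates.append(est)
        assert abs(float(np.mean(estimates)) - r_true) < 0.1


class TestSummarizePanel:
    def test_reference_panel_aggregates(self):
        from mapsat.fixtures import table1_fixture
        summary = summarize_panel(table1_fixture())
        assert round(summary.mean_na, 1) == 7.4
        assert round(summary.mean_he, 3) == 0.689
        assert round(summary.mean_ho, 3) == 0.599
        assert summary.n_in_hwe == 18

    def test_single_locus_means(self):
        table = _table([(1, 2), (1, 1), (2, 2)])
        summary = summarize_panel(table, seed=0)
        locus = summary.loci[0]
        assert summary.mean_he == locus.h_exp
        assert summary.mean_ho == locus.h_obs
        assert summary.mean_na == locus.n_alleles

    def test_alpha_one_counts_only_p_equal_one(self):
        from mapsat.fixtures import table1_fixture
        df = table1_fixture()
        summary = summarize_panel(df, alpha=1.0)
        assert summary.n_in_hwe == int((df["p_hwe"] == 1.0).sum())

    def test_empty_table_raises(self):
        import pandas as pd
        with pytest.raises(ValueError):
            summarize_panel(pd.DataFrame())

    def test_missing_excluded_locus_wise(self):
        records = [
            ("s1", "L1", 1, 2), ("s2", "L1", None, None), ("s3", "L1", 1, 1),
            ("s1", "L2", 5, 5), ("s2", "L2", 5, 6), ("s3", "L2", 6, 6),
        ]
        table = GenotypeTable.from_records(records)
        summary = summarize_panel(table, seed=0)
        assert [l.n for l in summary.loci] == [2, 3]
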