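"""Test statistics, P-values and log-space -log10 P numerics."""

import math
from fractions import Fraction

import mpmath as mp
import numpy as np
import pytest
from scipy.stats import chi2_contingency

from dpgwas.tables import AlleleTable, GenotypeTable, build_genotype_table, to_allele_table
from dpgwas.teststats import (
    TestKind,
    catt,
    chi2_allele,
    chi2_genotype,
    chi2_survival,
    fisher_neg_log10_p,
    fisher_point_p_allele,
    fisher_point_p_genotype,
    neg_log10_p_from_chi2,
    run_test,
)

from conftest import random_genotype_tables

mp.mp.dps = 50


class TestChiSquare:
    def test_identical_columns_give_zero(self):
        gt = build_genotype_table((1, 1, 2), (1, 1, 2))
        assert chi2_genotype(gt) == 0.0

    def test_hand_computed_3x2(self):
        # expected cells are (1, 1, 2) per column
        gt = build_genotype_table((2, 1, 1), (0, 1, 3))
        assert chi2_genotype(gt) == pytest.approx(3.0, abs=1e-12)

    def test_matches_generic_pearson_3x2(self):
        rng = np.random.default_rng(10)
        for gt in random_genotype_tables(rng, 300, 40):
            ref = chi2_contingency(np.array(gt.cells()), correction=False).statistic
            assert chi2_genotype(gt) == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("a, m, N, expected", [
        (50, 100, 100, 0.0),
        (60, 100, 100, 8.0),          # 200 * 20^2 / (100 * 100)
        (100, 100, 100, 200.0),       # 2N at the extreme corner (a, m) = (N, N)
    ])
    def test_2x2_closed_form_values(self, a, m, N, expected):
        assert chi2_allele(AlleleTable(a=a, m=m, N=N)) == pytest.approx(expected, abs=1e-12)

    def test_matches_generic_pearson_2x2(self):
        rng = np.random.default_rng(11)
        for gt in random_genotype_tables(rng, 300, 40):
            at = to_allele_table(gt)
            ref = chi2_contingency(np.array(at.cells()), correction=False).statistic
            assert chi2_allele(at) == pytest.approx(ref, abs=1e-10)


class TestTrendTest:
    def test_balanced_rows_give_zero(self):
        gt = GenotypeTable(a=5, b=10, m=10, n=20, N=100)
        assert catt(gt) == 0.0

    @pytest.mark.parametrize("abmn, expected", [
        ((1, 0, 2, 49), Fraction(240100, 2891)),
        ((0, 0, 1, 49), Fraction(260100, 2699)),
    ])
    def test_exact_fraction_values(self, abmn, expected):
        a, b, m, n = abmn
        gt = GenotypeTable(a=a, b=b, m=m, n=n, N=100)
        assert catt(gt) == pytest.approx(float(expected), rel=1e-14)

    def test_matches_score_test_form(self):
        """Independent oracle: the standard trend score statistic with
        dosage scores (0, 1, 2)."""
        def score_form(gt):
            s = np.array([0.0, 1.0, 2.0])
            cells = np.array(gt.cells(), dtype=float)
            n_g = cells.sum(axis=1)
            r_g = cells[:, 0]                     # first status column
            N, R = gt.N, gt.N / 2.0
            num = float(s @ (r_g - n_g * R / N)) ** 2
            var = (R / N) * (1 - R / N) * (float(s**2 @ n_g) - float(s @ n_g) ** 2 / N)
            return num / var

        rng = np.random.default_rng(12)
        for gt in random_genotype_tables(rng, 200, 60):
            assert catt(gt) == pytest.approx(score_form(gt), rel=1e-10)


class TestSurvivalAndLog10:
    def test_survival_anchors(self):
        assert chi2_survival(0.0, 1) == pytest.approx(1.0)
        assert chi2_survival(33.62, 2) == pytest.approx(5.0e-8, rel=2e-3)
        assert chi2_survival(8.0, 1) == pytest.approx(0.004678, abs=1e-6)

    def test_survival_monotone_neg_log10_increasing(self):
        x = np.linspace(0.0, 60.0, 200)
        for df in (1, 2):
            p = chi2_survival(x, df)
            assert np.all(np.diff(p) < 0)
            nlp = neg_log10_p_from_chi2(x, df)
            assert np.all(np.diff(nlp) > 0)

    def test_neg_log10_anchors(self):
        assert neg_log10_p_from_chi2(0.0, 2) == 0.0
        assert neg_log10_p_from_chi2(33.62, 2) == pytest.approx(7.30, abs=5e-3)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi2_survival(-1.0, 1)
        with pytest.raises(ValueError):
            neg_log10_p_from_chi2(-0.5, 2)

    def test_df1_log_space_no_underflow(self):
        """x = 3000 underflows any double-precision survival value; the
        log-space route must still match a 50-digit reference."""
        ref = float(-mp.log10(mp.erfc(mp.sqrt(mp.mpf(3000) / 2))))
        val = neg_log10_p_from_chi2(3000.0, 1)
        assert math.isfinite(val)
        assert val == pytest.approx(ref, rel=1e-10)

    def test_agrees_with_high_precision_reference(self):
        rng = np.random.default_rng(13)
        xs = rng.uniform(0.01, 5000.0, 100)
        for x in xs:
            ref1 = float(-mp.log10(mp.erfc(mp.sqrt(mp.mpf(x) / 2))))
            ref2 = float(mp.mpf(x) / 2 * mp.log10(mp.e))
            assert neg_log10_p_from_chi2(float(x), 1) == pytest.approx(ref1, rel=1e-8)
            assert neg_log10_p_from_chi2(float(x), 2) == pytest.approx(ref2, rel=1e-12)


class TestFisherPointProbability:
    def test_small_table_exact_fraction(self):
        at = AlleleTable(a=2, m=5, N=5)
        assert fisher_point_p_allele(at) == pytest.approx(100 / 252, rel=1e-12)
        assert fisher_neg_log10_p(at) == pytest.approx(-math.log10(100 / 252), rel=1e-12)

    def test_hypergeometric_normalization(self):
        N = 30
        for m in (3, 7, 30, 45):
            total = sum(fisher_point_p_allele(AlleleTable(a=a, m=m, N=N))
                        for a in range(max(0, m - N), min(m, N) + 1))
            assert total == pytest.approx(1.0, rel=1e-10)

    def test_worst_neighbor_gap_matches_closed_form(self):
        N = 100
        gap = abs(fisher_point_p_allele(AlleleTable(a=4, m=5, N=N))
                  - fisher_point_p_allele(AlleleTable(a=2, m=3, N=N)))
        assert gap == pytest.approx(0.222241, abs=1e-6)
        assert gap == pytest.approx(N * (7 * N - 3) / (8 * (2 * N - 1) * (2 * N - 3)),
                                    rel=1e-10)

    def test_3x2_point_probability_exact(self):
        gt = build_genotype_table((1, 1, 0), (0, 1, 1))
        assert fisher_point_p_genotype(gt) == pytest.approx(1 / 3, rel=1e-12)

    def test_3x2_normalization_over_fixed_margins(self):
        N, m, n = 20, 6, 9
        half = N // 2
        total = 0.0
        for a in range(0, m + 1):
            for b in range(0, n + 1):
                if a + b <= half and m + n - a - b <= half:
                    total += fisher_point_p_genotype(
                        GenotypeTable(a=a, b=b, m=m, n=n, N=N))
        assert total == pytest.approx(1.0, rel=1e-10)

    def test_column_swap_invariance(self):
        rng = np.random.default_rng(14)
        for gt in random_genotype_tables(rng, 100, 24):
            swapped = GenotypeTable(a=gt.m - gt.a, b=gt.n - gt.b,
                                    m=gt.m, n=gt.n, N=gt.N)
            assert fisher_point_p_genotype(gt) == pytest.approx(
                fisher_point_p_genotype(swapped), rel=1e-12)
            at = to_allele_table(gt)
            at_swapped = AlleleTable(a=at.m - at.a, m=at.m, N=at.N)
            assert fisher_point_p_allele(at) == pytest.approx(
                fisher_point_p_allele(at_swapped), rel=1e-12)

    def test_neg_log10_consistent_with_point_p(self):
        rng = np.random.default_rng(15)
        for gt in random_genotype_tables(rng, 100, 50):
            p = fisher_point_p_genotype(gt)
            assert fisher_neg_log10_p(gt) == pytest.approx(-math.log10(p), abs=1e-12)

    def test_agrees_with_high_precision_reference(self):
        rng = np.random.default_rng(16)
        for gt in random_genotype_tables(rng, 30, 80):
            at = to_allele_table(gt)
            ref = -mp.log10(mp.binomial(at.N, at.a) * mp.binomial(at.N, at.m - at.a)
                            / mp.binomial(2 * at.N, at.m))
            assert fisher_neg_log10_p(at) == pytest.approx(float(ref), rel=1e-8)


class TestRunTest:
    def test_consistent_fields(self):
        gt = build_genotype_table((20, 20, 10), (10, 20, 20))
        for kind in TestKind:
            res = run_test(gt, kind)
            assert 0.0 <= res.p <= 1.0
            if res.p > 0:
                assert res.neg_log10_p == pytest.approx(-math.log10(res.p), abs=1e-9)
            if res.statistic is not None:
                assert res.statistic >= 0.0

    def test_catt_df_flag(self):
        gt = build_genotype_table((20, 20, 10), (10, 20, 20))
        r2 = run_test(gt, TestKind.CATT)            # df = 2 default
        r1 = run_test(gt, TestKind.CATT, catt_df=1)
        assert r2.df == 2 and r1.df == 1
        assert r1.p < r2.p                          # same statistic, lighter tail
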