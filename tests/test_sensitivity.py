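"""Closed-form sensitivities and the brute-force enumeration oracle."""

import math

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from dpgwas.sensitivity import (
    brute_force_sensitivity,
    closed_form_sensitivity,
    log10p_bound_2x2,
    pvalue_sensitivity_integral_2x2,
    sensitivity_spec,
)
from dpgwas.teststats import ReleasedForm, TestKind, neg_log10_p_from_chi2

LOG10E = math.log10(math.e)


class TestClosedForms:
    @pytest.mark.parametrize("test, form, N, expected", [
        ("chi2_3x2", "statistic", 100, 400 / 102),
        ("chi2_3x2", "neg_log10_p", 100, LOG10E * 200 / 102),
        ("chi2_2x2", "statistic", 100, 800 / 102),
        ("fisher_2x2", "p_value", 100, 100 * 697 / (8 * 199 * 197)),
        ("fisher_2x2", "neg_log10_p", 100, math.log10(101 * 102 / 2)),
        ("fisher_3x2", "neg_log10_p", 100, math.log10(51)),
        ("catt", "statistic", 100, 16966400 / 1273928),
    ])
    def test_values(self, test, form, N, expected):
        assert closed_form_sensitivity(test, form, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("test, form", [
        ("chi2_3x2", "p_value"),
        ("catt", "p_value"),
        ("fisher_3x2", "p_value"),
        ("fisher_2x2", "statistic"),
        ("fisher_3x2", "statistic"),
    ])
    def test_unsupported_pairs_rejected(self, test, form):
        with pytest.raises(ValueError, match="not supported"):
            closed_form_sensitivity(test, form, 1000)

    def test_odd_or_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            closed_form_sensitivity("chi2_2x2", "statistic", 101)
        with pytest.raises(ValueError):
            closed_form_sensitivity("chi2_2x2", "statistic", 2)

    def test_log10_forms_are_half_log10e_times_statistic_forms(self):
        """The 2-df tests map statistic to -log10 P linearly (slope
        log10(e)/2), so the sensitivities must be exactly proportional."""
        for N in (100, 1000, 10**6):
            for test in (TestKind.CHI2_3X2, TestKind.CATT):
                stat = closed_form_sensitivity(test, "statistic", N)
                nlp = closed_form_sensitivity(test, "neg_log10_p", N)
                assert nlp == pytest.approx(LOG10E / 2 * stat, rel=1e-14)

    def test_large_n_limits(self):
        N = 10**9
        assert closed_form_sensitivity("chi2_2x2", "statistic", N) == pytest.approx(8, abs=1e-4)
        assert closed_form_sensitivity("catt", "statistic", N) == pytest.approx(16, abs=1e-4)
        assert closed_form_sensitivity("chi2_3x2", "neg_log10_p", N) == pytest.approx(
            2 * LOG10E, abs=1e-4)
        assert closed_form_sensitivity("catt", "neg_log10_p", N) == pytest.approx(
            8 * LOG10E, abs=1e-4)
        assert pvalue_sensitivity_integral_2x2(N) == pytest.approx(
            chi2_dist.cdf(1.0, 1), abs=1e-4)

    def test_spec_provenance(self):
        spec = sensitivity_spec("fisher_2x2", "neg_log10_p", 100)
        assert spec.delta > 0
        assert "exact-test" in spec.source
        assert spec.form is ReleasedForm.NEG_LOG10_P


class TestPvalueIntegral:
    def test_equals_chi2_cdf_identity(self):
        for N in (10, 100, 10**4, 10**8):
            assert pvalue_sensitivity_integral_2x2(N) == pytest.approx(
                chi2_dist.cdf(N / (N - 2), 1), abs=1e-10)

    def test_decreasing_in_n_and_bounded(self):
        ns = [10, 20, 50, 100, 1000, 10**6]
        vals = [pvalue_sensitivity_integral_2x2(n) for n in ns]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.68 < v < 1.0 for v in vals)


class TestLog10PBound:
    def test_computed_bound_below_released_constant(self):
        computed, released = log10p_bound_2x2()
        assert released == 2.33
        assert computed == pytest.approx(2.3299, abs=5e-4)
        assert computed < released

    def test_gap_decreasing_in_x(self):
        x = np.linspace(0.0, 50.0, 101)
        gap = neg_log10_p_from_chi2(x + 8.0, 1) - neg_log10_p_from_chi2(x, 1)
        assert np.all(np.diff(gap) < 0)


class TestBruteForceOracle:
    """Exhaustive certification at N=100 (2x2 lattices are small; the 3x2
    scans are exercised at N=100 in the acceptance suite and at a smaller
    N here to keep the unit run fast)."""

    @pytest.mark.parametrize("test, form", [
        ("chi2_2x2", "statistic"),
        ("chi2_2x2", "p_value"),
        ("fisher_2x2", "p_value"),
        ("fisher_2x2", "neg_log10_p"),
    ])
    def test_2x2_proof_moves_match_closed_forms(self, test, form):
        res = brute_force_sensitivity(test, form, 100)
        closed = closed_form_sensitivity(test, form, 100)
        assert res.proof_max == pytest.approx(closed, abs=1e-9)
        assert res.all_max <= closed + 1e-9

    def test_2x2_neg_log10_p_stays_below_constant_bound(self):
        res = brute_force_sensitivity("chi2_2x2", "neg_log10_p", 100)
        computed, released = log10p_bound_2x2()
        assert res.all_max < computed < released

    def test_3x2_scan_at_reduced_n(self):
        res = brute_force_sensitivity("catt", "statistic", 40)
        assert 0 < res.proof_max <= res.all_max
        assert res.all_max <= closed_form_sensitivity("catt", "statistic", 40) + 1e-9

    def test_argmax_pairs_are_neighbors(self):
        res = brute_force_sensitivity("fisher_2x2", "p_value", 60)
        (a1, m1), (a2, m2) = res.proof_argmax
        assert (a1 - a2, m1 - m2) == (2, 2)

    def test_enumeration_guards(self):
        with pytest.raises(ValueError, match="capped"):
            brute_force_sensitivity("chi2_2x2", "statistic", 300)
        with pytest.raises(ValueError, match="capped"):
            brute_force_sensitivity("catt", "statistic", 200)
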