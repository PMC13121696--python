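"""Formula-level checks of the core statistics against closed forms and
independent SciPy oracles."""

import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from crushkit.stats_core import (
    ContingencyTable2x2,
    SummaryStats2,
    chi_square_2x2,
    fisher_exact_2x2,
    median_iqr,
    sidak_adjust,
    welch_t,
)


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        r = welch_t(SummaryStats2(5.0, 1.0, 10, 5.0, 1.0, 10))
        assert r.statistic == 0.0
        assert r.p == pytest.approx(1.0)

    def test_porphyrin_summary_reproduces_published_p(self):
        # 48 h porphyrin/creatinine excretion: 52.6 +/- 31.3 (n=9 vehicle)
        # vs 110.4 +/- 96.4 (n=21 cilastatin), dispersion read as SD
        r = welch_t(SummaryStats2(52.6, 31.3, 9, 110.4, 96.4, 21))
        assert abs(r.statistic) == pytest.approx(2.46, abs=0.01)
        assert r.df == pytest.approx(27.0, abs=0.5)
        assert round(r.p, 2) == 0.02

    def test_equal_variance_equal_n_matches_pooled_t(self):
        s = SummaryStats2(3.0, 2.0, 12, 4.5, 2.0, 12)
        r = welch_t(s)
        t_p, p_p = sps.ttest_ind_from_stats(
            3.0, 2.0, 12, 4.5, 2.0, 12, equal_var=True
        )
        assert r.statistic == pytest.approx(t_p, rel=1e-12)
        assert r.p == pytest.approx(p_p, rel=1e-12)

    def test_p_symmetric_under_group_swap(self):
        a = welch_t(SummaryStats2(1.0, 2.0, 8, 3.0, 5.0, 15))
        b = welch_t(SummaryStats2(3.0, 5.0, 15, 1.0, 2.0, 8))
        assert a.p == pytest.approx(b.p, rel=1e-12)
        assert a.statistic == pytest.approx(-b.statistic, rel=1e-12)

    def test_matches_scipy_welch_oracle(self, rng):
        for _ in range(25):
            m1, m2 = rng.normal(0, 5, 2)
            s1, s2 = rng.uniform(0.5, 4, 2)
            n1, n2 = rng.integers(3, 40, 2)
            r = welch_t(SummaryStats2(m1, s1, int(n1), m2, s2, int(n2)))
            t_o, p_o = sps.ttest_ind_from_stats(
                m1, s1, n1, m2, s2, n2, equal_var=False
            )
            assert r.statistic == pytest.approx(t_o, rel=1e-10)
            assert r.p == pytest.approx(p_o, rel=1e-10)

    def test_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t(SummaryStats2(1.0, 0.0, 5, 2.0, 0.0, 5))

    def test_type_one_error_calibration(self, rng):
        """Under H0 with unequal variances and unequal n, the Welch test
        rejects at ~alpha; rate within the exact binomial 99% interval."""
        reps, alpha = 5000, 0.05
        rejections = 0
        n1, n2 = 15, 25
        x = rng.normal(0, 1, (reps, n1))
        y = rng.normal(0, 3, (reps, n2))
        for i in range(reps):
            r = welch_t(
                SummaryStats2(
                    x[i].mean(), x[i].std(ddof=1), n1,
                    y[i].mean(), y[i].std(ddof=1), n2,
                )
            )
            rejections += r.p < alpha
        lo = sps.binom.ppf(0.005, reps, alpha)
        hi = sps.binom.ppf(0.995, reps, alpha)
        assert lo <= rejections <= hi


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_reconstructed_recovery_table(self):
        # 12/21 vs 1/9 rapid recovery
        p = fisher_exact_2x2(ContingencyTable2x2(12, 9, 1, 8))
        assert p == pytest.approx(0.0417, abs=1e-4)

    def test_extreme_table_two_tables_only(self):
        p = fisher_exact_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert p == pytest.approx(2.0 / math.comb(20, 10), rel=1e-12)

    def test_zero_margin_returns_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 5, 0, 7)) == 1.0

    def test_matches_scipy_oracle(self, rng):
        for _ in range(40):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, 4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            mine = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            _, theirs = sps.fisher_exact([[a, b], [c, d]])
            assert mine == pytest.approx(theirs, rel=1e-9)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(1, 12),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_enumeration_probabilities_sum_to_one(self, a, b, c, d):
        from crushkit.stats_core import _hypergeom_numerators

        t = ContingencyTable2x2(a, b, c, d)
        r1, r2 = t.row_margins
        c1, _ = t.col_margins
        _, nums = _hypergeom_numerators(r1, r2, c1)
        assert sum(nums) == math.comb(t.total, c1)


class TestChiSquare:
    def test_symmetric_table_statistic_zero(self):
        r = chi_square_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert r.statistic == 0.0
        assert r.p == pytest.approx(1.0)

    def test_recovery_table_closed_form(self):
        r = chi_square_2x2(ContingencyTable2x2(12, 9, 1, 8))
        expected = 30 * (12 * 8 - 9 * 1) ** 2 / (21 * 9 * 13 * 17)
        assert r.statistic == pytest.approx(expected, rel=1e-12)
        assert r.statistic == pytest.approx(5.44, abs=0.01)

    def test_doubling_cells_doubles_statistic(self):
        r1 = chi_square_2x2(ContingencyTable2x2(6, 3, 2, 9))
        r2 = chi_square_2x2(ContingencyTable2x2(12, 6, 4, 18))
        assert r2.statistic == pytest.approx(2 * r1.statistic, rel=1e-12)

    def test_yates_never_exceeds_uncorrected(self, rng):
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(1, 20, 4))
            t = ContingencyTable2x2(a, b, c, d)
            assert chi_square_2x2(t, yates=True).statistic <= chi_square_2x2(t).statistic

    def test_matches_scipy_oracle(self):
        t = ContingencyTable2x2(12, 9, 1, 8)
        stat, p, _, _ = sps.chi2_contingency([[12, 9], [1, 8]], correction=False)
        r = chi_square_2x2(t)
        assert r.statistic == pytest.approx(stat, rel=1e-12)
        assert r.p == pytest.approx(p, rel=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 3, 4))


class TestSidak:
    def test_single_comparison_is_identity(self):
        assert sidak_adjust(0.037, 1) == pytest.approx(0.037)

    def test_worked_value(self):
        assert sidak_adjust(0.01, 7) == pytest.approx(1 - 0.99**7, rel=1e-12)
        assert sidak_adjust(0.01, 7) == pytest.approx(0.0679, abs=1e-4)

    def test_endpoints(self):
        assert sidak_adjust(0.0, 5) == 0.0
        assert sidak_adjust(1.0, 5) == 1.0

    @given(
        p1=st.floats(0, 1), p2=st.floats(0, 1),
        m1=st.integers(1, 50), m2=st.integers(1, 50),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_monotone_in_p_and_m(self, p1, p2, m1, m2):
        lo_p, hi_p = sorted((p1, p2))
        lo_m, hi_m = sorted((m1, m2))
        assert sidak_adjust(lo_p, lo_m) <= sidak_adjust(hi_p, lo_m)
        assert sidak_adjust(lo_p, lo_m) <= sidak_adjust(lo_p, hi_m)

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(0.5, 0)


class TestMedianIqr:
    def test_one_to_nine(self):
        assert median_iqr(range(1, 10)) == (5.0, 3.0, 7.0)

    def test_constant_vector(self):
        assert median_iqr([2.5] * 6) == (2.5, 2.5, 2.5)

    def test_permutation_invariant(self, rng):
        x = rng.normal(size=31)
        assert median_iqr(x) == median_iqr(rng.permutation(x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])
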