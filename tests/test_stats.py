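"""Exact tests, t test, Kaplan-Meier and log-rank, against independent oracles."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given
from hypothesis import strategies as st

from larcscore.stats import (ContingencyTable, crosstab, event_free_proportion,
                             fisher_exact, km_estimate, logrank_test,
                             survival_at, t_test_independent)

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


def table2x2(a, b, c, d):
    return ContingencyTable.from_array([[a, b], [c, d]], ["r1", "r2"],
                                       ["c1", "c2"])


def oracle_fisher_2x2(a, b, c, d):
    """Two-sided Fisher p straight from the hypergeometric pmf.

    Independent of the implementation under test: conditions on the
    margins and sums pmf values no larger than the observed one.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    ks = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = ss.hypergeom.pmf(ks, n, c1, r1)
    p_obs = ss.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestCrosstab:
    def test_direct_count(self):
        t = crosstab(["pCR", "pCR", "non"], ["low", "low", "high"],
                     row_order=["pCR", "non"], col_order=["low", "high"])
        assert t.to_array().tolist() == [[2, 0], [0, 1]]

    def test_missing_entries_dropped_pairwise(self):
        t = crosstab(["a", None, "a"], ["x", "x", None])
        assert t.total == 1

    def test_length_mismatch_and_empty_errors(self):
        with pytest.raises(ValueError):
            crosstab(["a"], ["x", "y"])
        with pytest.raises(ValueError):
            crosstab([None], ["x"])


class TestFisherExact:
    def test_modal_symmetric_table_gives_p_one(self):
        res = fisher_exact(table2x2(2, 2, 2, 2))
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_extremes_only(self):
        res = fisher_exact(table2x2(5, 0, 0, 5))
        assert res.p_value == pytest.approx(2 / 252)
        assert res.n_tables_enumerated == 6

    def test_p_at_least_observed_probability(self):
        res = fisher_exact(table2x2(3, 1, 2, 4))
        assert res.p_value >= res.observed_table_prob

    def test_all_2x2_tables_up_to_n12_match_hypergeometric_oracle(self):
        checked = 0
        for a, b, c, d in itertools.product(range(13), repeat=4):
            if not 0 < a + b + c + d <= 12:
                continue
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            got = fisher_exact(table2x2(a, b, c, d)).p_value
            assert got == pytest.approx(oracle_fisher_2x2(a, b, c, d),
                                        rel=1e-9), (a, b, c, d)
            checked += 1
        assert checked > 1000

    @pytest.mark.parametrize("table", [
        [[4, 9], [12, 1]], [[3, 7], [6, 2]], [[1, 5], [4, 4]]])
    def test_2x2_agrees_with_scipy(self, table):
        (a, b), (c, d) = table
        assert fisher_exact(table2x2(a, b, c, d)).p_value == pytest.approx(
            ss.fisher_exact(table)[1], rel=1e-9)

    def test_freeman_halton_2x3_full_enumeration(self):
        t = ContingencyTable.from_array([[4, 9, 9], [12, 1, 0]],
                                        ["non-pCR", "pCR"],
                                        ["low", "int", "high"])
        res = fisher_exact(t)
        assert res.p_value < 1e-4
        assert res.n_tables_enumerated > 10

    def test_zero_third_column_reduces_to_2x2(self):
        t3 = ContingencyTable.from_array([[4, 9, 0], [12, 1, 0]],
                                         ["a", "b"], ["x", "y", "z"])
        t2 = table2x2(4, 9, 12, 1)
        assert fisher_exact(t3).p_value == pytest.approx(
            fisher_exact(t2).p_value, rel=1e-12)

    @given(cells=st.lists(st.integers(0, 8), min_size=6, max_size=6))
    def test_invariant_to_row_swap_and_column_permutation(self, cells):
        arr = np.array(cells).reshape(2, 3)
        if min(arr.sum(axis=1)) == 0:
            return
        base = fisher_exact(ContingencyTable.from_array(
            arr, ["a", "b"], ["x", "y", "z"])).p_value
        swapped = fisher_exact(ContingencyTable.from_array(
            arr[::-1], ["b", "a"], ["x", "y", "z"])).p_value
        assert swapped == pytest.approx(base, rel=1e-9)
        for perm in itertools.permutations(range(3)):
            permuted = fisher_exact(ContingencyTable.from_array(
                arr[:, perm], ["a", "b"], ["x", "y", "z"])).p_value
            assert permuted == pytest.approx(base, rel=1e-9)

    def test_zero_row_margin_is_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="zero row margin"):
            res = fisher_exact(ContingencyTable.from_array(
                [[0, 0], [3, 4]], ["a", "b"], ["x", "y"]))
        assert res.p_value == 1.0

    def test_large_tables_unsupported(self):
        with pytest.raises(ValueError, match="unsupported"):
            fisher_exact(ContingencyTable.from_array(
                np.ones((3, 3), dtype=int), list("abc"), list("xyz")))


class TestWelchT:
    def test_identical_samples(self):
        t, df, p = t_test_independent([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_p_decreases_with_shift(self):
        x = [1.0, 2.0, 3.0]
        ps = [t_test_independent(x, [v + s for v in x])[2]
              for s in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_zero_variance_unequal_means_is_an_error(self):
        with pytest.raises(ValueError):
            t_test_independent([0.0, 0.0], [1.0, 1.0])

    def test_matches_scipy_welch(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        t, df, p = t_test_independent(x, y)
        ref = ss.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_too_small_samples_error(self):
        with pytest.raises(ValueError):
            t_test_independent([1.0], [1.0, 2.0])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        c = km_estimate([1, 2, 3], [1, 1, 1])
        assert c.survival == pytest.approx((1.0, 2 / 3, 1 / 3, 0.0))
        assert c.at_risk == (3, 3, 2, 1)

    def test_all_censored_stays_at_one(self):
        c = km_estimate([5, 7, 9], [0, 0, 0])
        assert c.survival == (1.0,)
        assert c.n_censored == 3

    def test_event_precedes_censoring_at_tied_time(self):
        c = km_estimate([1, 1], [1, 0])
        assert survival_at(c, 1) == pytest.approx(0.5)

    @given(st.lists(st.floats(0.1, 50), min_size=1, max_size=40))
    def test_no_censoring_matches_one_minus_ecdf(self, times):
        c = km_estimate(times, [1] * len(times))
        arr = np.asarray(times)
        for t, s in zip(c.times, c.survival):
            assert s == pytest.approx(np.mean(arr > t), abs=1e-12)

    def test_matches_lifelines_with_censoring(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(10, 60).round(2)
        e = rng.integers(0, 2, 60)
        c = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for ti, si in zip(c.times, c.survival):
            assert si == pytest.approx(
                float(kmf.survival_function_at_times(ti).iloc[0]), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestEventFreeProportion:
    def test_no_events_is_one(self):
        assert event_free_proportion([3, 4], [0, 0], 10) == 1.0

    def test_equals_empirical_without_censoring(self):
        t = list(range(1, 10))
        e = [1, 1, 1, 1, 0, 0, 0, 0, 0]
        # 4 events among 9 subjects, censoring only after the last event
        assert event_free_proportion(t, e, 100) == pytest.approx(5 / 9)

    def test_horizon_zero_is_one(self):
        assert event_free_proportion([1], [1], 0) == 1.0


class TestLogrank:
    def test_identical_groups_give_zero_chi2(self):
        g = ([1, 2, 3, 4], [1, 0, 1, 0])
        chi2, df, p = logrank_test([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_groups_have_two_degrees_of_freedom(self):
        groups = [([1, 2], [1, 1]), ([3, 4], [1, 0]), ([5, 6], [0, 0])]
        _, df, _ = logrank_test(groups)
        assert df == 2

    def test_separated_groups_detected(self):
        chi2, _, p = logrank_test([([1, 1, 1], [1, 1, 1]),
                                   ([2, 2, 2], [0, 0, 0])])
        assert chi2 > 0
        assert p < 1

    def test_invariant_to_group_relabeling(self):
        a = ([1, 3, 5, 9], [1, 1, 0, 1])
        b = ([2, 4, 6, 8], [0, 1, 1, 0])
        assert logrank_test([a, b])[0] == pytest.approx(
            logrank_test([b, a])[0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1], [1]), ([], [])])

    def test_matches_lifelines_multivariate_logrank(self):
        rng = np.random.default_rng(7)
        t = np.concatenate([rng.exponential(5, 30), rng.exponential(12, 30),
                            rng.exponential(20, 30)]).round(2)
        e = rng.integers(0, 2, 90)
        g = np.repeat([0, 1, 2], 30)
        chi2, df, p = logrank_test([(t[g == i], e[g == i]) for i in range(3)])
        ref = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-8)
        assert p == pytest.approx(ref.p_value, rel=1e-8)
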