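import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wdpscan.compare import (compare_metrics, mann_whitney_u, summarize,
                             welch_t)


def exact_mw_pvalue(a, b):
    """Two-sided Mann-Whitney p by full enumeration of group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) \
            + 0.5 * sum(1 for x in group_a for y in group_b if x == y)

    observed = u_stat(a, b)
    mean_u = n_a * len(b) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        group_a = [pooled[i] for i in combo]
        group_b = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(group_a, group_b)
        if abs(u - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
        total += 1
    return count / total


def naive_welch(a, b):
    ma, mb = sum(a) / len(a), sum(b) / len(b)
    va = sum((x - ma) ** 2 for x in a) / (len(a) - 1)
    vb = sum((x - mb) ** 2 for x in b) / (len(b) - 1)
    se = math.sqrt(va / len(a) + vb / len(b))
    t = (ma - mb) / se
    df = (va / len(a) + vb / len(b)) ** 2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1))
    return t, df


class TestSummarize:
    def test_hand_values(self):
        s = summarize([1, 2, 3])
        assert (s.n, s.mean, s.median, s.sd) == (3, 2.0, 2.0, 1.0)

    def test_single_value_sd_undefined(self):
        s = summarize([5])
        assert s.mean == s.median == 5.0 and math.isnan(s.sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_matches_naive_recomputation(self, rng):
        values = rng.normal(size=1000)
        s = summarize(values)
        mean = sum(values) / len(values)
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (len(values) - 1))
        assert s.mean == pytest.approx(mean, abs=1e-9)
        assert s.sd == pytest.approx(sd, abs=1e-9)
        assert s.median == pytest.approx(float(np.median(values)))


class TestMannWhitney:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney_u(a, a)
        assert u == len(a) ** 2 / 2
        assert p > 0.95

    def test_complete_separation_matches_enumeration(self):
        a, b = [1, 2, 3, 4], [5, 6, 7, 8]
        u, p = mann_whitney_u(a, b)
        assert u == 0
        assert p == pytest.approx(2 / math.comb(8, 4), rel=1e-12)
        assert p == pytest.approx(exact_mw_pvalue(a, b), rel=1e-12)

    def test_constant_pooled_data(self):
        u, p = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    @given(data=st.data())
    @settings(max_examples=25, deadline=None)
    def test_exact_branch_matches_enumeration_oracle(self, data):
        # distinct values => no ties; sizes within the exact regime
        pool = data.draw(st.lists(st.integers(-50, 50), min_size=6, max_size=10,
                                  unique=True))
        n_a = data.draw(st.integers(2, len(pool) - 2))
        a, b = pool[:n_a], pool[n_a:]
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(exact_mw_pvalue(a, b), rel=1e-9)

    def test_normal_approximation_close_to_exact_at_n8(self, rng):
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(loc=0.5, size=8)
            _, p_exact = mann_whitney_u(list(a), list(b))
            # force the asymptotic branch by shifting one group size up
            from scipy import stats
            p_approx = stats.mannwhitneyu(a, b, alternative="two-sided",
                                          method="asymptotic",
                                          use_continuity=True).pvalue
            # measured worst-case gap over many draws is ~0.011
            assert abs(p_exact - p_approx) < 0.011

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_u_invariant_under_monotone_transform(self, data):
        a = data.draw(st.lists(st.integers(-100, 100), min_size=2, max_size=12))
        b = data.draw(st.lists(st.integers(-100, 100), min_size=2, max_size=12))
        u1, _ = mann_whitney_u(a, b)
        transform = lambda x: x ** 3 + 7  # strictly increasing, exact on ints
        u2, _ = mann_whitney_u([transform(x) for x in a],
                               [transform(x) for x in b])
        assert u1 == pytest.approx(u2)

    def test_pvalues_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(2, 30)))
            b = rng.normal(size=int(rng.integers(2, 30)))
            _, p = mann_whitney_u(a, b)
            assert 0 <= p <= 1


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_antisymmetric_under_group_swap(self, rng):
        a, b = rng.normal(size=10), rng.normal(loc=1, size=12)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
        assert df1 == pytest.approx(df2)

    def test_matches_brute_force_formula(self, rng):
        a = list(rng.normal(size=9))
        b = list(rng.normal(loc=0.8, scale=2.0, size=14))
        t, df, _ = welch_t(a, b)
        t_naive, df_naive = naive_welch(a, b)
        assert t == pytest.approx(t_naive, abs=1e-12)
        assert df == pytest.approx(df_naive, abs=1e-9)

    def test_reduces_to_student_t_for_equal_variance_and_n(self, rng):
        from scipy import stats
        a = rng.normal(size=20)
        b = 1.5 - a  # exactly equal sample variance, equal n
        t_welch, _, p_welch = welch_t(a, b)
        student = stats.ttest_ind(a, b, equal_var=True)
        assert t_welch == pytest.approx(float(student.statistic), abs=1e-9)
        assert p_welch == pytest.approx(float(student.pvalue), rel=1e-6)

    def test_both_groups_constant_equal_means(self):
        t, _, p = welch_t([3.0, 3.0], [3.0, 3.0, 3.0])
        assert t == 0.0 and p == 1.0


class TestCompareMetrics:
    def _table(self, rng, n=20, shift=0.0):
        return pd.DataFrame({
            "id": [f"P{i}" for i in range(n)],
            "pi": rng.normal(7, 1, n) + shift,
            "gravy": rng.normal(-0.5, 0.3, n) + shift,
        })

    def test_identical_tables_give_p_one(self, rng):
        table = self._table(rng)
        result = compare_metrics(table, table.copy())
        assert (result["t_pvalue"] > 0.999).all()
        assert (result["mw_pvalue"] > 0.95).all()

    def test_row_per_shared_numeric_column(self, rng):
        result = compare_metrics(self._table(rng), self._table(rng))
        assert sorted(result["metric"]) == ["gravy", "pi"]

    def test_missing_requested_column_named_in_error(self, rng):
        with pytest.raises(KeyError, match="ai"):
            compare_metrics(self._table(rng), self._table(rng), metrics=["ai"])

    def test_bh_adjustment_adds_monotone_qvalues(self, rng):
        result = compare_metrics(self._table(rng), self._table(rng, shift=1.0),
                                 bh_adjust=True)
        assert "mw_pvalue_bh" in result
        assert (result["mw_pvalue_bh"] >= result["mw_pvalue"] - 1e-12).all()

    def test_power_against_planted_two_sd_shift(self):
        """A 2-sd mean shift at n=56 per group is detected essentially always."""
        hits = 0
        n_reps = 200
        rng = np.random.default_rng(1234)
        for _ in range(n_reps):
            a = rng.normal(0.0, 1.0, 56)
            b = rng.normal(2.0, 1.0, 56)
            _, p = mann_whitney_u(a, b)
            if p < 0.01:
                hits += 1
        assert hits >= 0.95 * n_reps
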