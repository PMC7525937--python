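"""Unit and property tests for the rank, contingency and correlation tests.

Every statistic is checked two ways: against hand/enumeration oracles
written from the definitions (independent of the implementation), and
against the corresponding SciPy routine where one exists.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cmfscan.group_stats import (
    fisher_exact_2x2,
    kendall_tau_b,
    kruskal_wallis,
    rank_sum_test,
)


# ---------------------------------------------------------------------------
# oracles (definition-level, no shared code with the implementation)
# ---------------------------------------------------------------------------

def _ranks_by_sorting(values):
    """Midranks computed by explicit sorting, no scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_mw_u(x, y):
    """U statistic by direct pair counting."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def oracle_ranksum_exact_p(x, y):
    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * len(y) / 2.0
    dev = abs(oracle_mw_u(x, y) - mu)
    extreme = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(oracle_mw_u(xs, ys) - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def oracle_kw_h(groups):
    pooled = [v for g in groups for v in g]
    ranks = _ranks_by_sorting(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for g in groups:
        rsum = sum(ranks[idx : idx + len(g)])
        h += rsum**2 / len(g)
        idx += len(g)
    return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)


def oracle_kw_exact_p(groups):
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    h_obs = oracle_kw_h(groups)
    extreme = total = 0
    seen_indices = list(range(len(pooled)))

    def assignments(remaining, sizes_left):
        if len(sizes_left) == 1:
            yield [tuple(remaining)]
            return
        for combo in itertools.combinations(remaining, sizes_left[0]):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, sizes_left[1:]):
                yield [combo] + tail

    for assign in assignments(seen_indices, sizes):
        total += 1
        gs = [[pooled[i] for i in idxs] for idxs in assign]
        if oracle_kw_h(gs) >= h_obs - 1e-12:
            extreme += 1
    return extreme / total


def oracle_fisher_p(table):
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa):
        return (
            math.comb(r1, aa)
            * math.comb(r2, c1 - aa)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(aa) for aa in range(lo, hi + 1) if prob(aa) <= p_obs * (1 + 1e-7))


def oracle_tau_b_direct(x, y):
    """tau-b by explicit O(n^2) pair counting."""
    n = len(x)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = (x[i] > x[j]) - (x[i] < x[j])
            dy = (y[i] > y[j]) - (y[i] < y[j])
            s += dx * dy
    n0 = n * (n - 1) / 2

    def tie_pairs(v):
        from collections import Counter

        return sum(t * (t - 1) // 2 for t in Counter(v).values())

    return s / math.sqrt((n0 - tie_pairs(x)) * (n0 - tie_pairs(y)))


# ---------------------------------------------------------------------------
# frozen examples
# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_rank_sum_example(self):
        res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        # R1=6, R2=15 -> H = 12/42 * (12 + 75) - 21 = 3.857
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings

    def test_fully_tied_data(self):
        res = kruskal_wallis([np.array([5, 5]), np.array([5, 5])])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_statistic_nonnegative_interleaved(self):
        res = kruskal_wallis([np.array([1, 3, 5]), np.array([2, 4, 6])])
        assert res.statistic >= 0.0

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(size=15), rng.normal(0.5, size=12), rng.normal(size=10)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_fewer_than_two_groups_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0, 2.0])])


class TestRankSum:
    def test_symmetric_samples_p_one(self):
        x = np.arange(20.0)
        res = rank_sum_test(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2.0)
        assert res.p_value == 1.0

    def test_exact_separated_example(self):
        res = rank_sum_test(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert res.p_value == pytest.approx(0.1)

    def test_single_swap_matches_enumeration_oracle(self):
        x, y = [1, 2, 4], [3, 5, 6]
        res = rank_sum_test(np.array(x), np.array(y))
        assert res.p_value == pytest.approx(oracle_ranksum_exact_p(x, y))

    def test_matches_scipy_large_sample(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=30)
        y = rng.normal(0.7, size=25)
        res = rank_sum_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[2, 0], [0, 2]], 1.0 / 3.0),
            ([[1, 1], [1, 1]], 1.0),
            ([[10, 0], [0, 10]], 2.0 / math.comb(20, 10)),
        ],
    )
    def test_frozen_examples(self, table, expected):
        assert fisher_exact_2x2(np.array(table)).p_value == pytest.approx(expected)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_2x2(np.array([[0, 0], [1, 1]]))

    def test_odds_ratio_flags(self):
        res = fisher_exact_2x2(np.array([[5, 0], [1, 4]]))
        assert math.isinf(res.statistic)
        assert "infinite" in res.method_details

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            t = rng.integers(1, 12, size=(2, 2))
            mine = fisher_exact_2x2(t).p_value
            ref = sps.fisher_exact(t, alternative="two-sided")[1]
            assert mine == pytest.approx(ref, rel=1e-6)


class TestKendallTau:
    def test_perfect_and_reversed(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert kendall_tau_b(x, x).statistic == pytest.approx(1.0)
        assert kendall_tau_b(x, -x).statistic == pytest.approx(-1.0)

    def test_pair_count_example(self):
        res = kendall_tau_b(np.array([1, 2, 3]), np.array([1, 3, 2]))
        assert res.statistic == pytest.approx(1.0 / 3.0)  # C=2, D=1

    def test_all_tied_errors(self):
        with pytest.raises(ValueError, match="tied"):
            kendall_tau_b(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, size=60).astype(float)
        y = (x + rng.integers(0, 4, size=60)).astype(float)
        res = kendall_tau_b(x, y)
        ref = sps.kendalltau(x, y, variant="b")
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 10, size=25).tolist()
        y = rng.integers(0, 10, size=25).tolist()
        res = kendall_tau_b(np.array(x, float), np.array(y, float))
        assert res.statistic == pytest.approx(oracle_tau_b_direct(x, y), rel=1e-12)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@given(
    st.lists(st.integers(0, 20), min_size=2, max_size=4),
    st.lists(st.integers(0, 20), min_size=2, max_size=4),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_exact_rank_sum_equals_enumeration(x, y):
    """Exact-path p equals brute-force enumeration over all labelings (N <= 8)."""
    if len(set(x + y)) < len(x) + len(y):
        return  # exact path requires no ties
    res = rank_sum_test(np.array(x, float), np.array(y, float))
    assert res.p_value == pytest.approx(oracle_ranksum_exact_p(x, y))


@given(
    st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=3),
    st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=3),
    st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=2),
)
@settings(deadline=None, max_examples=40, derandomize=True)
def test_exact_kruskal_equals_enumeration(a, b, c):
    groups = [a, b, c]
    if all(v == a[0] for g in groups for v in g):
        return
    res = kruskal_wallis([np.array(g) for g in groups])
    assert res.p_value == pytest.approx(oracle_kw_exact_p(groups))


@given(st.integers(1, 8), st.integers(1, 8), st.integers(1, 8), st.integers(1, 8))
@settings(deadline=None, max_examples=80, derandomize=True)
def test_fisher_enumeration_and_transpose_invariance(a, b, c, d):
    t = np.array([[a, b], [c, d]])
    p = fisher_exact_2x2(t).p_value
    assert p == pytest.approx(oracle_fisher_p([[a, b], [c, d]]))
    assert 0.0 <= p <= 1.0
    assert fisher_exact_2x2(t[::-1]).p_value == pytest.approx(p)


@given(
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=10),
    st.lists(st.floats(-50, 50, allow_nan=False), min_size=3, max_size=10),
)
@settings(deadline=None, max_examples=60, derandomize=True)
def test_two_sided_tests_invariant_under_group_relabel(x, y):
    x, y = np.array(x), np.array(y)
    assert rank_sum_test(x, y).p_value == pytest.approx(
        rank_sum_test(y, x).p_value
    )
    assert kruskal_wallis([x, y]).p_value == pytest.approx(
        kruskal_wallis([y, x]).p_value
    )
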