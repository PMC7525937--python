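"""Univariate and contingency statistics for group comparisons.

Each test is implemented from its definition rather than delegated, because
the pipeline's contracts require exact small-sample paths (full permutation
enumeration) alongside the usual asymptotic approximations, and the exact
and asymptotic branches must be reported explicitly.  The test suite
cross-checks every statistic against the corresponding SciPy routine and
against brute-force enumeration oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "kruskal_wallis",
    "rank_sum_test",
    "fisher_exact_2x2",
    "kendall_tau_b",
]

#: pooled sample size at or below which rank tests switch to full enumeration
EXACT_KRUSKAL_N = 8
EXACT_RANKSUM_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    method_details: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "method_details": self.method_details,
        }


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def _group_assignments(sizes: list[int]):
    """Yield all distinct assignments of indices 0..N-1 into groups of the given sizes."""
    n = sum(sizes)

    def rec(remaining: frozenset, k: int):
        if k == len(sizes) - 1:
            yield [tuple(sorted(remaining))]
            return
        for combo in itertools.combinations(sorted(remaining), sizes[k]):
            for rest in rec(remaining - set(combo), k + 1):
                yield [combo] + rest

    yield from rec(frozenset(range(n)), 0)


def _kw_h(ranks: np.ndarray, groups: list[tuple[int, ...]], n: int) -> float:
    h = 0.0
    for idx in groups:
        r = ranks[list(idx)]
        h += r.sum() ** 2 / len(idx)
    return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)


def kruskal_wallis(samples: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis rank test with midrank ties and tie correction.

    The H statistic uses the standard tie correction
    ``H / (1 - sum(t^3 - t) / (N^3 - N))``; p comes from the chi-square
    approximation with g-1 degrees of freedom, replaced by full permutation
    enumeration of group labelings when the pooled sample size is <= 8.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    sizes = [s.size for s in samples]
    n = sum(sizes)
    if n < 3:
        raise ValueError("pooled sample size must be >= 3")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, tuple(sizes), "all values identical"
        )
    ranks = _midranks(pooled)
    bounds = np.cumsum([0] + sizes)
    observed = [tuple(range(bounds[i], bounds[i + 1])) for i in range(len(sizes))]
    h = _kw_h(ranks, observed, n)
    ties = _tie_counts(pooled)
    correction = 1.0 - float(((ties**3 - ties).sum()) / (n**3 - n))
    h_corr = h / correction
    df = len(sizes) - 1
    if n <= EXACT_KRUSKAL_N:
        total = 0
        extreme = 0
        for assignment in _group_assignments(sizes):
            total += 1
            if _kw_h(ranks, assignment, n) >= h - 1e-12:
                extreme += 1
        p = extreme / total
        details = f"exact permutation enumeration over {total} labelings"
    else:
        p = float(sps.chi2.sf(h_corr, df))
        details = f"chi-square approximation, df={df}, tie correction {correction:.6f}"
    return TestResult("kruskal_wallis", float(h_corr), p, tuple(sizes), details)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test with midranks.

    Exact p by enumeration of all rank labelings when the pooled size
    is <= 12 and there are no ties; otherwise the normal approximation
    with tie-corrected variance and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = float(ranks[:nx].sum())
    u = r1 - nx * (nx + 1) / 2.0
    mu = nx * ny / 2.0
    ties = _tie_counts(pooled)
    has_ties = bool((ties > 1).any())
    n = nx + ny
    if not has_ties and n <= EXACT_RANKSUM_N:
        dev = abs(u - mu)
        extreme = 0
        total = 0
        for combo in itertools.combinations(range(n), nx):
            total += 1
            r1p = ranks[list(combo)].sum()
            up = r1p - nx * (nx + 1) / 2.0
            if abs(up - mu) >= dev - 1e-12:
                extreme += 1
        p = extreme / total
        details = f"exact enumeration over {total} labelings"
    else:
        tie_term = float((ties**3 - ties).sum()) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return TestResult(
                "rank_sum", float(u), 1.0, (nx, ny), "degenerate: all values tied"
            )
        z = (abs(u - mu) - 0.5) / math.sqrt(var)
        z = max(z, 0.0)
        p = min(1.0, 2.0 * float(sps.norm.sf(z)))
        details = "normal approximation, tie-corrected variance, continuity correction"
    return TestResult("rank_sum", float(u), p, (nx, ny), details)


def fisher_exact_2x2(table: np.ndarray) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    p is the sum of hypergeometric probabilities, over all tables with the
    observed margins, whose point probability does not exceed the observed
    one (relative tolerance 1e-7 on the comparison) — the point-probability
    ordering convention.  The sample odds ratio is reported as the
    statistic; a zero off-diagonal cell makes it infinite and is flagged.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("fisher_exact_2x2 requires all margins > 0")
    n = int(t.sum())
    dist = sps.hypergeom(n, int(row[0]), int(col[0]))
    support = np.arange(max(0, col[0] - row[1]), min(row[0], col[0]) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(int(t[0, 0]))
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    a, b, c, d = (float(v) for v in t.ravel())
    if b == 0 or c == 0:
        odds = math.inf
        details = "odds ratio infinite (zero off-diagonal cell)"
    elif a == 0 or d == 0:
        odds = 0.0
        details = "odds ratio zero (zero diagonal cell)"
    else:
        odds = (a * d) / (b * c)
        details = "point-probability two-sided convention"
    return TestResult(
        "fisher_exact", odds, p, (int(row[0]), int(row[1])), details
    )


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Kendall's tau-b rank correlation with tie correction.

    Concordant/discordant pairs are counted by vectorized O(n^2) sign
    comparison; tau-b = (C - D) / sqrt((n0 - n1)(n0 - n2)) with the
    standard tie terms, and p comes from the normal approximation on the
    tie-corrected variance of C - D.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise ValueError("kendall_tau_b needs n >= 2")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = float((sx[iu] * sy[iu]).sum())  # C - D
    n0 = n * (n - 1) / 2.0
    tx = _tie_counts(x).astype(float)
    ty = _tie_counts(y).astype(float)
    n1 = float((tx * (tx - 1)).sum()) / 2.0
    n2 = float((ty * (ty - 1)).sum()) / 2.0
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0.0:
        raise ValueError("tau undefined: all x or all y values tied")
    tau = s / denom
    v0 = n * (n - 1) * (2 * n + 5)
    vt = float((tx * (tx - 1) * (2 * tx + 5)).sum())
    vu = float((ty * (ty - 1) * (2 * ty + 5)).sum())
    var_s = (v0 - vt - vu) / 18.0
    if n > 2:
        var_s += (
            float((tx * (tx - 1) * (tx - 2)).sum())
            * float((ty * (ty - 1) * (ty - 2)).sum())
        ) / (9.0 * n * (n - 1) * (n - 2))
    var_s += (
        float((tx * (tx - 1)).sum()) * float((ty * (ty - 1)).sum())
    ) / (2.0 * n * (n - 1))
    if var_s <= 0:
        p = 1.0
    else:
        z = s / math.sqrt(var_s)
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return TestResult(
        "kendall_tau_b", float(tau), p, (n,), "normal approximation on C - D"
    )
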