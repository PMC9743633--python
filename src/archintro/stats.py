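"""Exact and asymptotic tests shared by all pipeline stages.

Every stage reports a :class:`TestResult` so that the method actually used
(exact enumeration vs normal approximation, corrected vs uncorrected) is
recorded next to each p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "chi2_2x2",
    "rank_sum",
    "signed_rank",
    "bonferroni",
]

#: total number of observations at or below which rank tests use exact
#: enumeration of the null distribution (ties force the approximation).
EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is the test statistic on its native scale (odds ratio for
    Fisher, Pearson X^2 for the chi-square test, rank-sum U otherwise).
    ``degenerate`` marks tables/vectors where the test is not informative
    (all-zero table, zero margin); such results carry a conventional or
    undefined p and are excluded from multiple-testing families upstream.
    """

    statistic: float
    p: float
    method: str
    alternative: str
    context: tuple = ()
    degenerate: bool = False


def _check_counts(*counts: int) -> None:
    for x in counts:
        if x < 0 or x != int(x):
            raise ValueError(f"contingency counts must be non-negative integers, got {x!r}")


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities of all tables with the
    same margins whose probability does not exceed that of the observed table
    (the probability-mass rule, as in R's ``fisher.test``). The statistic is
    the sample odds ratio ``(a*d)/(b*c)``.
    """
    _check_counts(a, b, c, d)
    if a + b + c + d == 0:
        return TestResult(float("nan"), 1.0, "fisher-exact", alternative,
                          (a, b, c, d), degenerate=True)
    stat, p = _sps.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return TestResult(float(stat), float(p), "fisher-exact", alternative, (a, b, c, d))


def chi2_2x2(a: int, b: int, c: int, d: int, continuity: bool = True) -> TestResult:
    """Pearson chi-square test of independence on a 2x2 table.

    Uses the closed form ``N (|ad - bc| - corr)^2 / (r1 r2 c1 c2)`` with the
    Yates term ``corr = min(N/2, |ad - bc|)`` when ``continuity`` is set, so
    the corrected statistic never goes negative. Zero row/column margins make
    the test undefined; such tables come back degenerate with p = NaN.
    """
    _check_counts(a, b, c, d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    method = "chi2-yates" if continuity else "chi2-pearson"
    if n == 0 or 0 in (r1, r2, c1, c2):
        return TestResult(float("nan"), float("nan"), method, "two-sided",
                          (a, b, c, d), degenerate=True)
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(_sps.chi2.sf(stat, df=1))
    return TestResult(float(stat), p, method, "two-sided", (a, b, c, d))


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def rank_sum(x: Sequence[float], y: Sequence[float],
             alternative: str = "two-sided",
             exact_max_n: int = EXACT_RANKSUM_MAX_N) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test of ``x`` against ``y``.

    Exact null enumeration when the pooled sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal approximation
    with midranks, tie correction and continuity correction.
    ``alternative='greater'`` tests whether ``x`` tends to exceed ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum requires at least one observation per group")
    exact = (x.size + y.size) <= exact_max_n and not _has_ties(x, y)
    method = "ranksum-exact" if exact else "ranksum-normal"
    res = _sps.mannwhitneyu(x, y, alternative=alternative,
                            method="exact" if exact else "asymptotic",
                            use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), method,
                      alternative, (int(x.size), int(y.size)))


def signed_rank(x: Sequence[float], y: Sequence[float],
                alternative: str = "two-sided") -> TestResult:
    """Paired Wilcoxon signed-rank test on matched vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("signed_rank requires matched non-empty vectors")
    d = x - y
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "signed-rank", alternative,
                          (int(x.size),), degenerate=True)
    res = _sps.wilcoxon(x, y, alternative=alternative, zero_method="wilcox")
    return TestResult(float(res.statistic), float(res.pvalue), "signed-rank",
                      alternative, (int(x.size),))


def bonferroni(ps: Sequence[float], n_tests: int | None = None) -> np.ndarray:
    """Bonferroni-adjust a family of p-values: ``min(1, p * n)``, order kept."""
    ps = np.asarray(ps, dtype=float)
    if ps.size and (np.nanmin(ps) < 0 or np.nanmax(ps) > 1):
        bad = ps[(ps < 0) | (ps > 1)][0]
        raise ValueError(f"p-values must lie in [0, 1], got {bad}")
    n = len(ps) if n_tests is None else int(n_tests)
    return np.minimum(1.0, ps * n)
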