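"""Exact small-sample nonparametric tests.

All null distributions are built exactly: the rank-sum null by dynamic
programming over subset rank sums, the signed-rank null by dynamic
programming over sign assignments of ranks. Two-sided p-values are twice
the smaller tail probability, capped at 1. When ties are present in the
data, midranks are used and the exact tie-free null is replaced by a
seeded Monte-Carlo permutation null.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

MC_PERMUTATIONS = 100_000

RANK_SUM_MAX_N = 15
SIGNED_RANK_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of one exact test, with multiplicity correction applied."""

    __test__ = False  # not a pytest test class

    method: str  # "rank_sum_exact" | "signed_rank_exact" | *_mc variants
    statistic: float
    n1: int
    p_raw: float
    p_corrected: float
    correction_factor: int = 1
    n2: Optional[int] = None
    n_zeros_dropped: int = 0
    tie_fallback: bool = False
    notes: str = ""

    def __post_init__(self):
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of (0, 1]: {self.p_raw}")
        expected = min(1.0, self.correction_factor * self.p_raw)
        if not math.isclose(self.p_corrected, expected, rel_tol=1e-12):
            raise ValueError("p_corrected inconsistent with correction_factor")


def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p_raw)."""
    if m < 1:
        raise ValueError(f"correction factor must be >= 1, got {m}")
    return min(1.0, m * p_raw)


# ---------------------------------------------------------------------------
# Rank-sum (two independent groups)
# ---------------------------------------------------------------------------

def rank_sum_null(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of the size-n1 group's rank sum (no ties).

    Returns (support, pmf) where support covers every attainable rank sum
    from n1(n1+1)/2 to n1(n1+2*n2+1)/2 inclusive. Counts are computed by a
    subset-sum dynamic program over ranks 1..n1+n2 constrained to subsets
    of size n1; masses sum to 1 and are symmetric about n1(n1+n2+1)/2.
    """
    support, pmf = _rank_sum_null_cached(n1, n2)
    return support.copy(), pmf.copy()


@functools.lru_cache(maxsize=256)
def _rank_sum_null_cached(n1: int, n2: int) -> tuple[np.ndarray, np.ndarray]:
    if not (1 <= n1 <= RANK_SUM_MAX_N and 1 <= n2 <= RANK_SUM_MAX_N):
        raise ValueError(
            f"group sizes must be in 1..{RANK_SUM_MAX_N}, got ({n1}, {n2})"
        )
    n = n1 + n2
    max_sum = n1 * (2 * n - n1 + 1) // 2
    # count[k, s] = number of size-k subsets of ranks seen so far with sum s
    count = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    count[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            count[k, rank:] += count[k - 1, : max_sum + 1 - rank]
    min_sum = n1 * (n1 + 1) // 2
    support = np.arange(min_sum, max_sum + 1)
    counts = count[n1, min_sum:]
    return support, counts / counts.sum()


def _two_sided_p(support: np.ndarray, pmf: np.ndarray, w: float) -> float:
    lo = pmf[support <= w + 1e-9].sum()
    hi = pmf[support >= w - 1e-9].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def rank_sum_test(
    x: Optional[Sequence[float]] = None,
    y: Optional[Sequence[float]] = None,
    *,
    statistic: Optional[float] = None,
    n1: Optional[int] = None,
    n2: Optional[int] = None,
    correction_factor: int = 1,
    seed: int = 0,
) -> TestResult:
    """Two-sided exact Wilcoxon rank-sum test.

    Either pass the two samples (x is the group whose rank sum is
    reported) or a precomputed rank-sum ``statistic`` with group sizes.
    Data with ties fall back to a seeded Monte-Carlo permutation null on
    midranks.
    """
    tie_fallback = False
    if statistic is None:
        if x is None or y is None:
            raise ValueError("provide either samples (x, y) or statistic with sizes")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n1, n2 = len(x), len(y)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # midranks
        statistic = float(ranks[:n1].sum())
        tie_fallback = len(np.unique(pooled)) < len(pooled)
    if n1 is None or n2 is None:
        raise ValueError("group sizes required with a precomputed statistic")

    if tie_fallback:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
        ranks = sps.rankdata(pooled)
        perms = rng.permuted(np.tile(ranks, (MC_PERMUTATIONS, 1)), axis=1)
        sums = perms[:, :n1].sum(axis=1)
        lo = np.mean(sums <= statistic + 1e-9)
        hi = np.mean(sums >= statistic - 1e-9)
        p_raw = float(min(1.0, 2.0 * min(lo, hi)))
        p_raw = max(p_raw, 1.0 / MC_PERMUTATIONS)
        method = "rank_sum_mc"
    else:
        support, pmf = rank_sum_null(n1, n2)
        if not (support[0] - 1e-9 <= statistic <= support[-1] + 1e-9):
            raise ValueError(
                f"rank sum {statistic} outside attainable range "
                f"[{support[0]}, {support[-1]}] for sizes ({n1}, {n2})"
            )
        p_raw = _two_sided_p(support, pmf, statistic)
        method = "rank_sum_exact"

    return TestResult(
        method=method,
        statistic=float(statistic),
        n1=n1,
        n2=n2,
        p_raw=p_raw,
        p_corrected=bonferroni(p_raw, correction_factor),
        correction_factor=correction_factor,
        tie_fallback=tie_fallback,
        notes=f"reported rank sum is for the size-{n1} group",
    )


# ---------------------------------------------------------------------------
# Signed-rank (one sample vs 0)
# ---------------------------------------------------------------------------

def signed_rank_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf of the positive-rank sum W+ over 2^n sign patterns."""
    support, pmf = _signed_rank_null_cached(n)
    return support.copy(), pmf.copy()


@functools.lru_cache(maxsize=256)
def _signed_rank_null_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    if not (1 <= n <= SIGNED_RANK_MAX_N):
        raise ValueError(f"n must be in 1..{SIGNED_RANK_MAX_N}, got {n}")
    max_sum = n * (n + 1) // 2
    count = np.zeros(max_sum + 1, dtype=np.float64)
    count[0] = 1.0
    for rank in range(1, n + 1):
        count[rank:] += count[: max_sum + 1 - rank].copy()
    support = np.arange(max_sum + 1)
    return support, count / count.sum()


def signed_rank_test(
    values: Optional[Sequence[float]] = None,
    *,
    statistic: Optional[float] = None,
    n: Optional[int] = None,
    correction_factor: int = 1,
    seed: int = 0,
) -> TestResult:
    """Two-sided exact one-sample Wilcoxon signed-rank test against 0.

    Either pass the sample ``values`` (zeros are dropped, with the count
    reported) or a precomputed positive-rank-sum ``statistic`` with the
    number of non-zero values ``n``. Tied absolute values fall back to a
    seeded Monte-Carlo sign-flip null on midranks.
    """
    n_zeros = 0
    tie_fallback = False
    abs_ranks = None
    if statistic is None:
        if values is None:
            raise ValueError("provide either values or statistic with n")
        v = np.asarray(values, dtype=float)
        n_zeros = int(np.sum(v == 0))
        v = v[v != 0]
        n = len(v)
        if n == 0:
            raise ValueError("no non-zero values remain after dropping zeros")
        abs_ranks = sps.rankdata(np.abs(v))
        statistic = float(abs_ranks[v > 0].sum())
        tie_fallback = len(np.unique(np.abs(v))) < n
    if n is None:
        raise ValueError("n required with a precomputed statistic")

    if tie_fallback:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(MC_PERMUTATIONS, n))
        sums = signs @ abs_ranks
        lo = np.mean(sums <= statistic + 1e-9)
        hi = np.mean(sums >= statistic - 1e-9)
        p_raw = float(min(1.0, 2.0 * min(lo, hi)))
        p_raw = max(p_raw, 1.0 / MC_PERMUTATIONS)
        method = "signed_rank_mc"
    else:
        support, pmf = signed_rank_null(n)
        if not (-1e-9 <= statistic <= support[-1] + 1e-9):
            raise ValueError(
                f"statistic {statistic} outside attainable range "
                f"[0, {support[-1]}] for n={n}"
            )
        p_raw = _two_sided_p(support, pmf, statistic)
        method = "signed_rank_exact"

    return TestResult(
        method=method,
        statistic=float(statistic),
        n1=n,
        p_raw=p_raw,
        p_corrected=bonferroni(p_raw, correction_factor),
        correction_factor=correction_factor,
        n_zeros_dropped=n_zeros,
        tie_fallback=tie_fallback,
    )


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_corr(
    x: Sequence[float],
    y: Sequence[float],
    *,
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Midranks handle ties. For n <= ``exact_max_n`` the p-value is computed
    by full enumeration of the n! permutations of one rank vector;
    otherwise the t-distribution approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = math.sqrt((a * a).sum() * (b * b).sum())
        if denom == 0:
            return 0.0
        return float((a * b).sum() / denom)

    rho = _rho(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rho(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)
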