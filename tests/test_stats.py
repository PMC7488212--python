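"""Exact-test machinery, validated against brute-force enumeration."""

import math
from collections import Counter
from itertools import combinations, permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from confield.stats import (
    TestResult,
    bonferroni,
    rank_sum_null,
    rank_sum_test,
    signed_rank_null,
    signed_rank_test,
    spearman_corr,
)


def brute_rank_sum_null(n1, n2):
    counts = Counter(sum(c) for c in combinations(range(1, n1 + n2 + 1), n1))
    total = math.comb(n1 + n2, n1)
    support = np.array(sorted(counts))
    pmf = np.array([counts[s] / total for s in support])
    return support, pmf


def brute_signed_rank_null(n):
    counts = Counter(
        sum(r for r, s in zip(range(1, n + 1), signs) if s)
        for signs in product([0, 1], repeat=n)
    )
    support = np.arange(n * (n + 1) // 2 + 1)
    pmf = np.array([counts.get(int(s), 0) / 2**n for s in support])
    return support, pmf


class TestRankSumNull:
    def test_minimal_case(self):
        support, pmf = rank_sum_null(1, 1)
        assert support.tolist() == [1, 2]
        assert pmf.tolist() == [0.5, 0.5]

    def test_support_count_8_6(self):
        support, pmf = rank_sum_null(8, 6)
        # all C(14,8) = 3003 subsets equally likely
        counts = pmf * math.comb(14, 8)
        assert np.allclose(counts, np.round(counts))
        assert int(counts.sum()) == 3003

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(1, 7)])
    def test_dp_equals_enumeration(self, n1, n2):
        support, pmf = rank_sum_null(n1, n2)
        b_support, b_pmf = brute_rank_sum_null(n1, n2)
        nonzero = pmf > 0
        assert np.array_equal(support[nonzero], b_support[b_pmf > 0])
        np.testing.assert_allclose(pmf[nonzero], b_pmf[b_pmf > 0], atol=1e-12)

    def test_mass_and_symmetry(self):
        support, pmf = rank_sum_null(8, 6)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(pmf, pmf[::-1], atol=1e-15)

    def test_sizes_out_of_contract(self):
        with pytest.raises(ValueError):
            rank_sum_null(0, 5)
        with pytest.raises(ValueError):
            rank_sum_null(16, 5)


class TestRankSumTest:
    def test_at_null_mean_p_is_one(self):
        res = rank_sum_test(statistic=60, n1=8, n2=6)
        assert res.p_raw == 1.0

    def test_w80_sizes_8_6(self):
        res = rank_sum_test(statistic=80, n1=8, n2=6)
        assert res.p_raw == pytest.approx(24 / 3003, abs=1e-12)

    def test_extreme_point_doubled(self):
        res = rank_sum_test(statistic=84, n1=8, n2=6)
        assert res.p_raw == pytest.approx(2 / 3003, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="attainable"):
            rank_sum_test(statistic=85, n1=8, n2=6)

    def test_from_data_no_ties(self):
        x = [5.0, 7.0, 9.0]
        y = [1.0, 2.0, 3.0]
        res = rank_sum_test(x, y)
        assert res.method == "rank_sum_exact"
        assert res.statistic == 4 + 5 + 6
        assert res.p_raw == pytest.approx(2 * 1 / math.comb(6, 3), abs=1e-12)

    def test_ties_trigger_mc_fallback(self):
        res = rank_sum_test([1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 4.0, 6.0], seed=7)
        assert res.method == "rank_sum_mc"
        assert res.tie_fallback
        # MC p close to the midrank permutation truth; loose sanity band
        assert 0.0 < res.p_raw <= 1.0

    def test_mc_seed_reproducible(self):
        a = rank_sum_test([1.0, 2.0, 2.0], [2.0, 3.0, 4.0], seed=3)
        b = rank_sum_test([1.0, 2.0, 2.0], [2.0, 3.0, 4.0], seed=3)
        assert a.p_raw == b.p_raw

    def test_symmetry_of_p(self):
        # p(W) == p(2*mean - W) in the tie-free case
        mean = 8 * 15 / 2
        for w in (40, 55, 70, 80):
            p1 = rank_sum_test(statistic=w, n1=8, n2=6).p_raw
            p2 = rank_sum_test(statistic=2 * mean - w, n1=8, n2=6).p_raw
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_null_calibration(self):
        # exactness => type-I error at alpha=0.05 is <= 0.05
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10_000, 14))
        ranks = sps.rankdata(data, axis=1)
        ws = ranks[:, :8].sum(axis=1)
        support, pmf = rank_sum_null(8, 6)
        lo = np.cumsum(pmf)
        hi = np.cumsum(pmf[::-1])[::-1]
        p_by_w = np.minimum(1.0, 2 * np.minimum(lo, hi))
        idx = (ws - support[0]).astype(int)
        rejections = np.mean(p_by_w[idx] <= 0.05)
        assert rejections <= 0.05


class TestSignedRank:
    def test_all_positive_n8(self):
        res = signed_rank_test(statistic=36, n=8)
        assert res.p_raw == pytest.approx(2 / 256, abs=1e-15)

    def test_w35_n8(self):
        res = signed_rank_test(statistic=35, n=8)
        assert res.p_raw == pytest.approx(4 / 256, abs=1e-15)

    def test_w10_n6_capped(self):
        res = signed_rank_test(statistic=10, n=6)
        assert res.p_raw == 1.0

    @pytest.mark.parametrize("n", range(1, 13))
    def test_dp_equals_enumeration(self, n):
        support, pmf = signed_rank_null(n)
        b_support, b_pmf = brute_signed_rank_null(n)
        assert np.array_equal(support, b_support)
        np.testing.assert_allclose(pmf, b_pmf, atol=1e-12)

    def test_zeros_dropped_and_reported(self):
        res = signed_rank_test([0.0, 1.0, 2.0, 3.0])
        assert res.n_zeros_dropped == 1
        assert res.n1 == 3
        assert res.statistic == 6.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            signed_rank_test([0.0, 0.0])

    def test_symmetry_of_p(self):
        mean = 8 * 9 / 4
        for w in (3, 10, 15, 30):
            p1 = signed_rank_test(statistic=w, n=8).p_raw
            p2 = signed_rank_test(statistic=2 * mean - w, n=8).p_raw
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_tied_magnitudes_fall_back(self):
        res = signed_rank_test([1.0, -1.0, 2.0, 3.0], seed=5)
        assert res.method == "signed_rank_mc"
        assert res.tie_fallback


class TestBonferroni:
    def test_printed_rounding_case(self):
        # 0.015625 * 3 = 0.046875, printed as 0.047
        assert bonferroni(0.015625, 3) == pytest.approx(0.046875)
        assert round(bonferroni(0.015625, 3), 3) == 0.047

    def test_capped(self):
        assert bonferroni(0.5, 3) == 1.0

    def test_identity(self):
        assert bonferroni(0.123, 1) == 0.123

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)

    @given(st.floats(1e-9, 1.0), st.integers(1, 50))
    def test_range(self, p, m):
        out = bonferroni(p, m)
        assert p <= out <= 1.0 or out == pytest.approx(min(1.0, m * p))


class TestResultInvariants:
    def test_corrected_consistency_enforced(self):
        with pytest.raises(ValueError):
            TestResult(method="rank_sum_exact", statistic=1, n1=2,
                       p_raw=0.2, p_corrected=0.5, correction_factor=2)

    @given(st.integers(1, 6), st.integers(1, 6), st.integers(1, 10))
    @settings(max_examples=30, deadline=None)
    def test_corrected_is_min_capped(self, n1, n2, m):
        support, _ = rank_sum_null(n1, n2)
        res = rank_sum_test(statistic=int(support[0]), n1=n1, n2=n2,
                            correction_factor=m)
        assert res.p_corrected == pytest.approx(min(1.0, m * res.p_raw))


class TestSpearman:
    def test_monotone_increasing(self):
        rho, p = spearman_corr([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        rho, _ = spearman_corr([1, 2, 3, 4], [8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_matches_permutation_oracle_n6(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman_corr(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)

        def pearson(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())

        obs = pearson(rx, ry)
        count = sum(
            abs(pearson(rx, np.asarray(perm))) >= abs(obs) - 1e-12
            for perm in permutations(ry)
        )
        assert rho == pytest.approx(obs, abs=1e-12)
        assert p == pytest.approx(count / math.factorial(6), abs=1e-12)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        rho, p = spearman_corr(x, y)
        rho_sp, p_sp = sps.spearmanr(x, y)
        assert rho == pytest.approx(rho_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2, 3], [1, 2, 3])
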