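"""Shared statistical primitives against independent oracles."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from twinewas._stats import (
    bh_fdr,
    binom_two_sided,
    fisher_enrichment,
    genomic_inflation,
    two_proportion_test,
    wilcoxon_signed_rank,
)


def binom_two_sided_rational(k: int, n: int) -> Fraction:
    """Exact rational minimum-likelihood two-sided binomial p at p0 = 1/2."""
    pmf = [Fraction(math.comb(n, i), 2**n) for i in range(n + 1)]
    obs = pmf[k]
    return min(Fraction(1), sum(p for p in pmf if p <= obs))


class TestBinomTwoSided:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (18, 36, 1.0),       # dead centre
            (2, 2, 0.5),
            (0, 10, 2 / 1024),
        ],
    )
    def test_simple_cases(self, k, n, expected):
        assert binom_two_sided(k, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k,n", [(3, 7), (0, 5), (40, 100), (55, 100),
                                     (17, 33), (50, 100)])
    def test_matches_exact_rational(self, k, n):
        """Log-space tail summation agrees with exact rational arithmetic."""
        expected = float(binom_two_sided_rational(k, n))
        assert binom_two_sided(k, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("k,n", [(4, 9), (123, 400), (3000, 7000)])
    def test_matches_scipy(self, k, n):
        assert binom_two_sided(k, n) == pytest.approx(
            stats.binomtest(k, n).pvalue, rel=1e-9
        )

    def test_nonhalf_null(self):
        assert binom_two_sided(3, 20, p0=0.3) == pytest.approx(
            stats.binomtest(3, 20, p=0.3).pvalue, rel=1e-9
        )

    @given(st.integers(0, 60), st.integers(1, 60))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetry_at_half(self, k, n):
        k = min(k, n)
        assert binom_two_sided(k, n) == pytest.approx(
            binom_two_sided(n - k, n), rel=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binom_two_sided(0, 0)
        with pytest.raises(ValueError):
            binom_two_sided(5, 3)


def wilcoxon_enumeration(diffs) -> float:
    """Brute-force exact two-sided signed-rank p over all sign patterns."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    total = n * (n + 1) / 2
    w_min = min(w_obs, total - w_obs)
    w_max = total - w_min
    count = 0
    for signs in product([0, 1], repeat=n):
        w = float(sum(r for s, r in zip(signs, ranks) if s))
        if w <= w_min or w >= w_max:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_three_positive_differences(self):
        # all-positive {1,2,3}: only the extreme orthants qualify
        assert wilcoxon_signed_rank([1, 2, 3]) == pytest.approx(0.25)

    def test_symmetric_two(self):
        assert wilcoxon_signed_rank([-1, 1]) == pytest.approx(1.0)

    def test_all_zero_is_null(self):
        assert wilcoxon_signed_rank([0.0, 0.0, 0.0]) == 1.0

    def test_single_nonzero_missing(self):
        assert math.isnan(wilcoxon_signed_rank([0.0, 0.5]))

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.normal(0.2, 1.0, size=n)
            assert wilcoxon_signed_rank(d) == pytest.approx(
                wilcoxon_enumeration(d), rel=1e-12
            )

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1.0, size=60)
        expected = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        ).pvalue
        assert wilcoxon_signed_rank(d) == pytest.approx(expected, rel=1e-12)


def bh_oracle(pvals):
    """Definition-based BH oracle: q_i = min over thresholds t >= p_i of
    m * t / #{p <= t}."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        cands = [
            m * t / np.sum(p <= t) for t in p if t >= p[i]
        ]
        q[i] = min(1.0, min(cands))
    return q


class TestBhFdr:
    def test_hand_example(self):
        # p * m / rank = {.04, .04, .04, .04} after monotone adjustment
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_fdr([0.05])[0] == pytest.approx(0.05)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_matches_definition_oracle(self, n):
        rng = np.random.default_rng(n + 100)
        p = rng.uniform(size=n)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=200)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, rtol=1e-12)

    def test_missing_propagates(self):
        q = bh_fdr([0.01, np.nan, 0.5])
        assert math.isnan(q[1])
        # adjustment uses only the two observed p-values
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.5]))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_q_sorted_with_p_and_bounded(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestFisherEnrichment:
    def test_hypergeometric_example(self):
        # table [[3,1],[1,3]]: two-sided p = 34/70 by enumeration
        _, p = fisher_enrichment(3, 4, 4, 8)
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_equal_proportions(self):
        _, p = fisher_enrichment(2, 4, 4, 8)
        assert p == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        odds, p = fisher_enrichment(0, 4, 0, 8)
        assert math.isnan(odds) and p == 1.0

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            fisher_enrichment(5, 6, 3, 100)


class TestTwoProportion:
    def test_equal(self):
        assert two_proportion_test(50, 100, 50, 100) == pytest.approx(1.0)

    def test_pooled_arithmetic(self):
        # pooled p = .5, z = .2/sqrt(.25 * .02) = 2.8284
        assert two_proportion_test(60, 100, 40, 100) == pytest.approx(
            2 * stats.norm.sf(0.2 / np.sqrt(0.25 * 0.02)), rel=1e-10
        )

    def test_both_zero(self):
        assert two_proportion_test(0, 50, 0, 60) == 1.0


class TestGenomicInflation:
    def test_all_half(self):
        assert genomic_inflation([0.5] * 200) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_null(self):
        rng = np.random.default_rng(3)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert 0.98 < lam < 1.02

    def test_inflated_when_p_shrunk(self):
        rng = np.random.default_rng(4)
        u = rng.uniform(size=20_000)
        assert genomic_inflation(u**2) > 1.0

    def test_too_few_p_is_missing(self):
        assert math.isnan(genomic_inflation([0.5] * 99))
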