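"""Shared statistical primitives used across the pipeline.

Exact binomial sign tests, Wilcoxon signed-rank with the exact/approximate
switch, Benjamini-Hochberg FDR, Fisher enrichment, pooled two-proportion
tests and the genomic-inflation factor. These are deliberately collected in
one module so that every stage of the pipeline applies identical conventions
(tie handling, zero handling, missing-value propagation).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger("twinewas")

__all__ = [
    "binom_two_sided",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "fisher_enrichment",
    "two_proportion_test",
    "genomic_inflation",
]

# exact Wilcoxon above this many nonzero pairs is replaced by the normal
# approximation with continuity correction
_WILCOXON_EXACT_MAX = 25


def binom_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test of ``k`` successes in ``n`` trials.

    The two-sided p-value is the sum of probabilities of all outcomes whose
    point probability does not exceed that of the observed ``k`` (the
    minimum-likelihood convention). Tail mass is accumulated in log space so
    the test remains accurate for epigenome-scale counts where individual
    point probabilities underflow. For ``p0 = 0.5`` this coincides with
    ``min(1, 2 * min(lower tail, upper tail))``.
    """
    if n <= 0:
        raise ValueError("binomial test requires n > 0")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    support = np.arange(n + 1)
    logpmf = stats.binom.logpmf(support, n, p0)
    # relative tolerance on the point probability guards against ties lost
    # to floating point, matching the usual exact-test convention
    cutoff = logpmf[k] + 1e-7
    return float(min(1.0, np.exp(logsumexp(logpmf[logpmf <= cutoff]))))


def wilcoxon_signed_rank(diffs) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped before ranking. With at most
    25 nonzero, tie-free differences the exact null distribution is used;
    otherwise the normal approximation with continuity correction. All-zero
    differences carry no evidence against the null and yield 1.0; a single
    nonzero difference cannot be tested and yields ``nan``.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 2:
        return float("nan")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= _WILCOXON_EXACT_MAX and not has_ties:
        method = "exact"
        res = stats.wilcoxon(d, alternative="two-sided", method=method)
    else:
        res = stats.wilcoxon(
            d, alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    Missing p-values are excluded from the adjustment and propagate as
    missing q-values; the effective number of tests is the number of
    non-missing p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    pv = p[ok]
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotone non-decreasing q along the sorted p
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def fisher_enrichment(
    sig_in: int, sig_total: int, bg_in: int, bg_total: int
) -> tuple[float, float]:
    """Two-sided Fisher exact test for overlap enrichment among significant
    probes relative to the full background.

    Returns ``(odds_ratio, p)``. The 2x2 table is (significant vs not) by
    (overlapping vs not), with the background including the significant set.
    A degenerate margin (no overlaps anywhere, or an empty stratum) is
    reported as ``(nan, 1.0)``.
    """
    if sig_in > bg_in or sig_total > bg_total:
        raise ValueError("significant counts must not exceed background counts")
    a = sig_in
    b = sig_total - sig_in
    c = bg_in - sig_in
    d = (bg_total - sig_total) - c
    if min(a + b, c + d) < 0:
        raise ValueError("inconsistent counts")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate Fisher margin for table %s", table.tolist())
        return float("nan"), 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided pooled z-test for equality of two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


# median of the chi-square distribution with one degree of freedom
_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def genomic_inflation(pvalues, min_n: int = 100) -> float:
    """Genomic-inflation factor lambda from a vector of association p-values.

    Lambda is the median of the implied one-degree-of-freedom chi-square
    statistics divided by the null chi-square median (0.4549). Values near 1
    indicate a well-calibrated test; inflation above 1 suggests confounding
    or polygenicity. Requires at least ``min_n`` valid p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < min_n:
        logger.warning(
            "genomic inflation needs >= %d p-values, got %d", min_n, p.size
        )
        return float("nan")
    chi2 = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)
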