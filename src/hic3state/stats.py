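"""Shared statistical primitives: BH step-up, Fisher exact, rank-sum tests
and resampling empirical p-values.

The Fisher two-sided p is computed by summing hypergeometric point
probabilities no larger than the observed one (the classical definition),
vectorized over tables so that large loop tables and exhaustive small-table
sweeps are cheap.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats as sps

_REL_EPS = 1 + 1e-7  # tolerance when comparing point probabilities


def bh_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` may exceed ``len(p)`` when the family contains additional implicit
    tests with p = 1 (e.g. zero-count locus pairs); those cannot change the
    ordering but inflate the denominator.
    """
    p = np.asarray(p, dtype=np.float64)
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("family size m cannot be smaller than len(p)")
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def fisher_exact_2x2(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher exact p for tables [[a, b], [c, d]], vectorized."""
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("table cells must be non-negative")
    n = a + b + c + d
    r = a + b        # first row margin
    k = a + c        # first column margin
    kmin = np.maximum(0, r + k - n)
    kmax = np.minimum(r, k)
    sizes = (kmax - kmin + 1).astype(np.int64)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    total = int(offsets[-1])
    table_idx = np.repeat(np.arange(len(a)), sizes)
    ks = np.arange(total) - offsets[table_idx] + kmin[table_idx]
    pmf = sps.hypergeom.pmf(ks, n[table_idx], k[table_idx], r[table_idx])
    pobs = sps.hypergeom.pmf(a, n, k, r)
    mask = pmf <= pobs[table_idx] * _REL_EPS
    p = np.zeros(len(a))
    np.add.at(p, table_idx[mask], pmf[mask])
    p[n == 0] = 1.0  # empty table: scipy's pmf degenerates
    return np.minimum(p, 1.0)


def fisher_test(table) -> tuple[float, float]:
    """Odds ratio and two-sided exact p for one 2x2 table."""
    (a, b), (c, d) = table
    p = float(fisher_exact_2x2(a, b, c, d)[0])
    odds = np.inf if b * c == 0 and a * d > 0 else (
        np.nan if b * c == 0 else a * d / (b * c)
    )
    return odds, p


_EXACT_RANKSUM_MAX_N = 16


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation enumeration (midranks) when n1 + n2 <= 16, otherwise
    the tie-corrected normal approximation via scipy.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= _EXACT_RANKSUM_MAX_N:
        return _exact_rank_sum(x, y, alternative)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def _exact_rank_sum(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    eps = 1e-9
    count = 0
    total = 0
    for subset in combinations(range(n), n1):
        w = ranks[list(subset)].sum()
        total += 1
        if alternative == "two-sided":
            count += abs(w - mu) >= abs(w_obs - mu) - eps
        elif alternative == "greater":
            count += w >= w_obs - eps
        elif alternative == "less":
            count += w <= w_obs + eps
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return count / total


def empirical_p(observed: float, null_values) -> float:
    """Add-one resampling p-value: (1 + #{null >= observed}) / (n + 1)."""
    null_values = np.asarray(null_values, dtype=np.float64)
    return float((1 + np.sum(null_values >= observed)) / (len(null_values) + 1))
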