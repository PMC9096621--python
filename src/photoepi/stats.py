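"""Shared statistical primitives: vectorized Fisher's exact test and BH-FDR.

The two-sided Fisher test follows the conventional "sum of all tables at
least as extreme" definition: with fixed margins the first cell is
hypergeometric, and the p-value sums the probabilities of all outcomes whose
point probability does not exceed that of the observed table (with a small
relative tolerance to absorb floating-point ties, matching scipy).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

_REL_TOL = 1 + 1e-7


def fisher_exact_vec(meth_a, total_a, meth_b, total_b):
    """Two-sided Fisher's exact test for many 2x2 tables at once.

    Each test i compares table ``[[meth_a, total_a-meth_a],
    [meth_b, total_b-meth_b]]``. Intended for per-cytosine testing where
    totals are sequencing coverages (support per table is small); the loop is
    over the hypergeometric support, vectorized over tables.

    Returns an array of p-values in [0, 1].
    """
    ma = np.atleast_1d(np.asarray(meth_a, dtype=np.int64))
    ta = np.atleast_1d(np.asarray(total_a, dtype=np.int64))
    mb = np.atleast_1d(np.asarray(meth_b, dtype=np.int64))
    tb = np.atleast_1d(np.asarray(total_b, dtype=np.int64))
    if (ma > ta).any() or (mb > tb).any() or (ma < 0).any() or (mb < 0).any():
        raise ValueError("counts must satisfy 0 <= meth <= total")
    if (ta == 0).any() or (tb == 0).any():
        raise ValueError("zero-total sample: filter before testing")

    n = ta + tb
    k = ma + mb  # successes pooled across both samples
    lo = np.maximum(0, k - tb)
    hi = np.minimum(k, ta)
    p_obs = hypergeom.pmf(ma, n, k, ta)
    p = np.zeros(ma.shape, dtype=float)
    for x in range(int(hi.max()) + 1):
        active = (x >= lo) & (x <= hi)
        if not active.any():
            continue
        px = hypergeom.pmf(x, n[active], k[active], ta[active])
        p[active] += np.where(px <= p_obs[active] * _REL_TOL, px, 0.0)
    return np.minimum(p, 1.0)


def fisher_exact_table(table):
    """Two-sided Fisher's exact test and odds ratio for one 2x2 table.

    Returns ``(odds_ratio, p)``; the odds ratio uses the Haldane-Anscombe
    0.5 correction when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b, c, d = t.ravel()
    p = float(
        fisher_exact_vec(
            int(a), int(a + b), int(c), int(c + d)
        )[0]
    )
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), p


def bh_adjust(p):
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Ties are handled by the standard cumulative-minimum from the largest
    p-value down; output is monotone in the input and >= it elementwise.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
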