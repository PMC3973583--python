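"""Shared statistical primitives: BH step-up FDR and exact tail probabilities."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["bh_fdr", "binomial_tail", "hypergeom_tail"]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up corrected q-values.

    q_i = min over all j with p_j >= p_i of (p_j * m / rank_j), capped at 1.
    Order-preserving: q is a monotone function of p.

    Parameters
    ----------
    pvals
        Raw p-values, each in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest p downwards implements the min-over-suffix
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p).

    P(X >= 0) is 1 by convention; ``k > n`` is an error rather than 0 because
    a bin can never contain more flagged genes than resident genes.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    return float(sps.binom.sf(k - 1, n, p))


def hypergeom_tail(k: int, n: int, M: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, M, n).

    Population of ``N`` items of which ``M`` are marked; ``n`` items are drawn
    without replacement; the tail is the chance of seeing at least ``k`` marked
    items among the draws.
    """
    if not 0 <= k <= n <= N:
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not 0 <= M <= N:
        raise ValueError(f"need 0 <= M <= N, got M={M}, N={N}")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, M, n))
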