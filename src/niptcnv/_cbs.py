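"""Numba kernels for circular binary segmentation.

The change-point statistic for an arc [i, j) of a length-n segment is the
two-sample t-like contrast between the arc and its complement under a
constant pooled variance,

    T(i, j) = |S_j - S_i - (j - i) * mean| / sqrt(k (n - k) / n),   k = j - i

(in units of the segment standard deviation, which is constant under
permutation and therefore drops out of the permutation test).  Every
circular split of the segment corresponds to exactly one non-wrapping arc,
so scanning all 0 <= i < j <= n covers the circularized search space.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["max_arc_stat", "permutation_exceedances"]


@njit(cache=True)
def max_arc_stat(x):
    """Maximal arc contrast; returns (stat, i, j) with split points i < j."""
    n = x.size
    cs = np.empty(n + 1)
    cs[0] = 0.0
    for i in range(n):
        cs[i + 1] = cs[i] + x[i]
    tot = cs[n]
    best = -1.0
    bi = 0
    bj = n
    for k in range(1, n):
        mu = k * tot / n
        den = np.sqrt(k * (n - k) / n)
        for i in range(n - k + 1):
            t = abs(cs[i + k] - cs[i] - mu) / den
            if t > best:
                best = t
                bi = i
                bj = i + k
    return best, bi, bj


@njit(cache=True)
def permutation_exceedances(x, stat_obs, n_perm, stop_after, seed):
    """Count permutations whose maximal arc contrast reaches ``stat_obs``.

    Stops early once ``stop_after`` exceedances are seen (the split can no
    longer be significant).  Returns (exceedances, permutations_done).
    """
    np.random.seed(seed)
    n = x.size
    y = x.copy()
    cs = np.empty(n + 1)
    exceed = 0
    for p in range(n_perm):
        np.random.shuffle(y)
        cs[0] = 0.0
        for i in range(n):
            cs[i + 1] = cs[i] + y[i]
        tot = cs[n]
        hit = False
        for k in range(1, n):
            mu = k * tot / n
            den = np.sqrt(k * (n - k) / n)
            for i in range(n - k + 1):
                if abs(cs[i + k] - cs[i] - mu) / den >= stat_obs:
                    hit = True
                    break
            if hit:
                break
        if hit:
            exceed += 1
            if exceed >= stop_after:
                return exceed, p + 1
    return exceed, n_perm
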