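"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own algorithms: the Fréchet oracle
enumerates every monotone coupling explicitly, the hypergeometric oracle
sums the pmf from binomial coefficients, and the mean/kappa oracles evaluate
their formulas directly.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb, sqrt

import numpy as np


def frechet_bruteforce(PA: np.ndarray, PB: np.ndarray) -> float:
    """Min over all monotone couplings of the max Euclidean ground distance."""
    m, n = len(PA), len(PB)

    def dist(i: int, j: int) -> float:
        return sqrt(((PA[i] - PB[j]) ** 2).sum())

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        d = dist(i, j)
        if i == m - 1 and j == n - 1:
            return d
        succ = []
        if i + 1 < m:
            succ.append(best(i + 1, j))
        if j + 1 < n:
            succ.append(best(i, j + 1))
        if i + 1 < m and j + 1 < n:
            succ.append(best(i + 1, j + 1))
        return max(d, min(succ))

    return best(0, 0)


def embed_points(times: np.ndarray, values: np.ndarray,
                 time_scale: float = 1.0) -> np.ndarray:
    """Replicate the (scaled time, value) embedding used by the package."""
    t = np.asarray(times, dtype=float)
    span = t.max() - t.min()
    u = np.zeros_like(t) if span == 0 else (t - t.min()) / span
    return np.column_stack([time_scale * u, np.asarray(values, dtype=float)])


def hypergeom_pmf(x: int, m: int, K: int, N: int) -> float:
    """P(X = x) for x annotated among m drawn from N with K annotated."""
    return comb(K, x) * comb(N - K, m - x) / comb(N, m)


def hypergeom_tail(x: int, m: int, K: int, N: int) -> float:
    """P(X >= x) by direct pmf summation."""
    return sum(hypergeom_pmf(i, m, K, N)
               for i in range(x, min(m, K) + 1))
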