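"""Penalized least-squares change-point search (PELT).

Dynamic program over candidate change points with Killick-style pruning,
minimizing

    sum_k SSE(segment_k)  +  penalty * (#change points)

for a piecewise-constant mean model with Gaussian L2 cost.  The search is
exact on the candidate grid: with ``grid=1`` every sample is a candidate and
the result is the global optimum of the penalized objective (verified against
an exhaustive O(n^2) dynamic program in the test suite).  For very long
recordings the caller may place candidates every ``grid`` samples and refine
afterwards (:func:`refine_changepoints`); segment SSE is always evaluated on
the full-resolution data via prefix sums.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _pelt_core(cs, css, n, grid, penalty):
    """PELT on candidate positions {0, grid, 2*grid, ..., n}.

    cs, css : prefix sums of x and x**2, length n+1 (cs[0] = 0).
    Returns change-point sample positions (excluding 0 and n), ascending.
    """
    # candidate grid positions; last entry is exactly n
    m = (n - 1) // grid + 1  # number of interior-or-zero grid points
    npos = m + 1
    pos = np.empty(npos, dtype=np.int64)
    for j in range(m):
        pos[j] = j * grid
    pos[m] = n

    F = np.empty(npos)
    F[0] = -penalty
    last = np.zeros(npos, dtype=np.int64)
    cand = np.empty(npos, dtype=np.int64)
    cand[0] = 0
    ncand = 1

    for j in range(1, npos):
        t = pos[j]
        cst = cs[t]
        csst = css[t]
        best = np.inf
        arg = 0
        for ci in range(ncand):
            s = cand[ci]
            ps = pos[s]
            d = cst - cs[ps]
            c = csst - css[ps] - d * d / (t - ps)
            if c < 0.0:
                c = 0.0
            v = F[s] + c
            if v < best:
                best = v
                arg = s
        F[j] = best + penalty
        last[j] = arg
        # prune candidates that can never be optimal again
        k = 0
        for ci in range(ncand):
            s = cand[ci]
            ps = pos[s]
            d = cst - cs[ps]
            c = csst - css[ps] - d * d / (t - ps)
            if c < 0.0:
                c = 0.0
            if F[s] + c <= F[j]:
                cand[k] = s
                k += 1
        cand[k] = j
        ncand = k + 1

    # backtrack
    cps = np.empty(npos, dtype=np.int64)
    ncp = 0
    j = npos - 1
    while j > 0:
        prev = last[j]
        if prev > 0:
            cps[ncp] = pos[prev]
            ncp += 1
        j = prev
    return cps[:ncp][::-1].copy()


def pelt_changepoints(x: np.ndarray, penalty: float, grid: int = 1) -> np.ndarray:
    """Return optimal change-point sample indices for signal ``x``.

    A change point at index ``i`` means segments ``x[:i]`` and ``x[i:]`` are
    fitted separately.  ``grid`` restricts candidates to multiples of that
    stride (plus the endpoint); use 1 for the exact search.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n < 2:
        return np.empty(0, dtype=np.int64)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    css = np.concatenate(([0.0], np.cumsum(x * x)))
    return _pelt_core(cs, css, n, int(grid), float(penalty))


def refine_changepoints(x: np.ndarray, cps: np.ndarray, radius: int) -> np.ndarray:
    """Locally refine each change point to the sample minimizing the SSE of
    its two flanking segments (neighboring change points held fixed).

    Used after a gridded search to restore single-sample localization.
    """
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if len(cps) == 0 or radius <= 0:
        return np.asarray(cps, dtype=np.int64)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    css = np.concatenate(([0.0], np.cumsum(x * x)))
    out = np.asarray(cps, dtype=np.int64).copy()
    bounds = np.concatenate(([0], out, [n]))
    for i in range(len(out)):
        lo = max(bounds[i] + 1, out[i] - radius)
        hi = min(bounds[i + 2] - 1, out[i] + radius)
        if hi <= lo:
            continue
        left, right = bounds[i], bounds[i + 2]
        best_cost = np.inf
        best = out[i]
        for b in range(lo, hi + 1):
            d1 = cs[b] - cs[left]
            d2 = cs[right] - cs[b]
            c = (css[b] - css[left] - d1 * d1 / (b - left)) + (
                css[right] - css[b] - d2 * d2 / (right - b)
            )
            if c < best_cost:
                best_cost = c
                best = b
        out[i] = best
        bounds[i + 1] = best
    return out
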