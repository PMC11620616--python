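"""Hartigan's dip statistic and a bootstrap unimodality test.

The dip of an empirical CDF F_n is the smallest sup-norm distance from F_n
to any unimodal CDF.  It is computed here by bisection over that distance
d: F_n is within d of some unimodal CDF iff there is a split point such
that a convex nondecreasing function fits inside the band
[F_n − d, F_n + d] to the left of the split and a concave one to the right
(the mode may carry an atom, so the band constraint at the split point
itself is one-sided).  Band feasibility on a prefix reduces to checking
that the greatest convex minorant of the upper band envelope stays above
the lower envelope, evaluated incrementally with a monotone convex hull.
The concave side is the same check on the reflected sample.

Known closed-form anchors used as tests: an equally spaced sample has dip
exactly 1/(2n); a half-and-half two-point sample has dip 1/4 (the maximum
possible).

P-values are calibrated by parametric bootstrap against the uniform null —
the least-favourable unimodal distribution — with a fixed seed; null
distributions are cached per sample size.  This matches the classical
table-based test in spirit while remaining self-contained.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic", "dip_test"]

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


@njit(cache=False)
def _max_feasible_prefix(x, lo, up):
    """Largest m such that a convex nondecreasing function fits in
    [lo, up] on points 0..m, with the lower bound at the last point of the
    prefix ignored (mode relaxation).  Returns -1 if even {x0} fails."""
    n = x.size
    hull = np.empty(n, dtype=np.int64)
    k = 0
    for j in range(n):
        if j >= 1 and up[j - 1] < lo[j - 1]:
            return j - 1
        # pop hull vertices that are no longer on the lower convex hull
        while k >= 2:
            a = hull[k - 2]
            b = hull[k - 1]
            cross = (x[b] - x[a]) * (up[j] - up[a]) - (up[b] - up[a]) * (
                x[j] - x[a]
            )
            if cross <= 0.0:
                k -= 1
            else:
                break
        if k >= 1:
            v = hull[k - 1]
            dxs = x[j] - x[v]
            for i in range(v + 1, j):
                val = up[v] + (up[j] - up[v]) * (x[i] - x[v]) / dxs
                if val < lo[i]:
                    return j - 1
        hull[k] = j
        k += 1
    return n - 1


@njit(cache=False)
def _feasible(x, f_lo, f_hi, d):
    """Is there a unimodal CDF within sup-distance d of the ECDF?"""
    n = x.size
    lo = f_hi - d  # G(x_j) must reach the post-jump value within d
    up = f_lo + d  # G(x_j−) must not exceed the pre-jump value plus d
    p = _max_feasible_prefix(x, lo, up)
    if p < 0:
        return False
    xr = -x[::-1]
    lor = 1.0 - up[::-1]
    upr = 1.0 - lo[::-1]
    q = _max_feasible_prefix(xr, lor, upr)
    if q < 0:
        return False
    return p + q >= n - 1


@njit(cache=False)
def _dip_sorted(xs, tol):
    n = xs.size
    if n <= 1:
        return 0.0
    # collapse ties into unique support points with cumulative ECDF values
    xu = np.empty(n)
    f_hi = np.empty(n)  # ECDF value at x_j (after the jump)
    f_lo = np.empty(n)  # ECDF value just before x_j
    m = 0
    prev = 0
    for i in range(n):
        if i == n - 1 or xs[i + 1] != xs[i]:
            xu[m] = xs[i]
            f_lo[m] = prev / n
            f_hi[m] = (i + 1) / n
            prev = i + 1
            m += 1
    xu = xu[:m]
    f_lo = f_lo[:m]
    f_hi = f_hi[:m]
    lo_d, hi_d = 0.0, 0.5
    while hi_d - lo_d > tol:
        mid = 0.5 * (lo_d + hi_d)
        if _feasible(xu, f_lo, f_hi, mid):
            hi_d = mid
        else:
            lo_d = mid
    return 0.5 * (lo_d + hi_d)


def dip_statistic(sample: np.ndarray, tol: float = 1e-8) -> float:
    """Hartigan's dip of a 1-D sample (bisection to absolute tolerance)."""
    xs = np.sort(np.asarray(sample, dtype=np.float64))
    return float(_dip_sorted(xs, tol))


def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (n, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        dips = np.empty(n_boot)
        for b in range(n_boot):
            dips[b] = _dip_sorted(np.sort(rng.random(n)), 1e-6)
        _NULL_CACHE[key] = np.sort(dips)
    return _NULL_CACHE[key]


def dip_test(
    sample: np.ndarray, n_boot: int = 2000, seed: int = 12345
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value under the uniform null.

    Small p-values reject unimodality.  Returns ``(dip, p_value)``.
    """
    sample = np.asarray(sample, dtype=np.float64)
    d = dip_statistic(sample)
    if sample.size <= 3:
        return d, 1.0
    nulls = _null_dips(sample.size, n_boot, seed)
    # one-sided: fraction of null dips at least as large as observed
    p = 1.0 - np.searchsorted(nulls, d, side="left") / nulls.size
    return d, float(p)
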