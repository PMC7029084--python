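"""Hartigan & Hartigan's dip statistic and Monte-Carlo unimodality test.

The dip D(x) is the smallest sup-norm distance between the empirical CDF of
a sample and the class of unimodal CDFs (convex on (-inf, m], concave on
[m, inf) for some mode m).  Large values indicate departure from
unimodality; the minimum attainable value is 1/(2n).

The computation follows the classic iterative algorithm: within the current
candidate modal interval, fit the greatest convex minorant (GCM) and least
concave majorant (LCM) of the empirical CDF, measure their maximal
separation and the residual deviation of the ECDF from each hull outside
the modal interval, then shrink the interval and repeat.  All bookkeeping
is done in units of counts (multiples of 1/n); the result is divided by 2n
at the end.

P-values are Monte Carlo: the null reference distribution is the dip of
uniform(0, 1) samples of the same size, which is the least favourable
unimodal null.  The inner loop is JIT-compiled with numba when available;
a pure-Python fallback gives identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trait_io import InsufficientSample


def _dip_sorted(x, mn, mj, gcm, lcm):
    """Dip of a sorted 1-D sample, in count units scaled to [0, 0.25].

    ``mn, mj, gcm, lcm`` are int64 work arrays of length n + 1 (1-based
    indexing inside; entry 0 unused) supplied by the caller so the function
    can be JIT-compiled without allocations.
    """
    n = x.shape[0]
    if n < 2 or x[n - 1] == x[0]:
        return 0.5 / n if n > 0 else 0.0

    low = 1
    high = n
    dip = 1.0  # count units; final division by 2n gives the 1/(2n) floor

    while True:
        # greatest convex minorant: predecessor touch point for each index
        mn[low] = low
        for j in range(low + 1, high + 1):
            mn[j] = j - 1
            while True:
                mnj = mn[j]
                mnmnj = mn[mnj]
                if mnj == low or (
                    (x[j - 1] - x[mnj - 1]) * (mnj - mnmnj)
                    < (x[mnj - 1] - x[mnmnj - 1]) * (j - mnj)
                ):
                    break
                mn[j] = mnmnj
        # least concave majorant: successor touch point for each index
        mj[high] = high
        for k in range(high - 1, low - 1, -1):
            mj[k] = k + 1
            while True:
                mjk = mj[k]
                mjmjk = mj[mjk]
                if mjk == high or (
                    (x[k - 1] - x[mjk - 1]) * (mjk - mjmjk)
                    < (x[mjk - 1] - x[mjmjk - 1]) * (k - mjk)
                ):
                    break
                mj[k] = mjmjk

        # collect GCM change points from high down to low
        ic = 1
        gcm[1] = high
        while gcm[ic] > low:
            gcm[ic + 1] = mn[gcm[ic]]
            ic += 1
        l_gcm = ic
        ig = ic
        ix = ic - 1
        # collect LCM change points from low up to high
        ic = 1
        lcm[1] = low
        while lcm[ic] < high:
            lcm[ic + 1] = mj[lcm[ic]]
            ic += 1
        l_lcm = ic
        ih = ic
        iv = 2

        # maximal separation d between the two hulls, walked low -> high
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # LCM touch point lies under the current GCM segment
                    gcmi1 = gcm[ix + 1]
                    dn = x[gcmix - 1] - x[gcmi1 - 1]
                    r = (x[lcmiv - 1] - x[gcmi1 - 1]) * (gcmix - gcmi1) / dn \
                        if dn > 0 else 0.0
                    dx = (lcmiv - gcmi1 + 1) - r
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # GCM touch point lies over the current LCM segment
                    lcmiv1 = lcm[iv - 1]
                    dn = x[lcmiv - 1] - x[lcmiv1 - 1]
                    r = (x[gcmix - 1] - x[lcmiv1 - 1]) * (lcmiv - lcmiv1) / dn \
                        if dn > 0 else 0.0
                    dx = r - (gcmix - 1 - lcmiv1)
                    ix -= 1
                    if dx > d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < dip:
            break

        # residual dip of the ECDF over the GCM, left of the modal interval
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb = gcm[j + 1]
            je = gcm[j]
            if je - jb > 1 and x[je - 1] != x[jb - 1]:
                c = (je - jb) / (x[je - 1] - x[jb - 1])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj - 1] - x[jb - 1]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t
        # residual dip of the ECDF under the LCM, right of the modal interval
        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb = lcm[j]
            je = lcm[j + 1]
            if je - jb > 1 and x[je - 1] != x[jb - 1]:
                c = (je - jb) / (x[je - 1] - x[jb - 1])
                for jj in range(jb, je + 1):
                    t = (x[jj - 1] - x[jb - 1]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dipnew = dip_l if dip_l > dip_u else dip_u
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def _dip_batch_py(X, out):
    n = X.shape[1]
    mn = np.zeros(n + 1, np.int64)
    mj = np.zeros(n + 1, np.int64)
    gcm = np.zeros(n + 2, np.int64)
    lcm = np.zeros(n + 2, np.int64)
    for i in range(X.shape[0]):
        out[i] = _dip_sorted(X[i], mn, mj, gcm, lcm)
    return out


try:  # optional JIT; the pure-Python path is the reference behaviour
    from numba import njit

    _dip_sorted_jit = njit(cache=False)(_dip_sorted)

    @njit(cache=False)
    def _dip_batch_jit(X, out):
        n = X.shape[1]
        mn = np.zeros(n + 1, np.int64)
        mj = np.zeros(n + 1, np.int64)
        gcm = np.zeros(n + 2, np.int64)
        lcm = np.zeros(n + 2, np.int64)
        for i in range(X.shape[0]):
            out[i] = _dip_sorted_jit(X[i], mn, mj, gcm, lcm)
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _dip_sorted_jit = None
    _dip_batch_jit = None
    _HAVE_NUMBA = False


def _dip_one(x_sorted: np.ndarray) -> float:
    n = x_sorted.shape[0]
    mn = np.zeros(n + 1, np.int64)
    mj = np.zeros(n + 1, np.int64)
    gcm = np.zeros(n + 2, np.int64)
    lcm = np.zeros(n + 2, np.int64)
    f = _dip_sorted_jit if _HAVE_NUMBA else _dip_sorted
    return float(f(x_sorted, mn, mj, gcm, lcm))


def _dip_batch(X_sorted: np.ndarray) -> np.ndarray:
    out = np.empty(X_sorted.shape[0])
    if _HAVE_NUMBA:
        return _dip_batch_jit(X_sorted, out)
    return _dip_batch_py(X_sorted, out)


def dip_statistic(x, min_n: int = 4) -> float:
    """Dip statistic of a numeric sample (invariant to monotone affine maps)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise InsufficientSample(f"dip needs n >= {min_n}, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic: sample contains non-finite values")
    return _dip_one(np.sort(x))


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its Monte-Carlo p-value under the uniform null."""

    D: float
    p: float
    n: int
    n_mc: int
    seed: int

    def __post_init__(self):
        assert 0.0 <= self.p <= 1.0
        assert self.D >= 1.0 / (2 * self.n) - 1e-12


def dip_pvalue(x, n_mc: int = 10_000, seed: int = 0, min_n: int = 4) -> DipResult:
    """Monte-Carlo dip test of unimodality.

    p = (1 + #{null dips >= D(x)}) / (n_mc + 1), where the null dips come
    from ``n_mc`` uniform(0, 1) samples of the same size (continuity
    corrected so p is never exactly 0).  Reproducible given ``seed``.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable p-value")
    x = np.asarray(x, dtype=float).ravel()
    d = dip_statistic(x, min_n=min_n)
    rng = np.random.default_rng(seed)
    null = rng.random((n_mc, x.size))
    null.sort(axis=1)
    null_d = _dip_batch(null)
    p = (1.0 + np.count_nonzero(null_d >= d - 1e-15)) / (n_mc + 1.0)
    return DipResult(D=d, p=float(p), n=int(x.size), n_mc=n_mc, seed=seed)
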