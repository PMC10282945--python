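"""numba fast paths for the Spatial Pooler inner loops.

These kernels replicate the pure-numpy step operations in
:mod:`sparsepool.spatial_pooler` exactly (same float64 arithmetic, same
lowest-index tie-breaking); a test asserts bit-identical results.  When
numba is unavailable the callers fall back to the numpy loop.

Layout and selection choices are purely for locality/speed: the
connected-synapse cache is stored transposed as (n_inputs, n_columns) so
overlap accumulation walks contiguous rows; learning operates on
permanences compressed to the potential pool; and when boosting is inert
(all boost factors exactly 1) top-k selection runs on the raw integer
overlaps with a counting select instead of a float sort.  Both selection
paths implement the same rule: every value above the k-th order statistic
wins, ties at the k-th fill remaining slots in ascending column order.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _overlap(conn_t, x_idx_row, L, acc):
    C = conn_t.shape[1]
    for c in range(C):
        acc[c] = 0
    for a in range(L):
        row = conn_t[x_idx_row[a]]
        for c in range(C):
            acc[c] += row[c]


@njit(cache=True)
def _topk_float(boosted, k, used, active, scratch):
    """k highest floats, lowest index first among ties; marks `used`."""
    C = boosted.shape[0]
    for c in range(C):
        scratch[c] = boosted[c]
        used[c] = 0
    scratch.sort()
    thresh = scratch[C - k]
    j = 0
    for c in range(C):
        if boosted[c] > thresh:
            active[j] = c
            used[c] = 1
            j += 1
    for c in range(C):
        if j == k:
            break
        if used[c] == 0 and boosted[c] == thresh:
            active[j] = c
            used[c] = 1
            j += 1


@njit(cache=True)
def _topk_int(acc, k, used, active, hist):
    """Counting select over integer overlaps; same rule as _topk_float."""
    C = acc.shape[0]
    maxv = 0
    for c in range(C):
        used[c] = 0
        hist[acc[c]] += 1
        if acc[c] > maxv:
            maxv = acc[c]
    cnt = 0
    v = maxv
    while True:
        cnt += hist[v]
        if cnt >= k or v == 0:
            break
        v -= 1
    thresh = v
    for c in range(C):
        hist[acc[c]] = 0
    j = 0
    for c in range(C):
        if acc[c] > thresh:
            active[j] = c
            used[c] = 1
            j += 1
    for c in range(C):
        if j == k:
            break
        if used[c] == 0 and acc[c] == thresh:
            active[j] = c
            used[c] = 1
            j += 1


@njit(cache=True)
def _all_ones(x):
    for v in x:
        if v != 1.0:
            return False
    return True


@njit(cache=True)
def sp_fit(
    perm_pot,
    pot_idx,
    conn_pot,
    conn_t,
    boost,
    duty,
    x_idx,
    x_len,
    k,
    perm_connected,
    perm_inc,
    perm_dec,
    boost_strength,
    period,
    target_density,
    n_iterations,
):
    C, S = pot_idx.shape
    T = x_idx.shape[0]
    N = conn_t.shape[0]
    xbuf = np.zeros(N, dtype=np.uint8)
    acc = np.empty(C, dtype=np.int32)
    boosted = np.empty(C, dtype=np.float64)
    scratch = np.empty(C, dtype=np.float64)
    hist = np.zeros(N + 2, dtype=np.int32)
    used = np.zeros(C, dtype=np.uint8)
    active = np.empty(k, dtype=np.int64)
    xg = np.empty(S, dtype=np.uint8)
    ncrow = np.empty(S, dtype=np.uint8)
    # boosting inert: factors stay exactly 1, so integer selection is identical
    int_path = boost_strength == 0.0 and _all_ones(boost)
    for _ in range(n_iterations):
        for t in range(T):
            L = x_len[t]
            for a in range(L):
                xbuf[x_idx[t, a]] = 1
            _overlap(conn_t, x_idx[t], L, acc)
            if int_path:
                _topk_int(acc, k, used, active, hist)
            else:
                for c in range(C):
                    boosted[c] = acc[c] * boost[c]
                _topk_float(boosted, k, used, active, scratch)
            for j in range(k):
                c = active[j]
                prow = perm_pot[c]
                crow = conn_pot[c]
                irow = pot_idx[c]
                for s in range(S):
                    xg[s] = xbuf[irow[s]]
                for s in range(S):
                    p = prow[s] + (perm_inc if xg[s] == 1 else -perm_dec)
                    p = min(max(p, 0.0), 1.0)
                    prow[s] = p
                    ncrow[s] = np.uint8(1) if p >= perm_connected else np.uint8(0)
                for s in range(S):
                    if ncrow[s] != crow[s]:
                        # scatter only on threshold crossings (rare after burn-in)
                        crow[s] = ncrow[s]
                        conn_t[irow[s], c] = ncrow[s]
            for c in range(C):
                duty[c] = (duty[c] * (period - 1) + used[c]) / period
            if boost_strength != 0.0:
                for c in range(C):
                    boost[c] = np.exp(boost_strength * (target_density - duty[c]))
            for a in range(L):
                xbuf[x_idx[t, a]] = 0


@njit(cache=True)
def sp_sdrs(conn_t, boost, x_idx, x_len, k):
    """Batch overlap → top-k (no learning); active columns sorted ascending."""
    C = conn_t.shape[1]
    N = conn_t.shape[0]
    T = x_idx.shape[0]
    acc = np.empty(C, dtype=np.int32)
    boosted = np.empty(C, dtype=np.float64)
    scratch = np.empty(C, dtype=np.float64)
    hist = np.zeros(N + 2, dtype=np.int32)
    used = np.zeros(C, dtype=np.uint8)
    active = np.empty(k, dtype=np.int64)
    out = np.empty((T, k), dtype=np.int64)
    int_path = _all_ones(boost)
    for t in range(T):
        _overlap(conn_t, x_idx[t], x_len[t], acc)
        if int_path:
            _topk_int(acc, k, used, active, hist)
        else:
            for c in range(C):
                boosted[c] = acc[c] * boost[c]
            _topk_float(boosted, k, used, active, scratch)
        out[t] = np.sort(active)
    return out
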