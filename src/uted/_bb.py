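"""Numba kernel for the colour-bounded branch-and-bound clique search.

Same search as the pure-Python engine in :mod:`uted.clique` — identical
vertex order, colouring, bound and tie-breaking, hence identical results —
compiled over explicit uint64 bitset words so the inner loops run at machine
speed. The recursion is unrolled into preallocated per-depth stacks.
"""

from __future__ import annotations

import time

import numpy as np
from numba import njit, objmode

_TOL = 1e-9
_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_ONE = np.uint64(1)
_ZERO = np.uint64(0)


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> _ONE) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return np.int64((x * _H01) >> np.uint64(56))


@njit(cache=True, inline="always")
def _ctz(x):
    # index of the lowest set bit (x must be nonzero)
    return _popcount((x & (_ZERO - x)) - _ONE)


@njit(cache=True)
def _solve(adj, w, deadline, best0, mask0):
    """adj: (n, words) uint64 bitset rows; w: float64 weights; deadline:
    monotonic seconds or a negative number for no limit; best0/mask0: an
    optional starting incumbent (weight and vertex mask; 0 and empty when
    unused). Returns (best_mask, best_value, nodes, timed_out)."""
    n = adj.shape[0]
    words = adj.shape[1]
    best = best0
    best_mask = mask0.copy()
    nodes = np.int64(0)
    timed_out = False
    if n == 0:
        return best_mask, best, nodes, timed_out

    maxd = n + 1
    cand = np.zeros((maxd, words), np.uint64)
    order = np.zeros((maxd, n), np.int32)
    bounds = np.zeros((maxd, n), np.float64)
    cnt = np.zeros(maxd, np.int32)
    ptr = np.zeros(maxd, np.int32)
    wsum = np.zeros(maxd, np.float64)
    chosen = np.zeros(maxd, np.int32)
    uncol = np.zeros(words, np.uint64)
    avail = np.zeros(words, np.uint64)

    # root frame: every vertex is a candidate
    for k in range(words):
        cand[0, k] = _ZERO - _ONE if (k + 1) * 64 <= n else _ZERO
    if n % 64:
        cand[0, words - 1] = (_ONE << np.uint64(n % 64)) - _ONE

    d = 0
    # greedy sequential colouring of the root candidate set
    _colour(adj, w, cand, order, bounds, cnt, d, uncol, avail)
    ptr[0] = cnt[0] - 1
    wsum[0] = 0.0

    while d >= 0:
        if ptr[d] < 0 or wsum[d] + bounds[d, ptr[d]] <= best + _TOL:
            d -= 1
            continue
        v = order[d, ptr[d]]
        ptr[d] -= 1
        nodes += 1
        if deadline >= 0.0 and nodes % 16384 == 0:
            with objmode(now="float64"):
                now = time.monotonic()
            if now > deadline:
                timed_out = True
                break
        chosen[d] = v
        wv = wsum[d] + w[v]
        vw = v >> 6
        vb = _ONE << np.uint64(v & 63)
        cand[d, vw] &= ~vb  # processed: drop from later siblings' view
        empty = True
        for k in range(words):
            c = cand[d, k] & adj[v, k]
            cand[d + 1, k] = c
            if c != _ZERO:
                empty = False
        if empty:
            if wv > best + _TOL:
                best = wv
                for k in range(words):
                    best_mask[k] = _ZERO
                for i in range(d + 1):
                    u = chosen[i]
                    best_mask[u >> 6] |= _ONE << np.uint64(u & 63)
        else:
            d += 1
            wsum[d] = wv
            _colour(adj, w, cand, order, bounds, cnt, d, uncol, avail)
            ptr[d] = cnt[d] - 1
    return best_mask, best, nodes, timed_out


@njit(cache=True, inline="always")
def _colour(adj, w, cand, order, bounds, cnt, d, uncol, avail):
    """Greedy colouring of cand[d] in ascending vertex order; fills order[d]
    grouped by colour class and bounds[d] with cumulative class maxima."""
    words = cand.shape[1]
    for k in range(words):
        uncol[k] = cand[d, k]
    pos = 0
    cum = 0.0
    while True:
        lead = -1
        for k in range(words):
            if uncol[k] != _ZERO:
                lead = k
                break
        if lead < 0:
            break
        for k in range(words):
            avail[k] = uncol[k]
        cls_start = pos
        cls_max = 0.0
        k = lead
        while k < words:
            if avail[k] == _ZERO:
                k += 1
                continue
            v = (k << 6) + _ctz(avail[k])
            order[d, pos] = v
            pos += 1
            if w[v] > cls_max:
                cls_max = w[v]
            for k2 in range(words):
                avail[k2] &= ~adj[v, k2]
            avail[v >> 6] &= ~(_ONE << np.uint64(v & 63))
            uncol[v >> 6] &= ~(_ONE << np.uint64(v & 63))
            if k > (v >> 6):
                k = v >> 6
        cum += cls_max
        for i in range(cls_start, pos):
            bounds[d, i] = cum
    cnt[d] = pos


def solve_numba(adj_masks: list[int], weights: list[float],
                timeout: float | None, initial=()):
    """Run the compiled search on python-int bitset adjacency."""
    n = len(adj_masks)
    words = max(1, (n + 63) // 64)
    adj = np.zeros((n, words), np.uint64)
    full = (1 << 64) - 1
    for v, m in enumerate(adj_masks):
        k = 0
        while m:
            adj[v, k] = np.uint64(m & full)
            m >>= 64
            k += 1
    w = np.asarray(weights, dtype=np.float64)
    deadline = -1.0 if timeout is None else time.monotonic() + timeout
    mask0 = np.zeros(words, np.uint64)
    best0 = 0.0
    for v in initial:
        mask0[v >> 6] |= np.uint64(1) << np.uint64(v & 63)
        best0 += w[v]
    best_mask, best, nodes, timed_out = _solve(adj, w, deadline, best0, mask0)
    out = set()
    for k in range(words):
        m = int(best_mask[k])
        while m:
            low = m & -m
            out.add(k * 64 + low.bit_length() - 1)
            m ^= low
    return frozenset(out), float(best), int(nodes), bool(timed_out)
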