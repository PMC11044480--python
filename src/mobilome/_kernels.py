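"""Numba inner loops: banded affine (Gotoh) alignment and seed chaining.

These kernels are the hot path of the built-in aligner; everything around
them (seeding, record building, I/O) is plain numpy/Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**30)

# op codes used in raw column arrays
OP_EQ = 0  # '='
OP_X = 1   # 'X'
OP_I = 2   # 'I'  consumes query
OP_D = 3   # 'D'  consumes target


@njit(cache=True)
def banded_global(a, b, band, match, mismatch, gap_open, gap_extend):
    """Banded global affine alignment of code arrays ``a`` (query) vs ``b``.

    The band always covers both the (0,0) and (la,lb) corners.  A length-L
    gap costs ``gap_open + gap_extend*L``.  Tie-break prefers diagonal,
    then target-gap (D), then query-gap (I), so results are deterministic.

    Returns ``(ops, score)`` where ``ops`` is an int8 array of alignment
    columns in forward order.
    """
    la = a.shape[0]
    lb = b.shape[0]
    lo = min(0, lb - la) - band
    hi = max(0, lb - la) + band
    W = hi - lo + 1

    M = np.full((la + 1, W), NEG, dtype=np.int32)
    X = np.full((la + 1, W), NEG, dtype=np.int32)  # gap in query (consumes b) -> 'D'
    Y = np.full((la + 1, W), NEG, dtype=np.int32)  # gap in target (consumes a) -> 'I'
    pM = np.zeros((la + 1, W), dtype=np.uint8)
    pX = np.zeros((la + 1, W), dtype=np.uint8)
    pY = np.zeros((la + 1, W), dtype=np.uint8)

    go = gap_open + gap_extend  # cost of opening a 1-column gap

    # row 0
    M[0, -lo] = 0
    jmax0 = min(lb, hi)
    for j in range(1, jmax0 + 1):
        c = j - lo
        X[0, c] = -(gap_open + gap_extend * j)
        pX[0, c] = 0 if j == 1 else 1
    # column 0
    imax0 = min(la, -lo)
    for i in range(1, imax0 + 1):
        c = -i - lo
        Y[i, c] = -(gap_open + gap_extend * i)
        pY[i, c] = 0 if i == 1 else 2

    for i in range(1, la + 1):
        jlow = max(1, i + lo)
        jhigh = min(lb, i + hi)
        ai = a[i - 1]
        for j in range(jlow, jhigh + 1):
            c = j - i - lo
            # M from (i-1, j-1): same banded column
            bm = M[i - 1, c]
            pm = 0
            if X[i - 1, c] > bm:
                bm = X[i - 1, c]
                pm = 1
            if Y[i - 1, c] > bm:
                bm = Y[i - 1, c]
                pm = 2
            if bm > NEG:
                s = match if ai == b[j - 1] else mismatch
                M[i, c] = bm + s
                pM[i, c] = pm
            # X from (i, j-1): banded column c-1, same row
            if c - 1 >= 0:
                bx = M[i, c - 1] - go
                px = 0
                if X[i, c - 1] - gap_extend > bx:
                    bx = X[i, c - 1] - gap_extend
                    px = 1
                if Y[i, c - 1] - go > bx:
                    bx = Y[i, c - 1] - go
                    px = 2
                if bx > NEG // 2:
                    X[i, c] = bx
                    pX[i, c] = px
            # Y from (i-1, j): banded column c+1, previous row
            if c + 1 < W:
                by = M[i - 1, c + 1] - go
                py = 0
                if X[i - 1, c + 1] - go > by:
                    by = X[i - 1, c + 1] - go
                    py = 1
                if Y[i - 1, c + 1] - gap_extend > by:
                    by = Y[i - 1, c + 1] - gap_extend
                    py = 2
                if by > NEG // 2:
                    Y[i, c] = by
                    pY[i, c] = py

    cend = lb - la - lo
    state = 0
    best = M[la, cend]
    if X[la, cend] > best:
        best = X[la, cend]
        state = 1
    if Y[la, cend] > best:
        best = Y[la, cend]
        state = 2
    score = best

    ops = np.empty(la + lb, dtype=np.int8)
    pos = la + lb
    i = la
    j = lb
    while i > 0 or j > 0:
        c = j - i - lo
        pos -= 1
        if state == 0:
            ops[pos] = OP_EQ if a[i - 1] == b[j - 1] else OP_X
            state = pM[i, c]
            i -= 1
            j -= 1
        elif state == 1:
            ops[pos] = OP_D
            state = pX[i, c]
            j -= 1
        else:
            ops[pos] = OP_I
            state = pY[i, c]
            i -= 1
    return ops[pos:], score


@njit(cache=True)
def lookup_hits(keys, pos, bucket_starts, shift, qkeys, qpos, max_occ):
    """Seed lookup: binary search of query k-mer keys in the sorted index.

    ``bucket_starts`` bounds the search range by the high bits of the key
    so each lookup touches a short, cache-friendly slice.  K-mers with more
    than ``max_occ`` reference occurrences are skipped as repeats.
    Returns (query_positions, target_positions) hit arrays.
    """
    nq = qkeys.shape[0]
    total = 0
    los = np.empty(nq, dtype=np.int64)
    his = np.empty(nq, dtype=np.int64)
    for i in range(nq):
        b = qkeys[i] >> shift
        lo = bucket_starts[b]
        hi = bucket_starts[b + 1]
        # lower bound
        l, h = lo, hi
        while l < h:
            m = (l + h) // 2
            if keys[m] < qkeys[i]:
                l = m + 1
            else:
                h = m
        start = l
        h = hi
        while l < h:
            m = (l + h) // 2
            if keys[m] <= qkeys[i]:
                l = m + 1
            else:
                h = m
        cnt = l - start
        if 0 < cnt <= max_occ:
            los[i] = start
            his[i] = l
            total += cnt
        else:
            los[i] = 0
            his[i] = 0
    hq = np.empty(total, dtype=np.int64)
    ht = np.empty(total, dtype=np.int64)
    out = 0
    for i in range(nq):
        for j in range(los[i], his[i]):
            hq[out] = qpos[i]
            ht[out] = pos[j]
            out += 1
    return hq, ht


@njit(cache=True)
def chain_dp(qpos, tpos, max_gap, band, max_pred):
    """Co-linear chaining DP over seed hits sorted by (qpos, tpos).

    dp[i] = length of the best chain ending at hit i; parent gives the
    predecessor hit or -1.  A predecessor must advance both coordinates,
    each by at most ``max_gap``, with diagonal drift at most ``band``.

    Predecessor lookup is O(1) through a per-diagonal-bucket registry
    (bucket width = ``band``): a chain's predecessor lives on a nearby
    diagonal, so checking the most recent and the best hit of the three
    neighbouring buckets suffices — and stays fast even when the target
    holds many tandem copies of the query (each copy occupies its own
    diagonal).  ``max_pred`` is unused but kept for signature stability.
    """
    n = qpos.shape[0]
    dp = np.ones(n, dtype=np.int32)
    parent = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return dp, parent
    dmin = tpos[0] - qpos[0]
    dmax = dmin
    for i in range(n):
        d = tpos[i] - qpos[i]
        if d < dmin:
            dmin = d
        if d > dmax:
            dmax = d
    nb = (dmax - dmin) // band + 3
    last = np.full(nb, -1, dtype=np.int64)   # most recent hit per bucket
    besti = np.full(nb, -1, dtype=np.int64)  # best-dp hit per bucket
    for i in range(n):
        di = tpos[i] - qpos[i]
        b = (di - dmin) // band + 1
        best = np.int32(1)
        for bb in range(b - 1, b + 2):
            for j in (last[bb], besti[bb]):
                if j < 0:
                    continue
                dq = qpos[i] - qpos[j]
                dt = tpos[i] - tpos[j]
                if (0 < dq <= max_gap and 0 < dt <= max_gap
                        and abs(dt - dq) <= band):
                    cand = dp[j] + np.int32(1)
                    if cand > best:
                        best = cand
                        parent[i] = j
        dp[i] = best
        last[b] = i
        if besti[b] < 0 or dp[i] >= dp[besti[b]]:
            besti[b] = i
    return dp, parent
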