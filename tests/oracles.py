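"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately simple and slow: full-matrix dynamic
programming, exact rational arithmetic, O(n*m) scans.  None of it shares
code with the package internals.
"""

from fractions import Fraction
from math import comb

import numpy as np

NEG = -(10 ** 9)


def affine_nw(a: str, b: str, match=1, mismatch=-2, gap_open=2,
              gap_extend=1):
    """Unbanded global affine (Gotoh) alignment.

    Returns (matches, columns, score).  A length-L gap costs
    open + extend*L.  Tie-breaks prefer diagonal, then gap-in-query
    consuming the target, then gap consuming the query — the conventional
    deterministic order.
    """
    la, lb = len(a), len(b)
    go = gap_open + gap_extend
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # consumes b ('D')
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # consumes a ('I')
    pM = [[0] * (lb + 1) for _ in range(la + 1)]
    pX = [[0] * (lb + 1) for _ in range(la + 1)]
    pY = [[0] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0
    for j in range(1, lb + 1):
        X[0][j] = -(gap_open + gap_extend * j)
        pX[0][j] = 0 if j == 1 else 1
    for i in range(1, la + 1):
        Y[i][0] = -(gap_open + gap_extend * i)
        pY[i][0] = 0 if i == 1 else 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            best, ptr = M[i - 1][j - 1], 0
            if X[i - 1][j - 1] > best:
                best, ptr = X[i - 1][j - 1], 1
            if Y[i - 1][j - 1] > best:
                best, ptr = Y[i - 1][j - 1], 2
            if best > NEG:
                M[i][j] = best + s
                pM[i][j] = ptr
            best, ptr = M[i][j - 1] - go, 0
            if X[i][j - 1] - gap_extend > best:
                best, ptr = X[i][j - 1] - gap_extend, 1
            if Y[i][j - 1] - go > best:
                best, ptr = Y[i][j - 1] - go, 2
            if best > NEG // 2:
                X[i][j] = best
                pX[i][j] = ptr
            best, ptr = M[i - 1][j] - go, 0
            if X[i - 1][j] - go > best:
                best, ptr = X[i - 1][j] - go, 1
            if Y[i - 1][j] - gap_extend > best:
                best, ptr = Y[i - 1][j] - gap_extend, 2
            if best > NEG // 2:
                Y[i][j] = best
                pY[i][j] = ptr
    state, score = 0, M[la][lb]
    if X[la][lb] > score:
        state, score = 1, X[la][lb]
    if Y[la][lb] > score:
        state, score = 2, Y[la][lb]
    i, j = la, lb
    matches = cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == 0:
            if a[i - 1] == b[j - 1]:
                matches += 1
            state = pM[i][j]
            i, j = i - 1, j - 1
        elif state == 1:
            state = pX[i][j]
            j -= 1
        else:
            state = pY[i][j]
            i -= 1
    return matches, cols, score


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for table [[a, b], [c, d]].

    Sums hypergeometric pmfs of all tables (with the same margins) whose
    probability does not exceed the observed one, using exact rational
    arithmetic; the conventional (1 + 1e-7) relative tolerance guards the
    tie comparison.
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(col1, k) * comb(n - col1, row1 - k), denom)

    kmin = max(0, row1 - (n - col1))
    kmax = min(row1, col1)
    observed = pmf(a)
    cutoff = observed * Fraction(10_000_001, 10_000_000)
    total = Fraction(0)
    for k in range(kmin, kmax + 1):
        p = pmf(k)
        if p <= cutoff:
            total += p
    return float(min(total, Fraction(1)))


def count_overlaps(read_intervals, elements, min_overlap):
    """Naive O(n*m) largest-overlap read counting.

    ``read_intervals``: list of (chrom, start, end) primary intervals;
    ``elements``: list of (id, chrom, start, end) sorted by position.
    """
    counts = {e[0]: 0 for e in elements}
    unassigned = 0
    for chrom, s, e in read_intervals:
        best, best_ov = None, 0
        for eid, ec, es, ee in elements:
            if ec != chrom:
                continue
            ov = min(e, ee) - max(s, es)
            if ov > best_ov:
                best, best_ov = eid, ov
        if best is not None and best_ov >= min_overlap:
            counts[best] += 1
        else:
            unassigned += 1
    return counts, unassigned


_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}


def orf_scan(seq: str, min_codons: int):
    """Brute-force 6-frame ORF scan; returns sorted (frame, start, end,
    codons) like the implementation contract."""
    out = []
    n = len(seq)
    for strand in (1, -1):
        s = seq if strand == 1 else seq.translate(_COMP)[::-1]
        for f in range(3):
            start = None
            for i in range(f, n - 2, 3):
                codon = s[i:i + 3]
                if codon == "ATG" and start is None:
                    start = i
                elif codon in _STOPS:
                    if start is not None:
                        codons = (i - start) // 3
                        if codons >= min_codons:
                            a, b = start, i + 3
                            if strand == -1:
                                a, b = n - b, n - a
                            out.append((strand * (f + 1), a, b, codons))
                    start = None
    out.sort(key=lambda o: (-o[3], o[1], o[0]))
    return out


def segment_runs(density, median, fold, min_windows, max_gap):
    """Brute-force introgression run scan over a density array."""
    above = [d >= fold * median for d in density]
    segs = []
    i, n = 0, len(above)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j, last, gap = i, i, 0
        while j + 1 < n:
            if above[j + 1]:
                j += 1
                last = j
                gap = 0
            elif gap < max_gap:
                j += 1
                gap += 1
            else:
                break
        j = last
        if j - i + 1 >= min_windows:
            segs.append((i, j + 1))
        i = j + 1
    return segs


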