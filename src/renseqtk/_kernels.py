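"""Numba DP kernels for the alignment engine.

Sequences are int8 code arrays (A=0, C=1, G=2, T=3, N=4). N never matches,
not even another N. Affine gap scoring charges ``gap_open`` for the first
base of a gap and ``gap_extend`` for each additional base (so a length-L gap
costs gap_open + (L-1)*gap_extend), which requires gap_open <= gap_extend.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2 ** 30))


@njit(cache=True)
def affine_band_dp(a, b, diag, band, match, mismatch, gap_open, gap_extend):
    """Banded affine-gap local DP (Gotoh) over a diagonal corridor.

    Cell (i, w) corresponds to (i, j) with j = i + diag - band + w. With a
    corridor covering the full matrix this is exhaustive Smith-Waterman.
    Returns the H/E/F band matrices and the best cell.
    """
    m = a.shape[0]
    n = b.shape[0]
    W = 2 * band + 1
    H = np.full((m + 1, W), NEG, np.int32)
    E = np.full((m + 1, W), NEG, np.int32)
    F = np.full((m + 1, W), NEG, np.int32)
    best = np.int32(0)
    bi = 0
    bw = 0
    for i in range(m + 1):
        jlo = i + diag - band
        for w in range(W):
            j = jlo + w
            if j < 0 or j > n:
                continue
            if i == 0 or j == 0:
                H[i, w] = 0
                continue
            e = NEG
            if w - 1 >= 0:
                if H[i, w - 1] > NEG:
                    e = H[i, w - 1] + gap_open
                if E[i, w - 1] > NEG and E[i, w - 1] + gap_extend > e:
                    e = E[i, w - 1] + gap_extend
            f = NEG
            if w + 1 < W:
                if H[i - 1, w + 1] > NEG:
                    f = H[i - 1, w + 1] + gap_open
                if F[i - 1, w + 1] > NEG and F[i - 1, w + 1] + gap_extend > f:
                    f = F[i - 1, w + 1] + gap_extend
            d = NEG
            if H[i - 1, w] > NEG:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    d = H[i - 1, w] + match
                else:
                    d = H[i - 1, w] + mismatch
            h = np.int32(0)
            if d > h:
                h = d
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, w] = h
            E[i, w] = e
            F[i, w] = f
            if h > best:
                best = h
                bi = i
                bw = w
    return H, E, F, best, bi, bw


@njit(cache=True)
def semiglobal_end_row(p, t):
    """Min edits of the full pattern vs a window of ``t`` ending at j.

    Pattern ends anchored, text start free: returns row[j] = min over s of
    editdist(p, t[s:j]) for j = 0..len(t).
    """
    m = p.shape[0]
    n = t.shape[0]
    prev = np.zeros(n + 1, np.int32)
    cur = np.zeros(n + 1, np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        for j in range(1, n + 1):
            c = prev[j - 1]
            if p[i - 1] != t[j - 1] or p[i - 1] >= 4:
                c += 1
            if prev[j] + 1 < c:
                c = prev[j] + 1
            if cur[j - 1] + 1 < c:
                c = cur[j - 1] + 1
            cur[j] = c
        tmp = prev
        prev = cur
        cur = tmp
    return prev.copy()


@njit(cache=True)
def nw_last_row(p, t):
    """Global edit distance of ``p`` vs every prefix of ``t``.

    Returns row[j] = editdist(p, t[:j]) for j = 0..len(t).
    """
    m = p.shape[0]
    n = t.shape[0]
    prev = np.empty(n + 1, np.int32)
    cur = np.empty(n + 1, np.int32)
    for j in range(n + 1):
        prev[j] = j
    for i in range(1, m + 1):
        cur[0] = i
        for j in range(1, n + 1):
            c = prev[j - 1]
            if p[i - 1] != t[j - 1] or p[i - 1] >= 4:
                c += 1
            if prev[j] + 1 < c:
                c = prev[j] + 1
            if cur[j - 1] + 1 < c:
                c = cur[j - 1] + 1
            cur[j] = c
        tmp = prev
        prev = cur
        cur = tmp
    return prev.copy()
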