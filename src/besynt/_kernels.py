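"""Numba kernels for banded affine-gap Smith-Waterman.

The band is expressed on the anti-diagonal offset d = j - i (1-based DP
coordinates: i indexes the query, j the subject). Column k of the internal
matrices corresponds to j = i + d_lo + k, so the diagonal predecessor of a
cell sits at the same k in the previous row, the left predecessor at k - 1
in the same row and the up predecessor at k + 1 in the previous row.

Gap costs are positive magnitudes; the first gap character costs
``gap_open`` and each further character ``gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(2**28)


@njit(cache=True)
def banded_sw(q, s, sub, gap_open, gap_extend, d_lo, d_hi):
    """Banded local alignment. Returns (best, bi, bk, H, E, F).

    ``best`` is the optimal local score within the band, ending at DP cell
    (bi, j = bi + d_lo + bk). H/E/F are the filled matrices (int32), kept
    for the Python-side traceback.
    """
    m = q.shape[0]
    n = s.shape[0]
    W = d_hi - d_lo + 1
    H = np.zeros((m + 1, W), np.int32)
    E = np.full((m + 1, W), NEG, np.int32)
    F = np.full((m + 1, W), NEG, np.int32)
    best = 0
    bi = 0
    bk = 0
    for i in range(1, m + 1):
        jlo = i + d_lo
        if jlo < 1:
            jlo = 1
        jhi = i + d_hi
        if jhi > n:
            jhi = n
        qi = q[i - 1]
        for j in range(jlo, jhi + 1):
            k = j - i - d_lo
            e = NEG
            if k >= 1:
                a = H[i, k - 1] - gap_open
                b = E[i, k - 1] - gap_extend
                e = a if a > b else b
            f = NEG
            if k + 1 < W:
                a = H[i - 1, k + 1] - gap_open
                b = F[i - 1, k + 1] - gap_extend
                f = a if a > b else b
            h = H[i - 1, k] + sub[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, k] = h
            E[i, k] = e
            F[i, k] = f
            if h > best:
                best = h
                bi = i
                bk = k
    return best, bi, bk, H, E, F


@njit(cache=True)
def banded_sw_score(q, s, sub, gap_open, gap_extend, d_lo, d_hi):
    """Score-only variant with O(band) memory; used for quick screening."""
    m = q.shape[0]
    n = s.shape[0]
    W = d_hi - d_lo + 1
    Hp = np.zeros(W, np.int32)
    Fp = np.full(W, NEG, np.int32)
    best = 0
    for i in range(1, m + 1):
        Hc = np.zeros(W, np.int32)
        Fc = np.full(W, NEG, np.int32)
        Ec = np.full(W, NEG, np.int32)
        jlo = i + d_lo
        if jlo < 1:
            jlo = 1
        jhi = i + d_hi
        if jhi > n:
            jhi = n
        qi = q[i - 1]
        for j in range(jlo, jhi + 1):
            k = j - i - d_lo
            e = NEG
            if k >= 1:
                a = Hc[k - 1] - gap_open
                b = Ec[k - 1] - gap_extend
                e = a if a > b else b
            f = NEG
            if k + 1 < W:
                a = Hp[k + 1] - gap_open
                b = Fp[k + 1] - gap_extend
                f = a if a > b else b
            h = Hp[k] + sub[qi, s[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hc[k] = h
            Ec[k] = e
            Fc[k] = f
            if h > best:
                best = h
        Hp = Hc
        Fp = Fc
    return best
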