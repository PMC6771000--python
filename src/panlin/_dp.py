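"""Affine-gap dynamic-programming kernels (Gotoh) compiled with numba.

A gap of length k costs gap_open + k * gap_extend.  State encoding for the
pointer matrices: 0 = match/mismatch (M), 1 = gap in b consuming a (X),
2 = gap in a consuming b (Y), 3 = local-alignment fresh start.
Tie-breaking is "high road": prefer M, then X, then Y.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def gotoh_global(ai, bi, sub, go, ge):  # pragma: no cover - exercised via wrapper
    n = ai.shape[0]
    m = bi.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + ge * i)
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(go + ge * j)
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[ai[i - 1], bi[j - 1]]
            v = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > v:
                v = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > v:
                v = Y[i - 1, j - 1]
                p = 2
            M[i, j] = v + s
            pM[i, j] = p

            v = M[i - 1, j] - go - ge
            p = 0
            if X[i - 1, j] - ge > v:
                v = X[i - 1, j] - ge
                p = 1
            if Y[i - 1, j] - go - ge > v:
                v = Y[i - 1, j] - go - ge
                p = 2
            X[i, j] = v
            pX[i, j] = p

            v = M[i, j - 1] - go - ge
            p = 0
            if X[i, j - 1] - go - ge > v:
                v = X[i, j - 1] - go - ge
                p = 1
            if Y[i, j - 1] - ge > v:
                v = Y[i, j - 1] - ge
                p = 2
            Y[i, j] = v
            pY[i, j] = p
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    return score, state, pM, pX, pY


@njit(cache=True)
def gotoh_local(ai, bi, sub, go, ge):  # pragma: no cover - exercised via wrapper
    n = ai.shape[0]
    m = bi.shape[0]
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    pM = np.zeros((n + 1, m + 1), np.int8)
    pX = np.zeros((n + 1, m + 1), np.int8)
    pY = np.zeros((n + 1, m + 1), np.int8)
    best = NEG
    bi_ = 0
    bj_ = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[ai[i - 1], bi[j - 1]]
            v = 0.0
            p = 3  # fresh start
            if M[i - 1, j - 1] > v:
                v = M[i - 1, j - 1]
                p = 0
            if X[i - 1, j - 1] > v:
                v = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > v:
                v = Y[i - 1, j - 1]
                p = 2
            M[i, j] = v + s
            pM[i, j] = p
            if M[i, j] > best:
                best = M[i, j]
                bi_ = i
                bj_ = j

            v = M[i - 1, j] - go - ge
            p = 0
            if X[i - 1, j] - ge > v:
                v = X[i - 1, j] - ge
                p = 1
            if Y[i - 1, j] - go - ge > v:
                v = Y[i - 1, j] - go - ge
                p = 2
            X[i, j] = v
            pX[i, j] = p

            v = M[i, j - 1] - go - ge
            p = 0
            if X[i, j - 1] - go - ge > v:
                v = X[i, j - 1] - go - ge
                p = 1
            if Y[i, j - 1] - ge > v:
                v = Y[i, j - 1] - ge
                p = 2
            Y[i, j] = v
            pY[i, j] = p
    return best, bi_, bj_, pM, pX, pY
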