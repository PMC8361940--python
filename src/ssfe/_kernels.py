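"""Numba kernel for global affine-gap dynamic programming.

One kernel serves both sequence-sequence and profile-profile alignment:
the caller supplies a dense pairing-score matrix ``S`` (``S[i, j]`` = score
of putting unit *i* of the first series against unit *j* of the second)
and positive gap penalties. A gap of length L costs
``gap_open + (L - 1) * gap_extend``; terminal gaps are penalized (true
global alignment).

Traceback is deterministic: on ties the diagonal move wins over the
up move (gap in the second series), which wins over the left move.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# moves emitted by the traceback
DIAG, UP, LEFT = 0, 1, 2

_NEG = -1e30


@njit(cache=True)
def affine_dp(S, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in second series (consume first; "up")
    Y = np.full((n + 1, m + 1), _NEG)  # gap in first series (consume second; "left")
    pm = np.zeros((n + 1, m + 1), np.int8)
    px = np.zeros((n + 1, m + 1), np.int8)
    py = np.zeros((n + 1, m + 1), np.int8)

    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        px[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        py[0, j] = 0 if j == 1 else 2

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: ties prefer M, then X, then Y (strict > keeps order)
            best = M[i - 1, j - 1]
            arg = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                arg = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                arg = 2
            M[i, j] = best + S[i - 1, j - 1]
            pm[i, j] = arg

            best = M[i - 1, j] - gap_open
            arg = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                arg = 1
            if Y[i - 1, j] - gap_open > best:
                best = Y[i - 1, j] - gap_open
                arg = 2
            X[i, j] = best
            px[i, j] = arg

            best = M[i, j - 1] - gap_open
            arg = 0
            if X[i, j - 1] - gap_open > best:
                best = X[i, j - 1] - gap_open
                arg = 1
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                arg = 2
            Y[i, j] = best
            py[i, j] = arg

    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2

    ops = np.empty(n + m, np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            state = pm[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = px[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = py[i, j]
            j -= 1
    return score, ops[k:]
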