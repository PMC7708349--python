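"""Low-level dynamic-programming kernels (numba-compiled).

Two primitives power the whole package:

* a semi-global edit-distance scan used to place short anchor probes on
  haplotype-length sequences, and
* an affine-gap global aligner over an arbitrary integer-coded alphabet,
  driven by a precomputed column-score matrix so the same kernel serves
  pairwise symbol alignment, pairwise DNA alignment and profile-profile
  merges.

Affine convention: a gap run of length k costs ``gap_open + k * gap_extend``
(both numbers are <= 0, scores are maximised).  Traceback ties are broken
deterministically: diagonal, then up (gap in the second sequence), then left.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1.0e30


@njit(cache=True)
def semiglobal_end_costs(text: np.ndarray, probe: np.ndarray) -> np.ndarray:
    """Edit cost of the best alignment of the full probe ending at each text offset.

    ``text`` and ``probe`` are uint8 code arrays.  Returns an int32 array ``c``
    of length ``len(text) + 1`` where ``c[j]`` is the minimum unit-cost edit
    distance between ``probe`` and any substring of ``text`` ending at ``j``
    (0-based exclusive).  The start of the window is free (semi-global).
    """
    n = text.shape[0]
    m = probe.shape[0]
    prev = np.zeros(n + 1, dtype=np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur[0] = i
        pi = probe[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (0 if text[j - 1] == pi else 1)
            dele = prev[j] + 1
            ins = cur[j - 1] + 1
            best = sub
            if dele < best:
                best = dele
            if ins < best:
                best = ins
            cur[j] = best
        prev, cur = cur, prev
    return prev.copy()


@njit(cache=True)
def _affine_fill(S: np.ndarray, go: float, ge: float):
    """Fill Gotoh matrices for column-score matrix S (n1 x n2); return
    (score, final_state, ptrM, ptrX, ptrY) where ptr values encode the
    predecessor state (0=M diag, 1=X up, 2=Y left)."""
    n1, n2 = S.shape
    M = np.full((n1 + 1, n2 + 1), NEG_INF)
    X = np.full((n1 + 1, n2 + 1), NEG_INF)
    Y = np.full((n1 + 1, n2 + 1), NEG_INF)
    ptrM = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptrX = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    ptrY = np.zeros((n1 + 1, n2 + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        if i == 1:
            X[i, 0] = go + ge
            ptrX[i, 0] = 0
        else:
            X[i, 0] = X[i - 1, 0] + ge
            ptrX[i, 0] = 1
    for j in range(1, n2 + 1):
        if j == 1:
            Y[0, j] = go + ge
            ptrY[0, j] = 0
        else:
            Y[0, j] = Y[0, j - 1] + ge
            ptrY[0, j] = 2
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            # M: diagonal step; predecessor preference M > X > Y
            bm = M[i - 1, j - 1]
            pm = 0
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                pm = 1
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                pm = 2
            M[i, j] = bm + S[i - 1, j - 1]
            ptrM[i, j] = pm
            # X: consume row i (gap in second sequence)
            bx = M[i - 1, j] + go + ge
            px = 0
            if X[i - 1, j] + ge > bx:
                bx = X[i - 1, j] + ge
                px = 1
            if Y[i - 1, j] + go + ge > bx:
                bx = Y[i - 1, j] + go + ge
                px = 2
            X[i, j] = bx
            ptrX[i, j] = px
            # Y: consume column j (gap in first sequence)
            by = M[i, j - 1] + go + ge
            py = 0
            if X[i, j - 1] + go + ge > by:
                by = X[i, j - 1] + go + ge
                py = 1
            if Y[i, j - 1] + ge > by:
                by = Y[i, j - 1] + ge
                py = 2
            Y[i, j] = by
            ptrY[i, j] = py
    score = M[n1, n2]
    state = 0
    if X[n1, n2] > score:
        score = X[n1, n2]
        state = 1
    if Y[n1, n2] > score:
        score = Y[n1, n2]
        state = 2
    return score, state, ptrM, ptrX, ptrY


@njit(cache=True)
def affine_align_ops(S: np.ndarray, go: float, ge: float):
    """Optimal global affine alignment for score matrix S.

    Returns ``(score, ops)`` where ``ops`` is an int8 array over alignment
    columns, left to right: 0 = match (consume one of each), 1 = consume a
    row of the first input only, 2 = consume a column of the second only.
    """
    n1, n2 = S.shape
    score, state, ptrM, ptrX, ptrY = _affine_fill(S, go, ge)
    ops = np.empty(n1 + n2, dtype=np.int8)
    k = 0
    i, j = n1, n2
    while i > 0 or j > 0:
        if state == 0:
            ops[k] = 0
            state = ptrM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            state = ptrX[i, j]
            i -= 1
        else:
            ops[k] = 2
            state = ptrY[i, j]
            j -= 1
        k += 1
    return score, ops[:k][::-1].copy()


def pair_score_matrix(a: np.ndarray, b: np.ndarray, match: float, mismatch: float) -> np.ndarray:
    """Identity scoring matrix for two integer-coded sequences."""
    eq = a[:, None] == b[None, :]
    return np.where(eq, float(match), float(mismatch))
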