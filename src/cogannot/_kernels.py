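"""Numba Smith-Waterman kernels (affine gaps, local).

Gap convention is BLAST-like: a gap of length k costs
``-(gap_open + k * gap_extend_magnitude)``; kernels take ``first_gap``
(score of the first gapped column, i.e. gap_open + gap_extend) and
``ext_gap`` (score of each further gapped column).

Sequences arrive as int64 index arrays into the scoring matrix; the
matrix must cover every index that appears.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def sw_score(q, s, mat, first_gap, ext_gap):
    """Best local-alignment score (linear memory, score only)."""
    n = s.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, -(10 ** 9), dtype=np.int64)
    best = 0
    for i in range(1, q.shape[0] + 1):
        diag = 0
        F = -(10 ** 9)
        qi = q[i - 1]
        for j in range(1, n + 1):
            E[j] = max(H[j] + first_gap, E[j] + ext_gap)
            F = max(H[j - 1] + first_gap, F + ext_gap)
            h = diag + mat[qi, s[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=False)
def sw_align(q, s, mat, first_gap, ext_gap):
    """Full-matrix local alignment with traceback.

    Returns ``(score, q_start, q_end, s_start, s_end, n_matches,
    n_columns)`` with 1-based inclusive coordinates; all zeros when no
    positive-scoring alignment exists.  Ties are broken toward the
    smallest (q_end, s_end) cell in row-major order; the traceback
    prefers diagonal moves, then gaps in the query, then gaps in the
    subject, which makes the reported alignment deterministic.
    """
    m = q.shape[0]
    n = s.shape[0]
    NEG = -(10 ** 9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] + first_gap, E[i, j - 1] + ext_gap)
            F[i, j] = max(H[i - 1, j] + first_gap, F[i - 1, j] + ext_gap)
            h = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback from (bi, bj) in state H
    i = bi
    j = bj
    n_matches = 0
    n_columns = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]:
            if q[i - 1] == s[j - 1]:
                n_matches += 1
            n_columns += 1
            i -= 1
            j -= 1
        elif h == E[i, j]:
            # gap in query: consume subject columns
            while True:
                n_columns += 1
                if E[i, j] == H[i, j - 1] + first_gap:
                    j -= 1
                    break
                j -= 1
        else:
            # gap in subject: consume query rows
            while True:
                n_columns += 1
                if F[i, j] == H[i - 1, j] + first_gap:
                    i -= 1
                    break
                i -= 1
    return best, i + 1, bi, j + 1, bj, n_matches, n_columns
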