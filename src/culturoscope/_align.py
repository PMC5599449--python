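"""Numba kernel for affine-gap Needleman-Wunsch with free end gaps.

The dynamic program keeps the usual three state matrices:

``M``  -- a[i-1] aligned against b[j-1] (match or mismatch),
``X``  -- gap in ``b`` (a base of ``a`` against ``-``),
``Y``  -- gap in ``a`` (a base of ``b`` against ``-``).

Leading and trailing gaps are free (semi-global alignment): the first
row/column of the gap states is initialised to zero and the optimum is
taken over the last row and last column.  A gap of length L scores
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(2**30))


@njit(cache=True)
def fill_matrices(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = 0  # free leading gap in b
    for j in range(1, m + 1):
        Y[0, j] = 0  # free leading gap in a
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai & b[j - 1]) != 0 else mismatch
            best_prev = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best_prev:
                best_prev = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best_prev:
                best_prev = Y[i - 1, j - 1]
            M[i, j] = s + best_prev

            v = M[i - 1, j] + gap_open
            if Y[i - 1, j] + gap_open > v:
                v = Y[i - 1, j] + gap_open
            if X[i - 1, j] + gap_extend > v:
                v = X[i - 1, j] + gap_extend
            X[i, j] = v

            v = M[i, j - 1] + gap_open
            if X[i, j - 1] + gap_open > v:
                v = X[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_extend > v:
                v = Y[i, j - 1] + gap_extend
            Y[i, j] = v
    return M, X, Y
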