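"""Numba-jitted affine-gap Smith-Waterman kernel with deterministic traceback.

Scoring: a match scores ``match``; a mismatch (or any column involving N)
scores ``mismatch``; a gap of length L costs ``gap_open + (L - 1) * gap_extend``.

Determinism: the end cell is the maximal-score cell with the smallest target
index, then the smallest query index. Traceback prefers diagonal moves over
query-consuming gaps (I) over target-consuming gaps (D), and closes gaps as
early as possible. The pure-Python oracle in the test suite implements the
identical rule, so scores AND per-alignment mismatch counts are comparable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 28)

# traceback op codes
OP_EQ = 0  # '='
OP_X = 1   # 'X'
OP_I = 2   # 'I' (consumes query)
OP_D = 3   # 'D' (consumes target)


@njit(cache=True)
def sw_align(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG, np.int32)
    F = np.full((m + 1, n + 1), NEG, np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            tj = t[j - 1]
            s = match if (qi == tj and qi < 4 and tj < 4) else mismatch
            e = H[i - 1, j] + gap_open
            if E[i - 1, j] + gap_extend > e:
                e = E[i - 1, j] + gap_extend
            f = H[i, j - 1] + gap_open
            if F[i, j - 1] + gap_extend > f:
                f = F[i, j - 1] + gap_extend
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best or (h == best and h > 0 and (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j

    ops = np.empty(m + n, np.uint8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E (gap consuming query), 2 = F (gap consuming target)
    if best > 0:
        while True:
            if state == 0:
                h = H[i, j]
                if h == 0:
                    break
                qi = q[i - 1]
                tj = t[j - 1]
                s = match if (qi == tj and qi < 4 and tj < 4) else mismatch
                if h == H[i - 1, j - 1] + s:
                    ops[k] = OP_EQ if (qi == tj and qi < 4 and tj < 4) else OP_X
                    k += 1
                    i -= 1
                    j -= 1
                elif h == E[i, j]:
                    state = 1
                else:
                    state = 2
            elif state == 1:
                ops[k] = OP_I
                k += 1
                if E[i, j] == H[i - 1, j] + gap_open:
                    state = 0
                i -= 1
            else:
                ops[k] = OP_D
                k += 1
                if F[i, j] == H[i, j - 1] + gap_open:
                    state = 0
                j -= 1
    return best, i, bi, j, bj, ops[:k][::-1].copy()
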