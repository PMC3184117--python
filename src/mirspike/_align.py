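"""Numba kernel for the mismatch-counting local alignment.

Smith-Waterman with linear gap costs, extended to track — lexicographically,
per cell — the best (score, fewest mismatches, largest aligned span) triple.
The span sum (aligned bases of A plus aligned bases of B) doubles as start
bookkeeping: start_a + start_b = end_a + end_b - span_sum, which is all the
overhang computation needs.

Cells are floored at the empty alignment (score 0, no mismatches, no span),
which also realizes the "prefer restart" rule on score ties.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Effective minus-infinity for a disabled gap move.
GAP_DISABLED = -1.0e30

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE[c] for c in seq], dtype=np.int8)


@njit(cache=False)
def sw_summary(a, b, match, mismatch, gap, count_indels):  # pragma: no cover - jit
    """Best local alignment of int8-encoded a vs b.

    Returns (score, mismatches, span_sum, columns, end_i, end_j); the empty
    alignment (all zeros) is returned when no positive-scoring alignment
    exists.  N (code 4) never matches, not even itself.
    """
    n = a.shape[0]
    m = b.shape[0]
    S = np.zeros((n + 1, m + 1))
    M = np.zeros((n + 1, m + 1), np.int64)
    P = np.zeros((n + 1, m + 1), np.int64)
    C = np.zeros((n + 1, m + 1), np.int64)
    bs = 0.0
    bm = 0
    bp = 0
    bc = 0
    bi = 0
    bj = 0
    indel_cost = 1 if count_indels else 0
    use_gaps = gap > GAP_DISABLED
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # floor: restart with the empty alignment
            cs = 0.0
            cm = 0
            cp = 0
            cc = 0
            bj_ = b[j - 1]
            eq = ai == bj_ and ai != 4
            ds = S[i - 1, j - 1] + (match if eq else mismatch)
            dm = M[i - 1, j - 1] + (0 if eq else 1)
            dp = P[i - 1, j - 1] + 2
            dc = C[i - 1, j - 1] + 1
            if ds > cs or (ds == cs and (dm < cm or (dm == cm and dp > cp))):
                cs, cm, cp, cc = ds, dm, dp, dc
            if use_gaps:
                us = S[i - 1, j] + gap
                um = M[i - 1, j] + indel_cost
                up = P[i - 1, j] + 1
                uc = C[i - 1, j] + 1
                if us > cs or (us == cs and (um < cm or (um == cm and up > cp))):
                    cs, cm, cp, cc = us, um, up, uc
                ls = S[i, j - 1] + gap
                lm = M[i, j - 1] + indel_cost
                lp = P[i, j - 1] + 1
                lc = C[i, j - 1] + 1
                if ls > cs or (ls == cs and (lm < cm or (lm == cm and lp > cp))):
                    cs, cm, cp, cc = ls, lm, lp, lc
            S[i, j] = cs
            M[i, j] = cm
            P[i, j] = cp
            C[i, j] = cc
            if cs > bs or (cs == bs and (cm < bm or (cm == bm and cp > bp))):
                bs, bm, bp, bc, bi, bj = cs, cm, cp, cc, i, j
    return bs, bm, bp, bc, bi, bj
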