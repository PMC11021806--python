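"""Affine-gap read-to-reference alignment kernel (Gotoh three-state DP).

Semantics: *global in the reference* (every reference base is consumed by a
match/mismatch or a deletion column), *semi-global in the read* (read bases
before the first and after the last reference-consuming column are
soft-clipped for free).  Scoring is bwa-like: match +1, mismatch -4, and a
gap of length L costs 6 + L (all scaled by 2 internally; see below for the
half-match wildcard columns).

Tie-breaking is fully deterministic: at equal score a diagonal (match or
mismatch) column is preferred over a gap, and a deletion over an insertion;
at the right boundary the end row with the larger read index wins ties
(least trailing clipping).  The pure-Python oracle in the test suite
implements the same rules independently.

Insertions can only occur between reference positions (j >= 1) and never
after the final reference base: terminal insertions are always represented
as soft clips instead.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Scoring is bwa-like (match +1, mismatch -4, gap of length L costs 6 + L),
# internally scaled by 2 so that degenerate reference columns can score half
# a match: an alignment that anchors real flank bases then beats one that
# slides an indel into or past a wildcard region, making indel placement at
# locus boundaries deterministic and data-driven.
MATCH = 2
MISMATCH = -8
GAP_OPEN = 12
GAP_EXTEND = 2
WILDMATCH = 1

#: Reference positions set to this code (ASCII 'N') match any read base with
#: the reduced (half-match) bonus.  Used for degenerate regions such as
#: barcode loci, whose reference content is a placeholder rather than an
#: expected sequence.
WILDCARD = 78

NEG = -(10**8)

# traceback states
S_M = 0  # diagonal (match/mismatch)
S_X = 1  # gap in read (reference base deleted)
S_Y = 2  # gap in reference (read base inserted)
S_START = 3  # free start in column 0

OP_DIAG = 0
OP_DEL = 1
OP_INS = 2


@njit(cache=True)
def _gotoh(read: np.ndarray, ref: np.ndarray):  # pragma: no cover - numba
    n = read.shape[0]
    m = ref.shape[0]
    GO = GAP_OPEN + GAP_EXTEND
    M = np.full((n + 1, m + 1), NEG, np.int32)
    X = np.full((n + 1, m + 1), NEG, np.int32)
    Y = np.full((n + 1, m + 1), NEG, np.int32)
    PM = np.zeros((n + 1, m + 1), np.int8)
    PX = np.zeros((n + 1, m + 1), np.int8)
    PY = np.zeros((n + 1, m + 1), np.int8)

    # row 0: only deletions of the reference prefix are possible
    X[0, 1] = -GO
    PX[0, 1] = S_START
    for j in range(2, m + 1):
        X[0, j] = X[0, j - 1] - GAP_EXTEND
        PX[0, j] = S_X

    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            rj = ref[j - 1]
            if rj == WILDCARD:
                s = WILDMATCH
            elif ri == rj:
                s = MATCH
            else:
                s = MISMATCH
            # M from (i-1, j-1); priority M > X > Y > START
            bm = M[i - 1, j - 1]
            pm = S_M
            if X[i - 1, j - 1] > bm:
                bm = X[i - 1, j - 1]
                pm = S_X
            if Y[i - 1, j - 1] > bm:
                bm = Y[i - 1, j - 1]
                pm = S_Y
            if j == 1 and 0 > bm:
                bm = 0
                pm = S_START
            M[i, j] = bm + s
            PM[i, j] = pm
            # X from (i, j-1); priority M > X > Y > START
            bx = M[i, j - 1] - GO
            px = S_M
            if X[i, j - 1] - GAP_EXTEND > bx:
                bx = X[i, j - 1] - GAP_EXTEND
                px = S_X
            if Y[i, j - 1] - GO > bx:
                bx = Y[i, j - 1] - GO
                px = S_Y
            if j == 1 and -GO > bx:
                bx = -GO
                px = S_START
            X[i, j] = bx
            PX[i, j] = px
            # Y from (i-1, j); priority M > X > Y
            by = M[i - 1, j] - GO
            py = S_M
            if X[i - 1, j] - GO > by:
                by = X[i - 1, j] - GO
                py = S_X
            if Y[i - 1, j] - GAP_EXTEND > by:
                by = Y[i - 1, j] - GAP_EXTEND
                py = S_Y
            Y[i, j] = by
            PY[i, j] = py

    # end state: column m, any row; larger score, then M over X, then larger i
    best = NEG - 1
    bi = 0
    bstate = S_M
    for i in range(n + 1):
        sc = M[i, m]
        st = S_M
        if X[i, m] > sc:
            sc = X[i, m]
            st = S_X
        if sc >= best:
            best = sc
            bi = i
            bstate = st

    ops = np.empty(n + m + 2, np.int8)
    k = 0
    i = bi
    j = m
    st = bstate
    while st != S_START and (i > 0 or j > 0):
        if st == S_M:
            p = PM[i, j]
            ops[k] = OP_DIAG
            i -= 1
            j -= 1
        elif st == S_X:
            p = PX[i, j]
            ops[k] = OP_DEL
            j -= 1
        else:
            p = PY[i, j]
            ops[k] = OP_INS
            i -= 1
        k += 1
        st = p

    out = ops[:k][::-1].copy()
    return best, out, i, bi


def align_codes(read_codes: np.ndarray, ref_codes: np.ndarray):
    """Run the kernel; returns (score, op codes 5'->3', read_start, read_end).

    ``read_start`` bases at the head and ``len(read) - read_end`` bases at the
    tail of the read are soft-clipped.
    """
    score, ops, read_start, read_end = _gotoh(read_codes, ref_codes)
    return int(score), ops, int(read_start), int(read_end)


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
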