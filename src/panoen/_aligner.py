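"""Affine-gap protein aligner used for all homology searches.

Semi-global ("free end gap") alignment under BLOSUM62 with affine gap
costs: a gap of length k costs ``gap_open + k * gap_extend`` (defaults
11 + k, the BLAST convention).  Leading and trailing gaps are free and
excluded from the aligned columns used for the identity denominator.

Among co-optimal alignments the aligner is fully determined: it
maximises the score, then the number of identical columns, then
minimises the number of aligned columns, so identity and coverage are
well-defined quantities rather than artefacts of traceback order.

The dynamic program packs (score, matches, columns) into a single
int64 per cell so the lexicographic maximisation is one integer
comparison; deltas are linear in the packed representation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices

# Field layout of the packed objective:  [ score+OFF : 23 ][ matches : 20 ][ K-cols : 20 ]
_OFF = 1 << 22
_K = (1 << 20) - 1
_NEG = np.int64(-1)  # below any reachable packed value


def _load_blosum62() -> tuple[str, np.ndarray]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    n = len(alphabet)
    scores = np.zeros((n, n), dtype=np.int64)
    for i, x in enumerate(alphabet):
        for j, y in enumerate(alphabet):
            scores[i, j] = int(mat[x, y])
    return alphabet, scores


ALPHABET, BLOSUM62 = _load_blosum62()

_CHAR_TO_IDX = np.full(128, ALPHABET.index("X"), dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _CHAR_TO_IDX[ord(_c)] = _i
    if _c.isalpha():
        _CHAR_TO_IDX[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as BLOSUM62 row indices (unknowns -> X)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    if raw.size and raw.max() >= 128:
        raise ValueError("non-ASCII character in protein sequence")
    return _CHAR_TO_IDX[raw]


def _delta_matrix(scores: np.ndarray) -> np.ndarray:
    # packed delta for an aligned column: score<<40, +1 match if same
    # residue, +1 column (stored as K-cols, hence the -1).
    n = scores.shape[0]
    ident = np.eye(n, dtype=np.int64)
    return (scores << 40) + (ident << 20) - 1


_DELTA = _delta_matrix(BLOSUM62)


@njit(cache=True, nogil=True)
def _semi_global(a, b, delta, gap_open, gap_extend):  # pragma: no cover - jit
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int64(-1)
    P0 = np.int64(_OFF) << 40 | np.int64(_K)
    GO = -((np.int64(gap_open + gap_extend)) << 40) - 1
    GE = -((np.int64(gap_extend)) << 40) - 1

    # packed objective rows (previous / current) per state
    pM = np.full(m + 1, NEG, dtype=np.int64)
    pE = np.full(m + 1, NEG, dtype=np.int64)
    pF = np.full(m + 1, NEG, dtype=np.int64)
    cM = np.full(m + 1, NEG, dtype=np.int64)
    cE = np.full(m + 1, NEG, dtype=np.int64)
    cF = np.full(m + 1, NEG, dtype=np.int64)
    # alignment start (i0 << 20 | j0) rows, propagated with the argmax
    psM = np.zeros(m + 1, dtype=np.int64)
    psE = np.zeros(m + 1, dtype=np.int64)
    psF = np.zeros(m + 1, dtype=np.int64)
    csM = np.zeros(m + 1, dtype=np.int64)
    csE = np.zeros(m + 1, dtype=np.int64)
    csF = np.zeros(m + 1, dtype=np.int64)

    best = NEG
    bstart = np.int64(0)
    bi1 = 0; bj1 = 0

    for i in range(1, n + 1):
        cM[0] = NEG; cE[0] = NEG; cF[0] = NEG
        ai = a[i - 1]
        drow = delta[ai]
        for j in range(1, m + 1):
            # --- M state: tie order M > E > F > fresh start
            bp = pM[j - 1]; s = psM[j - 1]
            if pE[j - 1] > bp:
                bp = pE[j - 1]; s = psE[j - 1]
            if pF[j - 1] > bp:
                bp = pF[j - 1]; s = psF[j - 1]
            if (i == 1 or j == 1) and P0 > bp:
                bp = P0; s = np.int64(i - 1) << 20 | np.int64(j - 1)
            if bp == NEG:
                cM[j] = NEG
            else:
                cM[j] = bp + drow[b[j - 1]]
                csM[j] = s
            # --- E state: gap in a (consume b[j-1]); open from M else extend
            eo = cM[j - 1] + GO if cM[j - 1] != NEG else NEG
            ee = cE[j - 1] + GE if cE[j - 1] != NEG else NEG
            if eo >= ee:
                cE[j] = eo; csE[j] = csM[j - 1]
            else:
                cE[j] = ee; csE[j] = csE[j - 1]
            # --- F state: gap in b (consume a[i-1])
            fo = pM[j] + GO if pM[j] != NEG else NEG
            fe = pF[j] + GE if pF[j] != NEG else NEG
            if fo >= fe:
                cF[j] = fo; csF[j] = psM[j]
            else:
                cF[j] = fe; csF[j] = psF[j]
        # alignment must end on an aligned column at the right or bottom edge
        if cM[m] > best:
            best = cM[m]; bstart = csM[m]; bi1 = i; bj1 = m
        if i == n:
            for j in range(1, m + 1):
                if cM[j] > best:
                    best = cM[j]; bstart = csM[j]; bi1 = n; bj1 = j
        pM, cM = cM, pM
        pE, cE = cE, pE
        pF, cF = cF, pF
        psM, csM = csM, psM
        psE, csE = csE, psE
        psF, csF = csF, psF

    score = (best >> 40) - _OFF
    matches = (best >> 20) & _K
    cols = _K - (best & _K)
    bi0 = bstart >> 20
    bj0 = bstart & _K
    return score, matches, cols, bi0, bj0, bi1, bj1


def align_encoded(
    a: np.ndarray,
    b: np.ndarray,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[int, int, int, int, int, int, int]:
    """Align two encoded sequences.

    Returns ``(score, matches, columns, a_start, b_start, a_end, b_end)``
    where the start/end pairs delimit the aligned (non-terminal-gap)
    spans, 0-based half-open on each sequence.
    """
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot align an empty sequence")
    out = _semi_global(a, b, _DELTA, gap_open, gap_extend)
    return tuple(int(x) for x in out)
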