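"""Low-level sequence utilities: encoding, reverse complement, IUPAC matching,
and a Gotoh-style local aligner (numba-accelerated).

The aligner uses the fixed scoring scheme match +1, mismatch -1, gap open -2,
gap extend -1 ("open" being the score of the first gapped column, as in
Biopython's PairwiseAligner convention).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# A,C,G,T -> 0..3; anything else (N, ambiguity codes in reads) -> 4, which
# never matches during alignment or overlap scoring.
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_mismatches(primer: str, window: str) -> int:
    """Number of primer positions whose IUPAC code does not cover the read base.

    ``N`` in the read matches nothing (counts as a mismatch) because an
    uncalled base carries no evidence of primer presence.
    """
    mm = 0
    for p, b in zip(primer, window):
        if b not in IUPAC.get(p.upper(), ""):
            mm += 1
    return mm


@njit(cache=True)
def _gotoh_local(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover - jitted
    n = q.shape[0]
    m = t.shape[0]
    NEG = -(10 ** 7)
    # rolling rows for values; full packed pointer matrix for traceback:
    # bits 0-1: H source (0 stop, 1 diag, 2 E, 3 F); bit 2: E opened;
    # bit 3: F opened
    h_prev = np.zeros(m + 1, np.int32)
    h_cur = np.zeros(m + 1, np.int32)
    e_row = np.full(m + 1, NEG, np.int32)
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        h_cur[0] = 0
        f = NEG
        ptr_i = ptr[i]
        for j in range(1, m + 1):
            p = 0
            e_open = h_prev[j] + gap_open
            e_ext = e_row[j] + gap_extend
            if e_open >= e_ext:
                e = e_open
                p |= 4
            else:
                e = e_ext
            e_row[j] = e
            f_open = h_cur[j - 1] + gap_open
            f_ext = f + gap_extend
            if f_open >= f_ext:
                f = f_open
                p |= 8
            else:
                f = f_ext
            if qi == t[j - 1] and qi != 4:
                diag = h_prev[j - 1] + match
            else:
                diag = h_prev[j - 1] + mismatch
            h = 0
            if diag > h:
                h = diag
                p |= 1
            if e > h:
                h = e
                p = (p & 12) | 2
            if f > h:
                h = f
                p = (p & 12) | 3
            h_cur[j] = h
            ptr_i[j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
    # traceback from (bi, bj)
    identities = 0
    mismatches = 0
    gapcols = 0
    i = bi
    j = bj
    state = 0  # 0 = H, 1 = E, 2 = F
    while i > 0 and j > 0:
        p = ptr[i, j]
        if state == 0:
            src = p & 3
            if src == 0:
                break
            if src == 1:
                if q[i - 1] == t[j - 1] and q[i - 1] != 4:
                    identities += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            gapcols += 1
            opened = p & 4
            i -= 1
            if opened:
                state = 0
        else:
            gapcols += 1
            opened = p & 8
            j -= 1
            if opened:
                state = 0
    q_start = i
    q_end = bi
    return best, identities, mismatches, gapcols, q_start, q_end


def local_align(query: str, target: str,
                match: int = 1, mismatch: int = -1,
                gap_open: int = -2, gap_extend: int = -1):
    """Local (Smith-Waterman/Gotoh) alignment of ``query`` against ``target``.

    Returns ``(score, identities, mismatches, gap_columns, q_start, q_end)``
    for one optimal local alignment; ``q_start:q_end`` is the aligned query
    span. A degenerate alignment (no positive score) returns all zeros.
    """
    if not query or not target:
        return 0, 0, 0, 0, 0, 0
    res = _gotoh_local(encode(query), encode(target),
                       match, mismatch, gap_open, gap_extend)
    if res[0] <= 0:
        return 0, 0, 0, 0, 0, 0
    return res
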