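"""Exact global DNA alignment used by the 97%-identity screen.

The similarity between two clone sequences is defined on the optimal
end-to-end (Needleman-Wunsch) global alignment with match +1, mismatch -1
and gap column -2; every gap column is scored, including terminal ones, so
the alignment must span both sequences. Identity is then

    matched columns / alignment columns excluding terminal-gap columns,

i.e. overhangs at either end are penalised when choosing the alignment but
do not dilute the identity ratio. (Leaving end gaps unscored instead would
let a short perfect end-overlap outscore the full-length alignment of two
unrelated sequences and report identity 1.0 for them — useless as a
screening measure.)

Because several alignments can share the optimal score, the measure is
pinned down by a deterministic tie-break: lexicographic maximum of
(score, matched columns, -interior gap columns, terminal gap columns).
The dynamic program propagates that additive quadruple packed into a
single int64 so the recurrence runs on machine integers inside a numba
kernel; an independent pure-Python oracle in the test suite recomputes it
from the definition.

A gap column is *terminal* when it lies on the border of the alignment
path: a gap in the first/last row or first/last column of the dynamic
program, i.e. an overhang run at either end of either sequence.

IUPAC ambiguity codes are handled as bitmasks over {A,C,G,T}: two symbols
match when one symbol's base set contains the other's, and mismatch
otherwise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: 4-bit base sets for the IUPAC nucleotide alphabet (U treated as T).
IUPAC_MASK = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

#: Longest sequence the packed-integer encoding is safe for.
MAX_LEN = 2000

# Bit layout of the packed quadruple, low to high: terminal gap columns
# (bits 0-11), interior-gap complement 4000 - g_int (bits 12-23), matched
# columns (bits 24-35), offset score (bit 36 up). Field bounds: every gap
# count <= 2 * MAX_LEN = 4000 < 4096, matches <= MAX_LEN < 4096,
# |score| <= 8 * 2 * MAX_LEN < 2^18.
_SHIFT_GI = 12
_SHIFT_M = 24
_SHIFT_S = 36
_GI_BASE = 4000
_OFFSET = 1 << 18

_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _sym, _bits in IUPAC_MASK.items():
    _MASK_TABLE[ord(_sym)] = _bits
    _MASK_TABLE[ord(_sym.lower())] = _bits


def encode_sequence(seq: str) -> np.ndarray:
    """Map a IUPAC nucleotide string to a uint8 bitmask array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    masks = _MASK_TABLE[raw]
    if np.any(masks == 0):
        bad = seq[int(np.argmax(masks == 0))]
        raise ValueError(f"non-IUPAC nucleotide symbol {bad!r} in sequence")
    if masks.size > MAX_LEN:
        raise ValueError(f"sequence longer than supported maximum {MAX_LEN}")
    return masks


@njit(cache=True)
def _align_quad(a, b, match, mismatch, gap):  # pragma: no cover - jitted
    m = a.shape[0]
    n = b.shape[0]
    base = (np.int64(_OFFSET) << _SHIFT_S) + (np.int64(_GI_BASE) << _SHIFT_GI)
    gap_term = (np.int64(gap) << _SHIFT_S) + 1            # g_term += 1
    gap_int = (np.int64(gap) << _SHIFT_S) - (np.int64(1) << _SHIFT_GI)
    match_delta = (np.int64(match) << _SHIFT_S) + (np.int64(1) << _SHIFT_M)
    mismatch_delta = np.int64(mismatch) << _SHIFT_S

    prev = np.empty(n + 1, dtype=np.int64)
    cur = np.empty(n + 1, dtype=np.int64)
    for j in range(n + 1):
        prev[j] = base + j * gap_term  # leading overhang of `b`

    for i in range(1, m + 1):
        cur[0] = base + i * gap_term   # leading overhang of `a`
        ai = a[i - 1]
        for j in range(1, n + 1):
            bj = b[j - 1]
            inter = ai & bj
            if inter == ai or inter == bj:
                v = prev[j - 1] + match_delta
            else:
                v = prev[j - 1] + mismatch_delta
            # gap in b (consumes a[i-1]); terminal when in the last column
            t = prev[j] + (gap_term if j == n else gap_int)
            if t > v:
                v = t
            # gap in a (consumes b[j-1]); terminal when in the last row
            t = cur[j - 1] + (gap_term if i == m else gap_int)
            if t > v:
                v = t
            cur[j] = v
        tmp = prev
        prev = cur
        cur = tmp

    best = prev[n]
    score = (best >> _SHIFT_S) - _OFFSET
    matches = (best >> _SHIFT_M) & 0xFFF
    g_int = _GI_BASE - ((best >> _SHIFT_GI) & 0xFFF)
    g_term = best & 0xFFF
    return score, matches, g_int, g_term


def alignment_stats(
    a: np.ndarray,
    b: np.ndarray,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> tuple[int, int, int, int]:
    """Optimal (score, matches, interior gap cols, terminal gap cols).

    Scores must be small integers (|s| <= 8) so the packed encoding cannot
    overflow; mismatch and gap must be negative.
    """
    for name, s in (("match", match), ("mismatch", mismatch), ("gap", gap)):
        if not float(s).is_integer() or abs(s) > 8:
            raise ValueError(f"{name} score must be an integer with |s| <= 8")
    if mismatch >= match or gap >= 0:
        raise ValueError("require mismatch < match and gap < 0")
    score, matches, g_int, g_term = _align_quad(
        a, b, np.int64(match), np.int64(mismatch), np.int64(gap)
    )
    return int(score), int(matches), int(g_int), int(g_term)


def identity_from_stats(
    score: int,
    matches: int,
    g_int: int,
    g_term: int,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> float:
    """Identity implied by alignment stats (0.0 on an all-gap alignment)."""
    mismatches, rem = divmod(score - match * matches - gap * (g_int + g_term), mismatch)
    if rem:  # defensive: stats inconsistent with the scoring scheme
        raise ValueError("alignment stats inconsistent with scoring")
    columns = matches + mismatches + g_int
    if columns == 0:
        return 0.0
    return matches / columns
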