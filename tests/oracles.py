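"""Independent reference implementations used only by the test suite.

Everything here is written from the definitions, deliberately avoiding the
package's own code paths: a tuple-valued dynamic program and a brute-force
path enumeration for the alignment identity, a Monte-Carlo subsampler for
rarefaction, and a direct intra-cluster certificate check for OTU
partitions.

Alignment convention under test: end-to-end global alignment, every gap
column scored (terminal ones included); identity = matches / columns with
terminal-gap columns excluded from the denominator; co-optimal alignments
resolved by the lexicographic maximum of
(score, matches, -interior_gap_columns, terminal_gap_columns). A gap
column is terminal when it lies on the border of the alignment grid
(first/last row or first/last column), i.e. an overhang run.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"}, "U": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}


def symbols_match(x: str, y: str) -> bool:
    sx, sy = IUPAC_SETS[x], IUPAC_SETS[y]
    return sx <= sy or sy <= sx


def _identity_of(quad, match, mismatch, gap):
    score, matches, neg_g_int, g_term = quad
    g_int = -neg_g_int
    mismatches = (score - match * matches - gap * (g_int + g_term)) // mismatch
    columns = matches + mismatches + g_int
    return matches / columns if columns else 0.0


def dp_identity(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> float:
    """Tuple-valued corner-to-corner DP over (score, matches, -g_int, g_term)."""
    m, n = len(a), len(b)
    H = [[None] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = (gap * j, 0, 0, j)
    for i in range(1, m + 1):
        H[i][0] = (gap * i, 0, 0, i)
        for j in range(1, n + 1):
            s, mt, gi, gt = H[i - 1][j - 1]
            if symbols_match(a[i - 1], b[j - 1]):
                best = (s + match, mt + 1, gi, gt)
            else:
                best = (s + mismatch, mt, gi, gt)
            s, mt, gi, gt = H[i - 1][j]  # gap in b, consumes a[i-1]
            cand = (s + gap, mt, gi, gt + 1) if j == n else (s + gap, mt, gi - 1, gt)
            if cand > best:
                best = cand
            s, mt, gi, gt = H[i][j - 1]  # gap in a, consumes b[j-1]
            cand = (s + gap, mt, gi, gt + 1) if i == m else (s + gap, mt, gi - 1, gt)
            if cand > best:
                best = cand
            H[i][j] = best
    return _identity_of(H[m][n], match, mismatch, gap)


def enumerate_identity(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2) -> float:
    """Exhaustive path enumeration (tiny inputs only) with the same tie-break."""
    m, n = len(a), len(b)
    best = None

    def walk(i: int, j: int, score: int, mt: int, gi: int, gt: int) -> None:
        nonlocal best
        if i == m and j == n:
            quad = (score, mt, -gi, gt)
            if best is None or quad > best:
                best = quad
            return
        if i < m and j < n:
            if symbols_match(a[i], b[j]):
                walk(i + 1, j + 1, score + match, mt + 1, gi, gt)
            else:
                walk(i + 1, j + 1, score + mismatch, mt, gi, gt)
        if i < m:  # gap in b; terminal when on the first or last column
            if j == 0 or j == n:
                walk(i + 1, j, score + gap, mt, gi, gt + 1)
            else:
                walk(i + 1, j, score + gap, mt, gi + 1, gt)
        if j < n:  # gap in a; terminal when on the first or last row
            if i == 0 or i == m:
                walk(i, j + 1, score + gap, mt, gi, gt + 1)
            else:
                walk(i, j + 1, score + gap, mt, gi + 1, gt)

    walk(0, 0, 0, 0, 0, 0)
    return _identity_of(best, match, mismatch, gap)


def mc_rarefaction(sizes, n_draws: int, rng: np.random.Generator):
    """Monte-Carlo expected richness per subsample size, with standard errors.

    Returns (mean, se) arrays indexed by n-1 for n = 1..N.
    """
    labels = np.repeat(np.arange(len(sizes)), sizes)
    N = labels.size
    acc = np.zeros(N)
    acc2 = np.zeros(N)
    for _ in range(n_draws):
        perm = rng.permutation(labels)
        first = np.zeros(N)
        _, first_idx = np.unique(perm, return_index=True)
        first[first_idx] = 1.0
        curve = np.cumsum(first)
        acc += curve
        acc2 += curve * curve
    mean = acc / n_draws
    var = np.maximum(acc2 / n_draws - mean * mean, 0.0)
    return mean, np.sqrt(var / n_draws)


def min_intra_cluster_identity(partition, identity_fn, clones) -> float:
    """Worst intra-OTU pairwise identity over all multi-member OTUs."""
    by_otu: dict[int, list] = {}
    for clone in clones:
        by_otu.setdefault(partition.assignments[clone.id], []).append(clone)
    worst = 1.0
    for members in by_otu.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                worst = min(worst, identity_fn(members[i], members[j]))
    return worst


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(4, size=length)])
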