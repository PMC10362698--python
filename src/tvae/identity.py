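"""Pairwise sequence identity by global and local alignment.

Scoring is match=1, mismatch=0, gap open/extend=0 — the classic
"count identical residues" scheme.  With all penalties zero the
maximum-score alignment is not unique and co-optimal alignments can
have different lengths, which would make identity (= matches /
alignment length) ill-defined; the dynamic programs here therefore
maximize (matches, -alignment_length) lexicographically, i.e. they
report the maximal number of identical aligned pairs over the shortest
alignment achieving it.  This makes every identity value
bit-reproducible.
"""

from __future__ import annotations

import numpy as np

_NEG = -(10**9)


def _pair_table(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    """DP over (matches, -length); returns the two value tables."""
    la, lb = len(a), len(b)
    m = np.zeros((la + 1, lb + 1), dtype=np.int64)  # matches
    ln = np.zeros((la + 1, lb + 1), dtype=np.int64)  # alignment length
    m[0, :] = 0
    ln[0, :] = np.arange(lb + 1)
    ln[:, 0] = np.arange(la + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = (m[i - 1, j - 1] + (a[i - 1] == b[j - 1]), ln[i - 1, j - 1] + 1)
            up = (m[i - 1, j], ln[i - 1, j] + 1)
            left = (m[i, j - 1], ln[i, j - 1] + 1)
            best = max(diag, up, left, key=lambda t: (t[0], -t[1]))
            m[i, j], ln[i, j] = best
    return m, ln


def global_identity(a: str, b: str) -> float:
    """Needleman-Wunsch identity (%): identical pairs / alignment length."""
    if not a or not b:
        raise ValueError("global identity requires nonempty sequences")
    m, ln = _pair_table(a, b)
    return 100.0 * m[-1, -1] / ln[-1, -1]


def local_identity(a: str, b: str) -> float:
    """Smith-Waterman identity (%) over the best local alignment.

    Prefix/suffix columns that cannot contribute matches are free, so
    the score is the best (matches, -length) over all subsegment
    alignments.  If no residue of ``a`` matches any of ``b`` the best
    local alignment is empty and the identity is reported as 0%.
    """
    if not a or not b:
        raise ValueError("local identity requires nonempty sequences")
    la, lb = len(a), len(b)
    m = np.zeros((la + 1, lb + 1), dtype=np.int64)
    ln = np.zeros((la + 1, lb + 1), dtype=np.int64)
    best = (0, 0)  # empty alignment allowed
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cand = [(0, 0), (m[i - 1, j], ln[i - 1, j] + 1),
                    (m[i, j - 1], ln[i, j - 1] + 1),
                    (m[i - 1, j - 1] + (a[i - 1] == b[j - 1]), ln[i - 1, j - 1] + 1)]
            m[i, j], ln[i, j] = max(cand, key=lambda t: (t[0], -t[1]))
            if (m[i, j], -ln[i, j]) > (best[0], -best[1]):
                best = (int(m[i, j]), int(ln[i, j]))
    if best[0] == 0:
        return 0.0
    return 100.0 * best[0] / best[1]
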