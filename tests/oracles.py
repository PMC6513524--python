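"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms:

* local alignment: exhaustive enumeration over alignment skeletons
  (all order-preserving sets of aligned column pairs, with minimal affine
  gap cost between consecutive pairs) instead of the Gotoh DP,
* RNA folding: recursive enumeration of all non-crossing pairings instead
  of the Nussinov table,
* UPGMA: scipy's average-linkage implementation, compared through
  cophenetic matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform


def enumerate_local_score(
    a: str, b: str, matrix, gap_open: int, gap_extend: int
) -> int:
    """Optimal local alignment score by exhaustive skeleton enumeration.

    A local alignment is determined by its aligned (substitution) columns:
    strictly increasing index pairs.  Between consecutive aligned columns
    the cheapest arrangement of the skipped residues is one gap run per
    sequence, costing ``open + (len - 1) * extend`` each; leading/trailing
    gaps never appear in an optimal local alignment.
    """

    def gap_cost(d: int) -> int:
        return 0 if d == 0 else gap_open + (d - 1) * gap_extend

    n, m = len(a), len(b)
    best = 0

    def rec(i: int, j: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        for i2 in range(i + 1, n):
            for j2 in range(j + 1, m):
                rec(
                    i2,
                    j2,
                    score
                    + matrix[a[i2], b[j2]]
                    - gap_cost(i2 - i - 1)
                    - gap_cost(j2 - j - 1),
                )

    for i in range(n):
        for j in range(m):
            rec(i, j, matrix[a[i], b[j]])
    return int(max(best, 0))


_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def enumerate_max_pairs(window: str, min_loop: int = 3) -> int:
    """Maximum pair count over all non-crossing pairings, by recursion
    without memoisation (pure enumeration)."""

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (window[i], window[k]) in _PAIRS:
                cand = 1 + rec(i + 1, k - 1) + rec(k + 1, j)
                if cand > best:
                    best = cand
        return best

    return rec(0, len(window) - 1)


def scipy_cophenetic(dist: np.ndarray) -> np.ndarray:
    """Cophenetic matrix of scipy's average-linkage (UPGMA) clustering."""
    condensed = squareform(np.asarray(dist, dtype=float), checks=False)
    return squareform(cophenet(linkage(condensed, method="average")))
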