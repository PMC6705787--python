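"""Independent oracles: brute-force alignment scoring and LCS.

Kept structurally independent of the package's dynamic program: the brute
force enumerates alignment move sequences recursively (no tabulation) and
the LCS is a plain textbook recurrence.
"""

from __future__ import annotations

import numpy as np


def brute_force_score(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                      gap_open: float = -1.0, gap_extend: float = -1.0,
                      table=None) -> float:
    """Maximum global-alignment score by exhaustive enumeration of all paths.

    Affine-aware: a gap costs gap_open for its first residue and gap_extend
    for each further one. X scores as a mismatch unless a table says otherwise.
    """

    def sub(x: str, y: str) -> float:
        if table is not None:
            return table[x][y]
        if x == "X" or y == "X":
            return mismatch
        return match if x == y else mismatch

    best = -np.inf

    def rec(i: int, j: int, state: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            if score > best:
                best = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + sub(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "A", score + (gap_extend if state == "A" else gap_open))
        if j < len(b):
            rec(i, j + 1, "B", score + (gap_extend if state == "B" else gap_open))

    rec(0, 0, "M", 0.0)
    return float(best)


def lcs_length(a: str, b: str) -> int:
    """Longest-common-subsequence length, textbook dynamic program."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                dp[i, j] = dp[i - 1, j - 1] + 1
            else:
                dp[i, j] = max(dp[i - 1, j], dp[i, j - 1])
    return int(dp[n, m])
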