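"""Independent brute-force oracles for the range statistics.

Deliberately naive implementations (explicit python loops, no shared code
with the package) used to validate the vectorized statistics.
"""

from __future__ import annotations

import numpy as np


def brute_embedded_absences(a: np.ndarray, both_axes: bool = True) -> int:
    """Count zeros strictly inside each column's (and row's) occupied span."""
    a = np.asarray(a)
    total = 0
    for j in range(a.shape[1]):
        col = [int(v) for v in a[:, j]]
        if 1 in col:
            first, last = col.index(1), len(col) - 1 - col[::-1].index(1)
            total += sum(1 for i in range(first, last + 1) if col[i] == 0)
    if both_axes:
        for i in range(a.shape[0]):
            row = [int(v) for v in a[i, :]]
            if 1 in row:
                first, last = row.index(1), len(row) - 1 - row[::-1].index(1)
                total += sum(1 for j in range(first, last + 1) if row[j] == 0)
    return total


def brute_fill(a: np.ndarray) -> np.ndarray:
    a = np.array(a)
    for j in range(a.shape[1]):
        col = [int(v) for v in a[:, j]]
        if 1 in col:
            first, last = col.index(1), len(col) - 1 - col[::-1].index(1)
            for i in range(first, last + 1):
                a[i, j] = 1
    return a


def brute_replacements(a: np.ndarray) -> int:
    """Sum over taxon pairs of (#sites with i only) x (#sites with j only)."""
    a = np.asarray(a)
    n, t = a.shape
    total = 0
    for i in range(t):
        for j in range(i + 1, t):
            only_i = sum(1 for s in range(n) if a[s, i] == 1 and a[s, j] == 0)
            only_j = sum(1 for s in range(n) if a[s, j] == 1 and a[s, i] == 0)
            total += only_i * only_j
    return total
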