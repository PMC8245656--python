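"""Margin-preserving swap kernel for the fixed-fixed (R1) null model.

The chain proposes a uniformly random pair of rows and pair of columns and,
when the 2x2 submatrix is a checkerboard (10/01 or 01/10), swaps it with
probability 1/2 (a lazy chain, which keeps tiny classes — e.g. the 2-state
class of a 2x2 identity — from cycling periodically).  The proposal is
symmetric, so the stationary distribution is exactly uniform over all
binary matrices sharing the observed row and column totals.

Burn-in and thinning are counted on the *proposal* clock, not in accepted
swaps: snapshots taken every k-th accepted swap (or swap event) oversample
states in proportion to their number of checkerboard units, because the
event rate is state-dependent — the recorded mass is the uniform occupancy
re-weighted by the per-state event rate.  Sampling at fixed proposal counts
keeps the clock independent of the state and the draws exactly uniform.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sample_chain(mat: np.ndarray, burn_in: int, thin: int, n_sims: int,
                  seed: int, out: np.ndarray) -> int:
    """Run the swap chain in place; snapshots go to ``out``.

    ``burn_in`` and ``thin`` are proposal counts.  Returns the total number
    of swap events seen (0 signals a frozen matrix: the margins admit no
    checkerboard swap).
    """
    np.random.seed(seed)
    n, m = mat.shape
    total_accepted = 0
    for k in range(n_sims):
        target = burn_in + thin if k == 0 else thin
        for _ in range(target):
            i1 = np.random.randint(n)
            i2 = np.random.randint(n)
            j1 = np.random.randint(m)
            j2 = np.random.randint(m)
            if i1 == i2 or j1 == j2:
                continue
            a = mat[i1, j1]
            b = mat[i1, j2]
            c = mat[i2, j1]
            d = mat[i2, j2]
            if a == d and b == c and a != b:
                if np.random.random() < 0.5:  # lazy step for aperiodicity
                    mat[i1, j1] = b
                    mat[i1, j2] = a
                    mat[i2, j1] = d
                    mat[i2, j2] = c
                total_accepted += 1
        out[k] = mat
    return total_accepted


@njit(cache=True)
def _has_checkerboard_unit(mat: np.ndarray) -> bool:
    n, m = mat.shape
    for i1 in range(n - 1):
        for i2 in range(i1 + 1, n):
            for j1 in range(m - 1):
                for j2 in range(j1 + 1, m):
                    a = mat[i1, j1]
                    b = mat[i1, j2]
                    c = mat[i2, j1]
                    d = mat[i2, j2]
                    if a == d and b == c and a != b:
                        return True
    return False


@njit(cache=True)
def _ordinated_absences_svd(mat):
    """Embedded absences (both axes) of ``mat`` ordered by its exact CA axis 1."""
    n, m = mat.shape
    rs = mat.sum(axis=1).astype(np.float64)
    cs = mat.sum(axis=0).astype(np.float64)
    total = rs.sum()
    S = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = (mat[i, j] / total - rs[i] * cs[j] / (total * total)) / \
                np.sqrt(rs[i] * cs[j] / (total * total))
    U, sv, Vt = np.linalg.svd(S)
    x = np.empty(n)
    for i in range(n):
        x[i] = U[i, 0] / np.sqrt(rs[i] / total)
    y = np.empty(m)
    for j in range(m):
        y[j] = Vt[0, j] / np.sqrt(cs[j] / total)
    ro = np.argsort(x)
    co = np.argsort(y)
    A = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        for j in range(m):
            A[i, j] = mat[ro[i], co[j]]
    total_abs = 0
    for j in range(m):
        first = -1
        last = -1
        cnt = 0
        for i in range(n):
            if A[i, j]:
                if first < 0:
                    first = i
                last = i
                cnt += 1
        if cnt > 0:
            total_abs += (last - first + 1) - cnt
    for i in range(n):
        first = -1
        last = -1
        cnt = 0
        for j in range(m):
            if A[i, j]:
                if first < 0:
                    first = j
                last = j
                cnt += 1
        if cnt > 0:
            total_abs += (last - first + 1) - cnt
    return total_abs


@njit(cache=True)
def _anneal_incoherence(mat, n_prop, seed, temp0):
    """Margin-preserving swaps annealed to maximize ordinated embedded absences.

    Plants the anti-coherent (checkerboard-pattern) extreme of the matrix's
    fixed-margin class.  Scoring uses the exact CA axis: near the optimum
    the top singular values are nearly degenerate, which approximate
    (power-iteration) scores cannot track.  Returns the best matrix found.
    """
    np.random.seed(seed)
    n, m = mat.shape
    cur = _ordinated_absences_svd(mat)
    best = mat.copy()
    best_v = cur
    k = 0
    while k < n_prop:
        i1 = np.random.randint(n)
        i2 = np.random.randint(n)
        j1 = np.random.randint(m)
        j2 = np.random.randint(m)
        if i1 == i2 or j1 == j2:
            continue
        a = mat[i1, j1]
        b = mat[i1, j2]
        c = mat[i2, j1]
        d = mat[i2, j2]
        if not (a == d and b == c and a != b):
            continue
        k += 1
        temp = temp0 * (1.0 - k / n_prop) + 0.01
        mat[i1, j1] = b
        mat[i1, j2] = a
        mat[i2, j1] = d
        mat[i2, j2] = c
        new = _ordinated_absences_svd(mat)
        if new >= cur or np.random.random() < np.exp((new - cur) / temp):
            cur = new
            if new > best_v:
                best_v = new
                best = mat.copy()
        else:
            mat[i1, j1] = a
            mat[i1, j2] = b
            mat[i2, j1] = c
            mat[i2, j2] = d
    return best
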