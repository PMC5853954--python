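"""Numba kernels shared by the search and tree modules.

The alignment kernels work on a precomputed position score matrix
``S[i, j]`` (score of pairing row-object i with column-object j) so the same
code serves sequence-vs-profile and profile-vs-profile alignment.  Gap cost
convention throughout the package: a gap of length L costs
``gap_open + (L - 1) * gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18


@njit(cache=False)
def local_best_score(S, gap_open, gap_extend):
    """Best local alignment score under Gotoh affine DP (no traceback).

    H = best score ending at (i,j) with a match; E = ending with a gap that
    consumes columns; F = with a gap that consumes rows; all clipped at 0.
    """
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
    return best


@njit(cache=False)
def global_align_matrices(S, gap_open, gap_extend):
    """Needleman–Wunsch/Gotoh global DP; returns (score, H, E, F) matrices.

    End gaps are charged at full cost.  Traceback is done in Python from the
    returned matrices (exact score re-derivation, no pointer storage).
    """
    m, n = S.shape
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -(gap_open + (j - 1) * gap_extend)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -(gap_open + (i - 1) * gap_extend)
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i, j - 1] - gap_open
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H[m, n], H, E, F


def global_align_path(S, gap_open, gap_extend):
    """Global affine alignment path on score matrix ``S``.

    Returns ``(score, path)`` where path is a list of (i, j) column pairs
    with -1 marking a gap on that side; i indexes rows of S, j columns.
    Ties broken in a fixed order (match > column-gap > row-gap).
    """
    score, H, E, F = global_align_matrices(
        np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_extend)
    )
    m, n = S.shape
    path: list[tuple[int, int]] = []
    i, j = m, n
    tol = 1e-9
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0 and abs(H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])) < tol:
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
            elif j > 0 and abs(H[i, j] - E[i, j]) < tol:
                state = "E"
            elif i > 0 and abs(H[i, j] - F[i, j]) < tol:
                state = "F"
            elif j > 0:  # boundary rows
                path.append((-1, j - 1))
                j -= 1
            else:
                path.append((i - 1, -1))
                i -= 1
        elif state == "E":
            path.append((-1, j - 1))
            if j > 1 and abs(E[i, j] - (E[i, j - 1] - gap_extend)) < tol and not (
                abs(E[i, j] - (H[i, j - 1] - gap_open)) < tol
            ):
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            path.append((i - 1, -1))
            if i > 1 and abs(F[i, j] - (F[i - 1, j] - gap_extend)) < tol and not (
                abs(F[i, j] - (H[i - 1, j] - gap_open)) < tol
            ):
                i -= 1
            else:
                i -= 1
                state = "H"
    path.reverse()
    return score, path


@njit(cache=False)
def fitch_score(left, right, masks, weights):
    """Weighted Fitch parsimony score of one rooted binary tree.

    ``left``/``right``: child indices per internal node in postorder; an
    index < n_leaves refers to a leaf row of ``masks`` (bitmask of allowed
    states per column; 0 is treated as "any state", i.e. missing), otherwise
    to internal node ``index - n_leaves``.  ``weights`` are per-column counts
    (bootstrap resampling weights).
    """
    n_int = left.shape[0]
    n_leaf, ncols = masks.shape
    states = np.empty((n_int, ncols), np.uint32)
    full = np.uint32((1 << 25) - 1)  # superset of any residue mask
    total = 0.0
    for k in range(n_int):
        for c in range(ncols):
            a = left[k]
            if a < n_leaf:
                sa = masks[a, c]
            else:
                sa = states[a - n_leaf, c]
            b = right[k]
            if b < n_leaf:
                sb = masks[b, c]
            else:
                sb = states[b - n_leaf, c]
            if sa == 0:
                sa = full
            if sb == 0:
                sb = full
            inter = sa & sb
            if inter != 0:
                states[k, c] = inter
            else:
                states[k, c] = sa | sb
                total += weights[c]
    return total
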