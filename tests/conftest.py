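"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Align import substitution_matrices


@pytest.fixture(scope="session")
def dna4_matrix():
    """4-letter substitution matrix (match 3 / mismatch -2) for small oracles."""
    m = substitution_matrices.Array("ACGT", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            m[a, b] = 3.0 if a == b else -2.0
    return m


def brute_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Independent local-alignment oracle: enumerate affine paths between all
    start anchors, tracking the per-state best over every end cell.

    Gap convention matches the package: first gap residue costs ``gap_open``,
    each further residue ``gap_extend``.
    """
    alpha = str(matrix.alphabet)
    la, lb = len(a), len(b)
    ai = [alpha.index(c) for c in a]
    bi = [alpha.index(c) for c in b]
    NEG = -1e18
    best = 0.0
    for i0 in range(la):
        for j0 in range(lb):
            # paths starting by pairing a[i0] with b[j0]
            # state table over (i, j): M / GA (gap consuming a) / GB
            M = [[NEG] * (lb + 1) for _ in range(la + 1)]
            GA = [[NEG] * (lb + 1) for _ in range(la + 1)]
            GB = [[NEG] * (lb + 1) for _ in range(la + 1)]
            M[i0 + 1][j0 + 1] = float(matrix[ai[i0], bi[j0]])
            for i in range(i0 + 1, la + 1):
                for j in range(j0 + 1, lb + 1):
                    if i < la and j < lb:
                        s = float(matrix[ai[i], bi[j]])
                        M[i + 1][j + 1] = max(
                            M[i + 1][j + 1],
                            max(M[i][j], GA[i][j], GB[i][j]) + s,
                        )
                    if i < la:
                        GA[i + 1][j] = max(
                            GA[i + 1][j],
                            max(M[i][j], GB[i][j]) - gap_open,
                            GA[i][j] - gap_extend,
                        )
                    if j < lb:
                        GB[i][j + 1] = max(
                            GB[i][j + 1],
                            max(M[i][j], GA[i][j]) - gap_open,
                            GB[i][j] - gap_extend,
                        )
                    best = max(best, M[i][j], GA[i][j], GB[i][j])
            best = max(best, M[la][lb], GA[la][lb], GB[la][lb])
    return best


@pytest.fixture(scope="session")
def brute_local_oracle():
    return brute_local_score


def random_protein(rng: np.random.Generator, length: int) -> str:
    from phylofam.simulate import AMINO_ACIDS

    return "".join(rng.choice(list(AMINO_ACIDS), length))


@pytest.fixture(scope="session")
def protein_factory():
    return random_protein
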