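"""Congruence among distance matrices: Kendall's W and the CADM test.

Trees and dendrograms are compared through their leaf-pair distance
matrices.  Each matrix's unfolded lower triangle is rank-transformed; the
concordance of the p rank vectors is Kendall's coefficient W (1 = complete
congruence, 1/p expected under independence; the test statistic is reported
raw, without rescaling to 0).  Significance comes from a permutation null:
object labels of every matrix except the first are permuted independently,
and p = (exceedances + 1) / (permutations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from scipy.stats import rankdata

from .content import Dendrogram

__all__ = [
    "CADMResult",
    "cophenetic_distances",
    "patristic_distances",
    "kendall_w",
    "cadm_test",
]


@dataclass
class CADMResult:
    W: float
    p_value: float
    permutations: int
    seed: int


def cophenetic_distances(dendrogram: Dendrogram) -> tuple[np.ndarray, list[str]]:
    """Merge-height cophenetic distances of a dendrogram (ultrametric).

    Convention: d(a, b) equals the merge height of the smallest cluster
    containing both (not twice the height).
    """
    return dendrogram.cophenetic()


def patristic_distances(tree: dendropy.Tree | str) -> tuple[np.ndarray, list[str]]:
    """Leaf-pair path-length distances of a phylogeny.

    Accepts a dendropy tree or a newick string.  Edges without branch
    lengths fall back to unit length (with a warning).
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    missing = [e for e in tree.preorder_edge_iter() if e.length is None and e.head_node is not tree.seed_node]
    if missing:
        warnings.warn("missing branch lengths; using unit lengths")
        for e in missing:
            e.length = 1.0
    if any(e.length is not None and e.length < 0 for e in tree.preorder_edge_iter()):
        raise ValueError("negative branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return D, labels


def _unfold(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def _check_set(matrices: Sequence[np.ndarray]) -> list[np.ndarray]:
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if len(mats) < 2:
        raise ValueError("need at least 2 matrices")
    n = mats[0].shape[0]
    for m in mats:
        if m.shape != (n, n):
            raise ValueError("all matrices must share dimensions")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("matrices must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("matrices must have zero diagonals")
    if n < 4:
        raise ValueError("need at least 4 objects")
    return mats


def _kendall_w_from_ranks(R: np.ndarray, T: np.ndarray) -> float:
    """W from a (p, m) matrix of within-matrix ranks and tie corrections."""
    p, m = R.shape
    Rj = R.sum(axis=0)
    S = float((Rj**2).sum())
    num = 12.0 * S - 3.0 * p * p * m * (m + 1) ** 2
    den = p * p * (m**3 - m) - p * float(T.sum())
    if den <= 0:
        warnings.warn("degenerate tie structure (constant matrices)")
        return 1.0
    return float(min(1.0, max(0.0, num / den)))


def _ranks_and_ties(vals: np.ndarray) -> tuple[np.ndarray, float]:
    r = rankdata(vals)
    _, counts = np.unique(vals, return_counts=True)
    T = float((counts**3 - counts).sum())
    return r, T


def kendall_w(matrices: Sequence[np.ndarray]) -> float:
    """Kendall's coefficient of concordance over unfolded distance matrices.

    W = (12 S - 3 p^2 m (m+1)^2) / (p^2 (m^3 - m) - p sum(T)) with S the sum
    of squared summed ranks, m = n(n-1)/2 unfolded values per matrix and T
    the usual tie correction; clamped into [0, 1].
    """
    mats = _check_set(matrices)
    R = []
    T = []
    for m in mats:
        r, t = _ranks_and_ties(_unfold(m))
        R.append(r)
        T.append(t)
    return _kendall_w_from_ranks(np.vstack(R), np.array(T))


def cadm_test(
    matrices: Sequence[np.ndarray],
    permutations: int = 999,
    seed: int = 0,
) -> CADMResult:
    """CADM permutation test of congruence among distance matrices.

    The observed W is compared against a null in which the object labels
    (rows and columns jointly) of every matrix except the first are permuted
    independently per matrix and replicate;
    p = (#{W_perm >= W_obs} + 1) / (permutations + 1).
    """
    if permutations < 19:
        raise ValueError("permutations < 19 gives too coarse a p-value resolution")
    mats = _check_set(matrices)
    n = mats[0].shape[0]
    rng = np.random.default_rng(seed)
    obs = kendall_w(mats)

    # precompute ranks of the fixed first matrix
    fixed_r, fixed_t = _ranks_and_ties(_unfold(mats[0]))
    exceed = 0
    for _ in range(permutations):
        R = [fixed_r]
        T = [fixed_t]
        for m in mats[1:]:
            perm = rng.permutation(n)
            pm = m[np.ix_(perm, perm)]
            r, t = _ranks_and_ties(_unfold(pm))
            R.append(r)
            T.append(t)
        w = _kendall_w_from_ranks(np.vstack(R), np.array(T))
        if w >= obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (permutations + 1)
    return CADMResult(W=obs, p_value=p, permutations=permutations, seed=seed)
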