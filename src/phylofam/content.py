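"""Gene-content matrix construction and hierarchical clustering of strains.

Rows are strains, columns are (family-namespaced) sequence groups, entries
are protein counts.  Strains are clustered on Euclidean row distances with
complete linkage; the agglomeration is written out explicitly so that
tie-breaking (lexicographically smallest cluster pair) is deterministic and
documented, and merge heights feed the cophenetic distances used by the
congruence test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Dendrogram",
    "build_count_matrix",
    "euclidean_distances",
    "complete_linkage",
]


@dataclass
class _Cluster:
    members: tuple[str, ...]
    height: float
    children: tuple["_Cluster", "_Cluster"] | None = None


@dataclass
class Dendrogram:
    """Rooted binary merge tree with non-decreasing merge heights."""

    root: _Cluster
    labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def cophenetic(self) -> tuple[np.ndarray, list[str]]:
        """d(a, b) = merge height of the smallest cluster containing both."""
        idx = {l: i for i, l in enumerate(self.labels)}
        n = len(self.labels)
        D = np.zeros((n, n))

        def rec(cl: _Cluster) -> None:
            if cl.children is None:
                return
            a, b = cl.children
            for x in a.members:
                for y in b.members:
                    D[idx[x], idx[y]] = D[idx[y], idx[x]] = cl.height
            rec(a)
            rec(b)

        rec(self.root)
        return D, list(self.labels)

    def newick(self) -> str:
        """Newick with branch lengths = height differences between merges."""

        def rec(cl: _Cluster, parent_height: float) -> str:
            if cl.children is None:
                return f"{cl.members[0]}:{parent_height - 0.0:.6g}"
            inner = ",".join(rec(c, cl.height) for c in cl.children)
            return f"({inner}):{parent_height - cl.height:.6g}"

        if self.root.children is None:
            return f"{self.root.members[0]}:0;"
        inner = ",".join(rec(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def build_count_matrix(
    groups_per_family: Mapping[str, Sequence],
    strain_of: Mapping[str, str],
    strains: Sequence[str],
) -> pd.DataFrame:
    """Strains x groups integer count matrix.

    ``groups_per_family`` maps family name to its (already size-filtered)
    groups; each group exposes ``group_id`` and ``members`` (gene ids).
    Columns are namespaced ``family:group_id`` and ordered by (family,
    group id); strains with no grouped genes keep zero rows.
    """
    strains = list(strains)
    columns: list[str] = []
    data: dict[str, np.ndarray] = {}
    sidx = {s: i for i, s in enumerate(strains)}
    for family in sorted(groups_per_family):
        for grp in sorted(groups_per_family[family], key=lambda g: g.group_id):
            col = f"{family}:{grp.group_id}"
            vec = np.zeros(len(strains), dtype=int)
            for gid in grp.members:
                strain = strain_of[gid]
                if strain not in sidx:
                    raise KeyError(f"gene {gid} maps to unknown strain {strain}")
                vec[sidx[strain]] += 1
            columns.append(col)
            data[col] = vec
    return pd.DataFrame(data, index=strains, columns=columns)


def euclidean_distances(matrix: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances between count rows (symmetric, 0 diag)."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))


def complete_linkage(dist: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """Naive agglomerative complete-linkage clustering.

    Inter-cluster distance is the maximum pairwise member distance; at each
    step the closest pair is merged, ties broken by the lexicographically
    smallest (sorted) cluster-pair key.  Merge heights are non-decreasing
    (complete linkage is reducible).
    """
    dist = np.asarray(dist, dtype=float)
    labels = list(labels)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix / label size mismatch")
    idx = {l: i for i, l in enumerate(labels)}
    clusters: dict[tuple[str, ...], _Cluster] = {
        (l,): _Cluster(members=(l,), height=0.0) for l in labels
    }
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def cdist(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return max(dist[idx[x], idx[y]] for x in a for y in b)

    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                d = cdist(ka, kb)
                pair_key = (d, ka, kb)
                if best is None or pair_key < best:
                    best = pair_key
        d, ka, kb = best
        ca, cb = clusters.pop(ka), clusters.pop(kb)
        merged = tuple(sorted(ca.members + cb.members))
        clusters[merged] = _Cluster(members=merged, height=d, children=(ca, cb))
        merges.append((ka, kb, d))
    root = next(iter(clusters.values()))
    return Dendrogram(root=root, labels=labels, merges=merges)
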