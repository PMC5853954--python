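"""Phylogeny-based sequence grouping.

The second grouping route builds, per family: a guide tree (neighbor
joining on global-alignment distances), a progressive multiple alignment,
a conserved-column trim, a maximum-parsimony tree (random-addition stepwise
insertion + NNI hill climbing, Fitch scoring with gaps as missing data),
bootstrap supports from column resampling, and finally sequence groups
extracted as maximal clades whose subtending node exceeds a support
threshold (default 50%), discarding groups below a minimum size (default 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from ._dp import fitch_score, global_align_path
from .search import SearchConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Msa",
    "SupportTree",
    "CladeGroup",
    "pairwise_distance",
    "neighbor_joining",
    "progressive_align",
    "trim_alignment",
    "parsimony_score",
    "search_mp_tree",
    "enumerate_unrooted_topologies",
    "bootstrap_support",
    "extract_supported_groups",
]


@dataclass
class Msa:
    """Ordered aligned records; '-' is the gap character."""

    records: list[tuple[str, str]]  # (id, aligned sequence)

    def __post_init__(self) -> None:
        if self.records:
            ncols = len(self.records[0][1])
            if any(len(s) != ncols for _, s in self.records):
                raise ValueError("aligned sequences must have equal length")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def ncols(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def nseq(self) -> int:
        return len(self.records)

    def ungapped(self) -> dict[str, str]:
        return {i: s.replace("-", "") for i, s in self.records}

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{s}\n" for i, s in self.records)


@dataclass
class SupportTree:
    """Rooted tree over gene ids with integer bootstrap supports (0-100)
    stored as internal node labels."""

    tree: dendropy.Tree

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def supports(self) -> list[int]:
        out = []
        for nd in self.tree.preorder_node_iter():
            if nd.is_leaf() or nd.label in (None, ""):
                continue
            out.append(int(nd.label))
        return out


@dataclass
class CladeGroup:
    group_id: str
    members: list[str]
    support: int

    @property
    def size(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# distances, guide tree, progressive alignment
# ---------------------------------------------------------------------------

def pairwise_distance(a: str, b: str, cfg: SearchConfig | None = None) -> float:
    """1 - (identical positions / columns) of the optimal global alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    cfg = cfg or SearchConfig()
    aln = cfg.aligner("global").align(a, b)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*(blk for blk in aln.aligned)):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                ident += 1
    return 1.0 - ident / aln.length


def neighbor_joining(dist: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix (skbio backend).

    Returns an unrooted tree (dendropy representation with a basal
    trichotomy).  Raises on non-symmetric input or fewer than 3 taxa.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix / label size mismatch")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    safe = [f"t{i}" for i in range(n)]
    tree = _skbio_nj(DistanceMatrix(dist, ids=safe))
    newick = str(tree).strip()
    dt = dendropy.Tree.get(data=newick, schema="newick")
    for lf in dt.leaf_node_iter():
        lf.taxon.label = labels[int(lf.taxon.label[1:])]
    return dt


class _Prof:
    """Alignment profile: aligned rows + per-column residue counts."""

    __slots__ = ("ids", "rows", "counts")

    def __init__(self, ids: list[str], rows: list[str], index: dict[str, int]):
        self.ids = ids
        self.rows = rows
        ncols = len(rows[0])
        counts = np.zeros((ncols, len(index)))
        for r in rows:
            for j, c in enumerate(r):
                k = index.get(c)
                if k is not None:
                    counts[j, k] += 1
        self.counts = counts


def _merge_profiles(
    p1: _Prof, p2: _Prof, M: np.ndarray, index: dict[str, int], go: float, ge: float
) -> _Prof:
    f1 = p1.counts / len(p1.rows)
    f2 = p2.counts / len(p2.rows)
    S = f1 @ M @ f2.T
    _, path = global_align_path(S, go, ge)
    rows1 = ["".join(r[i] if i >= 0 else "-" for i, _ in path) for r in p1.rows]
    rows2 = ["".join(r[j] if j >= 0 else "-" for _, j in path) for r in p2.rows]
    return _Prof(p1.ids + p2.ids, rows1 + rows2, index)


def progressive_align(
    seqs: Sequence[tuple[str, str]], cfg: SearchConfig | None = None
) -> Msa:
    """Guide-tree-ordered progressive profile--profile alignment.

    Pairwise global-alignment distances feed a neighbor-joining guide tree;
    profiles are merged in its postorder with affine-gap global DP on
    average substitution scores ("once a gap, always a gap").
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    cfg = cfg or SearchConfig()
    mat = cfg.matrix()
    index = {c: i for i, c in enumerate(str(mat.alphabet))}
    M = np.asarray(mat, dtype=float)
    go, ge = float(cfg.gap_open), float(cfg.gap_extend)
    profs = {sid: _Prof([sid], [s], index) for sid, s in seqs}
    if len(seqs) == 2:
        merged = _merge_profiles(profs[seqs[0][0]], profs[seqs[1][0]], M, index, go, ge)
    else:
        ids = [sid for sid, _ in seqs]
        n = len(ids)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pairwise_distance(seqs[i][1], seqs[j][1], cfg)
        guide = neighbor_joining(D, ids)

        def rec(node) -> _Prof:
            if node.is_leaf():
                return profs[node.taxon.label]
            children = [rec(c) for c in node.child_nodes()]
            acc = children[0]
            for ch in children[1:]:
                acc = _merge_profiles(acc, ch, M, index, go, ge)
            return acc

        merged = rec(guide.seed_node)
    order = {sid: k for k, (sid, _) in enumerate(seqs)}
    recs = sorted(zip(merged.ids, merged.rows), key=lambda t: order[t[0]])
    return Msa(records=list(recs))


def trim_alignment(
    msa: Msa, max_gap_fraction: float = 0.5, min_conservation: float = 0.5
) -> Msa:
    """Conserved-block column filter (a simplified Gblocks-style trim).

    Keeps columns whose gap fraction is <= ``max_gap_fraction`` and whose
    majority residue (among non-gap characters) reaches ``min_conservation``
    of the non-gap entries.  Raises if nothing survives.
    """
    nseq = msa.nseq
    keep: list[int] = []
    for j in range(msa.ncols):
        col = [s[j] for _, s in msa.records]
        gaps = sum(1 for c in col if c == "-")
        if gaps / nseq > max_gap_fraction:
            continue
        residues = [c for c in col if c != "-"]
        top = max(residues.count(c) for c in set(residues))
        if top / len(residues) < min_conservation:
            continue
        keep.append(j)
    if not keep:
        raise ValueError("all columns removed by trimming")
    return Msa(records=[(i, "".join(s[j] for j in keep)) for i, s in msa.records])


# ---------------------------------------------------------------------------
# maximum parsimony
# ---------------------------------------------------------------------------

def _encode_masks(msa: Msa) -> np.ndarray:
    """Per-leaf, per-column character-state bitmasks; 0 encodes gap/unknown.

    The state alphabet is whatever characters the MSA uses ('-' and 'X' are
    missing data), so reduced alphabets work unchanged.
    """
    chars = sorted({c for _, s in msa.records for c in s} - {"-", "X"})
    if len(chars) > 25:
        raise ValueError("state alphabet too large for bitmask encoding")
    index = {c: k for k, c in enumerate(chars)}
    masks = np.zeros((msa.nseq, msa.ncols), dtype=np.uint32)
    for i, (_, s) in enumerate(msa.records):
        for j, c in enumerate(s):
            k = index.get(c)
            if k is not None:
                masks[i, j] = np.uint32(1 << k)
    return masks


def _postorder_arrays(adj: dict[int, set[int]], n_leaves: int):
    """Left/right child arrays for Fitch, rooting on the lowest leaf's edge."""
    r = min(u for u in adj if u < n_leaves)
    v0 = next(iter(adj[r]))
    order: list[tuple[int, int, int]] = []  # (node, child_a, child_b) in postorder
    index_of: dict[int, int] = {}

    def rec(u: int, parent: int) -> int:
        if u < n_leaves:
            return u
        kids = sorted(k for k in adj[u] if k != parent)
        a = rec(kids[0], u)
        b = rec(kids[1], u)
        order.append((u, a, b))
        idx = n_leaves + len(order) - 1
        index_of[u] = idx
        return idx

    top = rec(v0, r)
    order.append((-1, r, top))  # virtual root joining the lowest leaf and the rest
    left = np.array([a for _, a, _ in order], dtype=np.int64)
    right = np.array([b for _, _, b in order], dtype=np.int64)
    return left, right


def _score_adj(adj, n_leaves, masks, weights) -> float:
    if n_leaves == 2:
        a, b = masks[0], masks[1]
        disjoint = ((np.where(a == 0, np.uint32((1 << 25) - 1), a)
                     & np.where(b == 0, np.uint32((1 << 25) - 1), b)) == 0)
        return float(weights[disjoint].sum())
    left, right = _postorder_arrays(adj, n_leaves)
    return float(fitch_score(left, right, masks, weights))


def _edges(adj) -> list[tuple[int, int]]:
    return sorted({(min(u, v), max(u, v)) for u in adj for v in adj[u]})


def _copy(adj):
    return {u: set(vs) for u, vs in adj.items()}


def _insert_leaf(adj, leaf: int, edge: tuple[int, int], new_internal: int):
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_internal] = {u, v, leaf}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj[leaf] = {new_internal}


def _canonical(adj, n_leaves) -> str:
    def rec(u: int, parent: int):
        if u < n_leaves:
            return u, str(u)
        kids = [rec(k, u) for k in adj[u] if k != parent]
        kids.sort(key=lambda t: t[0])
        return kids[0][0], "(" + ",".join(s for _, s in kids) + ")"

    r = min(u for u in adj if u < n_leaves)
    v0 = next(iter(adj[r]))
    return f"({r}," + rec(v0, r)[1] + ")"


def enumerate_unrooted_topologies(n_leaves: int):
    """Yield every unrooted binary topology over leaves 0..n-1 (adjacency
    dicts); (2n-5)!! trees, intended for oracle checks at small n."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    hub = n_leaves
    base = {0: {hub}, 1: {hub}, 2: {hub}, hub: {0, 1, 2}}

    def rec(adj, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield adj
            return
        for edge in _edges(adj):
            child = _copy(adj)
            _insert_leaf(child, next_leaf, edge, next_internal)
            yield from rec(child, next_leaf + 1, next_internal + 1)

    yield from rec(base, 3, n_leaves + 1)


def _nni_neighbors(adj, n_leaves):
    """All NNI rearrangements (two per internal edge), deterministic order."""
    out = []
    for u, v in _edges(adj):
        if u < n_leaves or v < n_leaves:
            continue
        a, b = sorted(k for k in adj[u] if k != v)
        c, d = sorted(k for k in adj[v] if k != u)
        for x, y in ((b, c), (b, d)):
            alt = _copy(adj)
            alt[u].discard(x)
            alt[x].discard(u)
            alt[v].discard(y)
            alt[y].discard(v)
            alt[u].add(y)
            alt[y].add(u)
            alt[v].add(x)
            alt[x].add(v)
            out.append(alt)
    return out


def _stepwise_tree(order: Sequence[int], masks, weights, n_leaves: int):
    adj = {
        order[0]: {n_leaves},
        order[1]: {n_leaves},
        order[2]: {n_leaves},
        n_leaves: {order[0], order[1], order[2]},
    }
    nxt = n_leaves + 1
    for leaf in order[3:]:
        best = None
        for edge in _edges(adj):
            cand = _copy(adj)
            _insert_leaf(cand, leaf, edge, nxt)
            sc = _score_adj(cand, n_leaves, masks, weights)
            if best is None or sc < best[0]:
                best = (sc, cand)
        adj = best[1]
        nxt += 1
    return adj


def _hill_climb(adj, masks, weights, n_leaves: int):
    score = _score_adj(adj, n_leaves, masks, weights)
    improved = True
    while improved:
        improved = False
        for alt in _nni_neighbors(adj, n_leaves):
            sc = _score_adj(alt, n_leaves, masks, weights)
            if sc < score - 1e-9:
                adj, score = alt, sc
                improved = True
                break
    return adj, score


def _spr_neighbors(adj, n_leaves):
    """Subtree-prune-and-regraft rearrangements, deterministic order.

    For each directed edge (p, s) the subtree rooted at s (away from p) is
    pruned — p's remaining two neighbors are joined — and regrafted onto
    every edge of the remaining tree.
    """
    out = []
    for p, s in _directed_edges(adj):
        if p < n_leaves:
            continue  # the prune point must be an internal node
        rest = _copy(adj)
        # detach the subtree rooted at s; p's remaining neighbors are joined
        rest[p].discard(s)
        rest[s].discard(p)
        a, b = sorted(rest.pop(p))
        rest[a].discard(p)
        rest[b].discard(p)
        rest[a].add(b)
        rest[b].add(a)
        sub_nodes = _component(rest, s)
        for x, y in _edges(rest):
            if x in sub_nodes or y in sub_nodes:
                continue
            if {x, y} == {a, b}:
                continue  # regrafting here recreates the original topology
            cand = {u: set(vs) for u, vs in rest.items()}
            cand[x].discard(y)
            cand[y].discard(x)
            cand[p] = {x, y, s}
            cand[x].add(p)
            cand[y].add(p)
            cand[s].add(p)
            out.append(cand)
    return out


def _directed_edges(adj):
    return sorted((u, v) for u in adj for v in adj[u])


def _component(adj, start):
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for w in adj.get(u, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return seen


def _search_adj(
    masks, weights, n_leaves: int, seed: int, restarts: int = 5, spr: bool = True
):
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            order = list(range(n_leaves))
        else:
            order = [int(x) for x in rng.permutation(n_leaves)]
        adj = _stepwise_tree(order, masks, weights, n_leaves)
        adj, score = _hill_climb(adj, masks, weights, n_leaves)
        while spr:
            better = None
            for alt in _spr_neighbors(adj, n_leaves):
                sc = _score_adj(alt, n_leaves, masks, weights)
                if sc < score - 1e-9:
                    better = (alt, sc)
                    break
            if better is None:
                break
            adj, score = _hill_climb(better[0], masks, weights, n_leaves)
        key = (score, _canonical(adj, n_leaves))
        if best is None or key < best[0]:
            best = (key, adj)
    (score, _), adj = best
    return adj, score


def _adj_to_newick(adj, n_leaves, names, supports=None, lengths: float = 1.0,
                   root_edge: tuple[int, int] | None = None):
    """Newick of the unrooted tree, rooted on an edge (default: the lowest
    leaf's pendant edge).

    ``supports`` maps frozensets of leaf indices (one bipartition side) to
    integer support labels.
    """

    def rec(u: int, parent: int) -> tuple[frozenset, str]:
        if u < n_leaves:
            return frozenset([u]), f"{names[u]}:{lengths}"
        parts = []
        below: set[int] = set()
        for k in sorted(x for x in adj[u] if x != parent):
            side, s = rec(k, u)
            below |= side
            parts.append(s)
        side = frozenset(below)
        lab = ""
        if supports is not None and side in supports:
            lab = str(supports[side])
        return side, "(" + ",".join(parts) + f"){lab}:{lengths}"

    if root_edge is None:
        r = min(u for u in adj if u < n_leaves)
        root_edge = (r, next(iter(adj[r])))
    u, v = root_edge
    _, left = rec(u, v)
    _, right = rec(v, u)
    return f"({left},{right});"


def _midpoint_edge(adj, n_leaves) -> tuple[int, int]:
    """Edge containing the topological midpoint (unit branch lengths).

    Double sweep: farthest leaf from leaf 0, then the diameter path from it;
    the midpoint edge is the central edge of that path (ties broken toward
    smaller node ids).
    """
    import collections

    def bfs(start):
        dist, parent = {start: 0}, {start: None}
        q = collections.deque([start])
        while q:
            x = q.popleft()
            for w in sorted(adj[x]):
                if w not in dist:
                    dist[w] = dist[x] + 1
                    parent[w] = x
                    q.append(w)
        return dist, parent

    leaves = [x for x in adj if x < n_leaves]
    d0, _ = bfs(min(leaves))
    a = min(leaves, key=lambda x: (-d0[x], x))
    da, pa = bfs(a)
    b = min(leaves, key=lambda x: (-da[x], x))
    path = [b]
    while pa[path[-1]] is not None:
        path.append(pa[path[-1]])
    L = len(path) - 1  # number of edges on the diameter path
    return path[(L - 1) // 2], path[(L + 1) // 2]


def _tree_to_adj(tree: dendropy.Tree, id_index: dict[str, int]):
    """Unrooted adjacency from a dendropy tree (root of degree 2 suppressed)."""
    n_leaves = len(id_index)
    adj: dict[int, set[int]] = {}
    node_id: dict[int, int] = {}
    nxt = [n_leaves]

    def get_id(nd) -> int:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            return id_index[label]
        if id(nd) not in node_id:
            node_id[id(nd)] = nxt[0]
            nxt[0] += 1
        return node_id[id(nd)]

    def add_edge(a, b):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            add_edge(get_id(nd), get_id(ch))
    # suppress degree-2 nodes (rooted representation of an unrooted tree)
    for u in [u for u in list(adj) if len(adj[u]) == 2 and u >= n_leaves]:
        a, b = adj.pop(u)
        adj[a].discard(u)
        adj[b].discard(u)
        adj[a].add(b)
        adj[b].add(a)
    return adj


def parsimony_score(tree, msa: Msa, weights: np.ndarray | None = None) -> int:
    """Fitch small-parsimony score of a fixed topology on an MSA.

    ``tree`` may be a dendropy Tree or a newick string; its leaf labels must
    match the MSA record ids.  Gaps are missing data; the score is invariant
    to leaf order and to (re)rooting.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    id_index = {sid: i for i, sid in enumerate(msa.ids)}
    leaf_labels = {lf.taxon.label if lf.taxon else lf.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(id_index):
        raise ValueError("tree leaf set must equal MSA record ids")
    adj = _tree_to_adj(tree, id_index)
    masks = _encode_masks(msa)
    w = weights if weights is not None else np.ones(msa.ncols)
    return int(round(_score_adj(adj, msa.nseq, masks, np.asarray(w, dtype=np.float64))))


def search_mp_tree(
    msa: Msa, seed: int = 0, restarts: int = 5, weights: np.ndarray | None = None
):
    """Heuristic maximum-parsimony search; returns (newick, score).

    Random-addition-order stepwise insertion followed by NNI hill climbing,
    repeated over ``restarts`` addition orders; deterministic per seed.
    With fewer than 4 sequences the unique topology is returned.
    """
    n = msa.nseq
    if n < 2:
        raise ValueError("need at least 2 sequences")
    masks = _encode_masks(msa)
    w = np.asarray(weights if weights is not None else np.ones(msa.ncols), dtype=np.float64)
    names = msa.ids
    if n == 2:
        score = _score_adj({0: {1}, 1: {0}}, 2, masks, w)
        return f"({names[0]}:1.0,{names[1]}:1.0);", int(round(score))
    if n == 3:
        adj = {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
        return _adj_to_newick(adj, 3, names), int(round(_score_adj(adj, 3, masks, w)))
    adj, score = _search_adj(masks, w, n, seed, restarts)
    return _adj_to_newick(adj, n, names), int(round(score))


def _splits(adj, n_leaves) -> set[frozenset]:
    out = set()

    def rec(u: int, parent: int) -> frozenset:
        if u < n_leaves:
            return frozenset([u])
        below: set[int] = set()
        for k in adj[u]:
            if k != parent:
                below |= rec(k, u)
        side = frozenset(below)
        if 1 < len(side) < n_leaves - 1:
            out.add(side)
        return side

    v0 = next(iter(adj[0]))
    rec(v0, 0)
    return out


def bootstrap_support(
    msa: Msa,
    replicates: int = 100,
    seed: int = 0,
    restarts: int = 5,
    bootstrap_restarts: int = 2,
) -> SupportTree:
    """Column-resampling bootstrap supports on the best full-data MP tree.

    Each replicate resamples columns with replacement (implemented as Fitch
    column weights), reruns the parsimony search, and the support of each
    bipartition of the full-data tree is the percentage of replicate trees
    containing it.  The supported tree is midpoint-rooted on unit branch
    lengths.
    """
    n = msa.nseq
    masks = _encode_masks(msa)
    w1 = np.ones(msa.ncols)
    names = msa.ids
    rng = np.random.default_rng(seed)
    if n < 4:
        nwk, _ = search_mp_tree(msa, seed=seed, restarts=restarts)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        return SupportTree(tree=tree)
    adj, _ = _search_adj(masks, w1, n, int(rng.integers(2**31)), restarts)
    target = _splits(adj, n)
    counts = {s: 0 for s in target}
    for _ in range(replicates):
        w = rng.multinomial(msa.ncols, np.full(msa.ncols, 1.0 / msa.ncols)).astype(np.float64)
        radj, _ = _search_adj(
            masks, w, n, int(rng.integers(2**31)), bootstrap_restarts, spr=False
        )
        rsplits = _splits(radj, n)
        for s in target:
            if s in rsplits:
                counts[s] += 1
    supports = {s: int(round(100.0 * c / replicates)) for s, c in counts.items()}
    nwk = _adj_to_newick(adj, n, names, root_edge=_midpoint_edge(adj, n))
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    # annotate supports on the rooted tree: each internal node's clade is one
    # side of an unrooted bipartition; look its support up by the canonical
    # (away-from-leaf-0) side
    name_idx = {nm: i for i, nm in enumerate(names)}
    everything = frozenset(range(n))
    for nd in tree.preorder_node_iter():
        if nd.is_leaf() or nd is tree.seed_node:
            continue
        side = frozenset(name_idx[lf.taxon.label] for lf in nd.leaf_iter())
        key = side if 0 not in side else everything - side
        nd.label = str(supports[key]) if key in supports else None
    return SupportTree(tree=tree)


def extract_supported_groups(
    stree: SupportTree | dendropy.Tree,
    threshold: int = 50,
    min_size: int = 4,
    strict: bool = False,
):
    """Supported maximal clades as sequence groups.

    A group is the leaf set of a maximal clade whose subtending node support
    exceeds ``threshold`` while its parent's does not (or the parent is the
    root); with ``strict=True`` every internal node inside the clade must
    also exceed the threshold.  Groups smaller than ``min_size`` are
    discarded; ungrouped leaves are returned as unclassified.

    Returns ``(groups, unclassified)``.
    """
    tree = stree.tree if isinstance(stree, SupportTree) else stree
    if not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        logger.info("unrooted input; applying midpoint rooting")
        for e in tree.preorder_edge_iter():
            if e.length is None:
                e.length = 1.0
        tree.reroot_at_midpoint(update_bipartitions=False)

    def sup(nd) -> int | None:
        if nd.is_leaf() or nd is tree.seed_node:
            return None
        if nd.label in (None, ""):
            return None
        return int(nd.label)

    def subtree_supported(nd) -> bool:
        for d in nd.preorder_iter():
            if d.is_leaf() or d is nd:
                continue
            s = sup(d)
            if s is None or s <= threshold:
                return False
        return True

    candidates = []
    for nd in tree.preorder_node_iter():
        s = sup(nd)
        if s is None or s <= threshold:
            continue
        if strict:
            if not subtree_supported(nd):
                continue
        else:
            parent = nd.parent_node
            ps = sup(parent) if parent is not None else None
            if ps is not None and ps > threshold:
                continue
        candidates.append(nd)
    # keep only maximal candidates (no candidate ancestor)
    chosen = []
    selected = set()
    for nd in candidates:  # preorder: ancestors come first
        anc = nd.parent_node
        inside = False
        while anc is not None:
            if id(anc) in selected:
                inside = True
                break
            anc = anc.parent_node
        if not inside:
            chosen.append(nd)
            selected.add(id(nd))

    groups: list[CladeGroup] = []
    grouped: set[str] = set()
    chosen_info = []
    for nd in chosen:
        members = sorted(lf.taxon.label for lf in nd.leaf_iter())
        if len(members) < min_size:
            continue
        chosen_info.append((members, sup(nd)))
    chosen_info.sort(key=lambda t: t[0])
    for k, (members, s) in enumerate(chosen_info):
        groups.append(CladeGroup(group_id=f"C{k + 1}", members=members, support=int(s)))
        grouped.update(members)
    unclassified = sorted(
        lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label not in grouped
    )
    return groups, unclassified
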