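"""Forward simulation of gene-family evolution along a species tree.

The simulator stands in for real per-strain protein sets.  It produces, for a
known species phylogeny, gene families shaped by lineage-specific duplication,
loss and (optionally) horizontal transfer, together with ground-truth ortholog
groups, so that every downstream grouping step can be scored against truth.

The model, in run order:

1. a pure-birth (Yule) species tree with ``n_species`` extant strains;
2. per family, a birth--death-with-transfer process along every species
   branch starting from a single root gene: duplications split a gene
   lineage in place, losses prune it, transfers move it onto a
   contemporaneous branch of the species tree;
3. sequences evolved down the resulting gene tree under a 20-state
   equal-rates substitution model (a Jukes--Cantor analogue for amino
   acids), no indels by default.

True ortholog groups are defined by duplication age: duplications older than
``resolution_depth`` x (tree height) found new groups, younger duplications
produce in-paralogs that stay in their parent's group.  This mirrors
genus-level radiations: deep duplicates behave as distinct families, shallow
ones as recent paralogs.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "TreeNode",
    "SpeciesTree",
    "GeneFamilyTruth",
    "SimulationConfig",
    "simulate_species_tree",
    "simulate_gene_family",
    "evolve_sequences",
    "calibrate_subst_rate",
    "jc20_p_distance",
    "write_fixture",
    "read_truth_table",
    "simulate_dataset",
]


@dataclass
class ProteinRecord:
    """One peptide with its strain of origin and optional truth labels."""

    gene_id: str
    strain: str
    sequence: str
    family: str | None = None
    true_group: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id}")


@dataclass
class TreeNode:
    """Node of a simulated (species or gene) tree; ``time`` is age from root."""

    name: str
    time: float
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None
    # gene-tree bookkeeping
    strain: str | None = None
    event: str | None = None  # "speciation" | "duplication" | "transfer" | None
    group: str | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            nd = stack.pop()
            if nd.is_leaf():
                out.append(nd)
            else:
                stack.extend(reversed(nd.children))
        return out

    def newick(self, with_lengths: bool = True) -> str:
        def rec(nd: TreeNode) -> str:
            if nd.is_leaf():
                lab = nd.name
            else:
                lab = "(" + ",".join(rec(c) for c in nd.children) + ")"
            if with_lengths and nd.parent is not None:
                lab += f":{nd.time - nd.parent.time:.6f}"
            return lab

        return rec(self) + ";"


@dataclass
class SpeciesTree:
    """Rooted binary ultrametric tree over uniquely named strains."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    @property
    def height(self) -> float:
        return max(lf.time for lf in self.root.leaves())

    def newick(self) -> str:
        return self.root.newick()

    def mean_leaf_pair_distance(self) -> float:
        """Mean patristic (time) distance over all leaf pairs."""
        leaves = self.root.leaves()
        total = 0.0
        npairs = 0
        for i, a in enumerate(leaves):
            for b in leaves[i + 1 :]:
                total += _patristic_time(a, b)
                npairs += 1
        return total / npairs if npairs else 0.0


def _patristic_time(a: TreeNode, b: TreeNode) -> float:
    anc_a = {}
    nd: TreeNode | None = a
    while nd is not None:
        anc_a[id(nd)] = nd
        nd = nd.parent
    nd = b
    while id(nd) not in anc_a:
        assert nd is not None
        nd = nd.parent
    mrca = anc_a[id(nd)]
    return (a.time - mrca.time) + (b.time - mrca.time)


@dataclass
class GeneFamilyTruth:
    """Simulated gene family: surviving gene trees plus truth labels."""

    family: str
    gene_trees: list[TreeNode]
    events: list[tuple[str, str, float]]  # (kind, species branch child name, time)
    true_groups: dict[str, str]  # gene id -> group id
    origin: dict[str, str]  # gene id -> strain id

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.origin)

    def partition(self) -> dict[str, set[str]]:
        part: dict[str, set[str]] = {}
        for gid, grp in self.true_groups.items():
            part.setdefault(grp, set()).add(gid)
        return part


@dataclass
class SimulationConfig:
    """All knobs of the generator; a fixed seed makes every output identical.

    Rates are per unit tree time.  ``subst_rate=None`` calibrates the rate so
    that the expected pairwise difference between two average strains equals
    ``target_divergence`` (solve the 20-state JC p-distance at the mean
    leaf-pair patristic time).
    """

    n_species: int = 12
    n_families: int = 4
    birth_rate: float = 1.0
    dup_rate: float = 0.3
    loss_rate: float = 0.1
    transfer_rate: float = 0.0
    root_length: int = 300
    subst_rate: float | None = None
    target_divergence: float = 0.2
    resolution_depth: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        for r in (self.birth_rate, self.dup_rate, self.loss_rate, self.transfer_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.root_length <= 0:
            raise ValueError("root_length must be > 0")


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

def simulate_species_tree(
    n_species: int, birth_rate: float = 1.0, seed: int | np.random.Generator = 0
) -> SpeciesTree:
    """Sample a Yule (pure-birth) species tree with ``n_species`` extant tips.

    The tree is rooted, binary and exactly ultrametric: after the last
    speciation all lineages are extended by one further exponential waiting
    time so no terminal branch has zero length.  Leaves are named
    ``S01 … Snn`` in a deterministic traversal order.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    root = TreeNode(name="", time=0.0)
    tips: list[TreeNode] = []
    for _ in range(2):
        child = TreeNode(name="", time=0.0, parent=root)
        root.children.append(child)
        tips.append(child)
    t = 0.0
    while len(tips) < n_species:
        k = len(tips)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        nd = tips[idx]
        nd.time = t
        for _ in range(2):
            child = TreeNode(name="", time=t, parent=nd)
            nd.children.append(child)
        tips[idx : idx + 1] = nd.children
    t += rng.exponential(1.0 / (birth_rate * len(tips)))
    for tip in tips:
        tip.time = t
    for i, leaf in enumerate(root.leaves()):
        leaf.name = f"S{i + 1:02d}"
    return SpeciesTree(root=root)


# ---------------------------------------------------------------------------
# gene family evolution
# ---------------------------------------------------------------------------

def _species_branches(tree: SpeciesTree) -> list[TreeNode]:
    """All non-root nodes; the branch is (node.parent.time, node.time]."""
    out = []
    stack = [tree.root]
    while stack:
        nd = stack.pop()
        if nd.parent is not None:
            out.append(nd)
        stack.extend(reversed(nd.children))
    return out


def simulate_gene_family(
    tree: SpeciesTree,
    dup_rate: float = 0.3,
    loss_rate: float = 0.1,
    transfer_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    family: str = "fam1",
    resolution_depth: float = 0.5,
) -> GeneFamilyTruth:
    """Run a duplication/loss/transfer birth--death process along ``tree``.

    One ancestral gene enters the species root.  Along each species branch a
    gene lineage experiences duplications (rate ``dup_rate``), losses
    (``loss_rate``) and transfers (``transfer_rate``) as a Poisson process;
    at speciation nodes surviving lineages enter both daughter branches.
    Transfers move the lineage onto a uniformly chosen contemporaneous
    species branch.

    True groups: duplications at ages older than ``resolution_depth`` x tree
    height found new groups; younger duplications inherit the parent group.
    """
    for r in (dup_rate, loss_rate, transfer_rate):
        if r < 0:
            raise ValueError("rates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    height = tree.height
    cutoff = resolution_depth * height
    branches = _species_branches(tree)

    events: list[tuple[str, str, float]] = []
    group_counter = [0]
    gene_counter: dict[str, int] = {}
    origin: dict[str, str] = {}
    true_groups: dict[str, str] = {}

    def new_group() -> str:
        group_counter[0] += 1
        return f"{family}.g{group_counter[0]}"

    def contemporaries(t: float, exclude: TreeNode) -> list[TreeNode]:
        out = []
        for br in branches:
            if br is exclude:
                continue
            assert br.parent is not None
            if br.parent.time <= t < br.time:
                out.append(br)
        return out

    total_rate = dup_rate + loss_rate + transfer_rate

    def evolve_on_branch(gnode: TreeNode, sp: TreeNode, t: float) -> None:
        """Evolve the lineage hanging below ``gnode`` along species branch ``sp``
        starting at time ``t``; ``gnode`` has time ``t`` already set."""
        cur_sp = sp
        while True:
            if total_rate > 0:
                dt = rng.exponential(1.0 / total_rate)
            else:
                dt = math.inf
            if t + dt >= cur_sp.time:
                # survives to the bottom of the species branch
                if cur_sp.is_leaf():
                    strain = cur_sp.name
                    k = gene_counter.get(strain, 0) + 1
                    gene_counter[strain] = k
                    gid = f"{family}|{strain}|{k:03d}"
                    leaf = TreeNode(
                        name=gid, time=cur_sp.time, parent=gnode, strain=strain,
                        group=gnode.group,
                    )
                    gnode.children.append(leaf)
                    origin[gid] = strain
                    true_groups[gid] = gnode.group or ""
                    return
                spec = TreeNode(
                    name="", time=cur_sp.time, parent=gnode,
                    event="speciation", group=gnode.group,
                )
                gnode.children.append(spec)
                for child_sp in cur_sp.children:
                    evolve_on_branch(spec, child_sp, cur_sp.time)
                return
            t = t + dt
            u = rng.random() * total_rate
            if u < dup_rate:
                events.append(("duplication", cur_sp.name or "<internal>", t))
                dup = TreeNode(
                    name="", time=t, parent=gnode, event="duplication",
                    group=gnode.group,
                )
                gnode.children.append(dup)
                if t < cutoff:
                    left_grp, right_grp = new_group(), new_group()
                else:
                    left_grp = right_grp = dup.group
                # two daughter lineages continue on the same species branch
                for grp in (left_grp, right_grp):
                    stub = TreeNode(name="", time=t, parent=dup, group=grp)
                    dup.children.append(stub)
                    evolve_on_branch(stub, cur_sp, t)
                    # stub is a degree-2 placeholder; flattened during pruning
                return
            elif u < dup_rate + loss_rate:
                events.append(("loss", cur_sp.name or "<internal>", t))
                return
            else:
                targets = contemporaries(t, cur_sp)
                if not targets:
                    continue  # nowhere to go; transfer has no effect
                tgt = targets[int(rng.integers(len(targets)))]
                events.append(("transfer", tgt.name or "<internal>", t))
                hop = TreeNode(
                    name="", time=t, parent=gnode, event="transfer",
                    group=gnode.group,
                )
                gnode.children.append(hop)
                gnode = hop
                cur_sp = tgt

    root_gene = TreeNode(name="", time=0.0, event="speciation", group=new_group())
    for child_sp in tree.root.children:
        evolve_on_branch(root_gene, child_sp, 0.0)

    pruned = _prune_gene_tree(root_gene)
    gene_trees = [pruned] if pruned is not None else []
    return GeneFamilyTruth(
        family=family,
        gene_trees=gene_trees,
        events=events,
        true_groups=true_groups,
        origin=origin,
    )


def _prune_gene_tree(root: TreeNode) -> TreeNode | None:
    """Drop extinct lineages and suppress degree-2 internals (keeping times)."""

    def rec(nd: TreeNode) -> TreeNode | None:
        if nd.is_leaf():
            return nd if nd.strain is not None else None
        kept = [c for c in (rec(c) for c in nd.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        nd.children = kept
        for c in kept:
            c.parent = nd
        return nd

    out = rec(root)
    if out is not None:
        out.parent = None
    return out


# ---------------------------------------------------------------------------
# sequence evolution (20-state equal-rates model)
# ---------------------------------------------------------------------------

def jc20_p_distance(t: float, subst_rate: float) -> float:
    """Expected fraction of differing sites after time ``t``:
    p(t) = (19/20) * (1 - exp(-20*r*t/19))."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * subst_rate * t / 19.0))


def calibrate_subst_rate(tree: SpeciesTree, target_divergence: float = 0.2) -> float:
    """Substitution rate at which two average strains differ at
    ``target_divergence`` of sites (inverting the 20-state JC p-distance at
    the mean leaf-pair patristic time)."""
    if not 0 < target_divergence < 19.0 / 20.0:
        raise ValueError("target_divergence must be in (0, 0.95)")
    tbar = tree.mean_leaf_pair_distance()
    return -(19.0 / (20.0 * tbar)) * math.log(1.0 - (20.0 / 19.0) * target_divergence)


def evolve_sequences(
    family: GeneFamilyTruth,
    length: int = 300,
    subst_rate: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> list[ProteinRecord]:
    """Evolve an i.i.d. uniform root sequence down every gene tree.

    Along a branch of time-length t each site independently substitutes to a
    uniformly chosen *different* residue with probability
    p(t) = (19/20)(1 - exp(-20*r*t/19)); no indels, so all sequences share
    ``length``.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    if subst_rate < 0:
        raise ValueError("subst_rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records: list[ProteinRecord] = []

    for gtree in family.gene_trees:
        root_seq = rng.integers(0, 20, size=length)
        stack = [(gtree, root_seq)]
        while stack:
            nd, seq = stack.pop()
            if nd.is_leaf():
                s = aa[seq].tobytes().decode()
                records.append(
                    ProteinRecord(
                        gene_id=nd.name,
                        strain=nd.strain or "",
                        sequence=s,
                        family=family.family,
                        true_group=family.true_groups.get(nd.name),
                    )
                )
                continue
            for child in nd.children:
                t = child.time - nd.time
                p = jc20_p_distance(t, subst_rate)
                mutated = seq.copy()
                hit = rng.random(length) < p
                n_hit = int(hit.sum())
                if n_hit:
                    # uniform over the 19 other residues
                    shift = rng.integers(1, 20, size=n_hit)
                    mutated[hit] = (mutated[hit] + shift) % 20
                stack.append((child, mutated))
    records.sort(key=lambda r: r.gene_id)
    return records


# ---------------------------------------------------------------------------
# fixture writing / whole-dataset convenience
# ---------------------------------------------------------------------------

def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fixture(
    families: Sequence[GeneFamilyTruth],
    records: Sequence[ProteinRecord],
    tree: SpeciesTree,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write one FASTA per strain, a truth TSV and the species-tree Newick.

    FASTA headers are ``>strain|gene_id`` (the gene id itself embeds family
    and strain); sequences are wrapped at 60 columns.  Returns a map of
    logical names to the paths written.
    """
    if not families:
        raise ValueError("need at least one family")
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    strains = tree.leaf_names
    by_strain: dict[str, list[ProteinRecord]] = {s: [] for s in strains}
    for rec in records:
        by_strain.setdefault(rec.strain, []).append(rec)

    paths: dict[str, str] = {}
    for strain in strains:
        path = os.path.join(outdir, f"{strain}.fasta")
        with open(path, "w") as fh:
            for rec in sorted(by_strain[strain], key=lambda r: r.gene_id):
                fh.write(f">{strain}|{rec.gene_id}\n{_wrap(rec.sequence)}\n")
        paths[f"fasta:{strain}"] = path

    truth_path = os.path.join(outdir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("gene_id\tstrain\tfamily\ttrue_group\n")
        for fam in families:
            for gid in fam.gene_ids:
                fh.write(
                    f"{gid}\t{fam.origin[gid]}\t{fam.family}\t{fam.true_groups[gid]}\n"
                )
    paths["truth"] = truth_path

    tree_path = os.path.join(outdir, "species_tree.nwk")
    with open(tree_path, "w") as fh:
        fh.write(tree.newick() + "\n")
    paths["species_tree"] = tree_path
    return paths


def read_truth_table(path: str | os.PathLike) -> dict[str, str]:
    """Read the truth TSV back as a gene_id -> true_group map."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["gene_id", "strain", "family", "true_group"]:
            raise ValueError(f"unexpected truth-table header: {header}")
        for line in fh:
            gid, _strain, _fam, grp = line.rstrip("\n").split("\t")
            out[gid] = grp
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[SpeciesTree, list[GeneFamilyTruth], list[ProteinRecord]]:
    """Full generator: species tree, families and sequences from one config.

    The config seed fans out to independent streams (tree / each family /
    each family's sequences) via ``numpy.random.SeedSequence.spawn``, so any
    sub-result is reproducible in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_ss, *fam_ss = ss.spawn(1 + 2 * config.n_families)
    tree = simulate_species_tree(
        config.n_species, config.birth_rate, np.random.default_rng(tree_ss)
    )
    rate = (
        config.subst_rate
        if config.subst_rate is not None
        else calibrate_subst_rate(tree, config.target_divergence)
    )
    families: list[GeneFamilyTruth] = []
    records: list[ProteinRecord] = []
    for i in range(config.n_families):
        fam = simulate_gene_family(
            tree,
            dup_rate=config.dup_rate,
            loss_rate=config.loss_rate,
            transfer_rate=config.transfer_rate,
            seed=np.random.default_rng(fam_ss[2 * i]),
            family=f"fam{i + 1}",
            resolution_depth=config.resolution_depth,
        )
        families.append(fam)
        records.extend(
            evolve_sequences(
                fam,
                length=config.root_length,
                subst_rate=rate,
                seed=np.random.default_rng(fam_ss[2 * i + 1]),
            )
        )
    return tree, families, records
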