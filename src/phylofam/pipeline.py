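"""End-to-end orchestration: search -> {similarity, phylogeny} grouping ->
gene-content clustering -> congruence, with manifest logging.

A run either consumes user-supplied inputs (per-strain FASTAs, per-family
query FASTAs, a species-tree newick) or generates a fully synthetic fixture
from a :class:`~phylofam.simulate.SimulationConfig`.  In fixture mode the
family query sets are drawn from the first few strains (mirroring curated
query sets collated from a handful of reference genomes) and the seed
alignment of each family is the progressive alignment of its queries.

All stage randomness fans out from one global seed by stable hashing of
stage names, so a stage re-run in isolation reproduces its in-pipeline
result, and two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .simulate import (
    ProteinRecord,
    SimulationConfig,
    simulate_dataset,
    write_fixture,
)
from .search import (
    SearchConfig,
    dedup_and_filter_fragments,
    identify_family_members,
    read_fasta,
)
from .ortho import (
    MclConfig,
    all_vs_all_similarity,
    build_orthomcl_graph,
    filter_small_groups,
    mcl_detailed,
)
from .genetrees import (
    bootstrap_support,
    extract_supported_groups,
    progressive_align,
    trim_alignment,
)
from .content import build_count_matrix, complete_linkage, euclidean_distances
from .congruence import cadm_test, cophenetic_distances, patristic_distances

__all__ = ["RunConfig", "run_pipeline", "compare_group_paths", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of the stage name mixed with the run seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed * 2654435761)) % (2**31)


@dataclass
class RunConfig:
    """One configuration object driving every stage (serialized verbatim
    into the run manifest)."""

    outdir: str = "run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    search: SearchConfig = field(default_factory=SearchConfig)
    mcl: MclConfig = field(default_factory=MclConfig)
    inflation_per_family: dict[str, float] = field(default_factory=dict)
    n_query_strains: int = 4
    bootstrap_replicates: int = 100
    support_threshold: int = 50
    min_group_size: int = 4
    permutations: int = 999
    # input-paths mode (used when simulation is None)
    strain_fastas: list[str] = field(default_factory=list)
    family_queries: dict[str, str] = field(default_factory=dict)
    species_tree_path: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and not self.strain_fastas:
            self.simulation = SimulationConfig(seed=self.seed)


def _write_tsv(path: str, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _write_matrix(path: str, matrix: pd.DataFrame) -> None:
    matrix.to_csv(path, sep="\t", index_label="strain")


def run_pipeline(config: RunConfig) -> str:
    """Execute the full pipeline; returns the run directory.

    Writes: the fixture (fixture mode), hits.tsv, curated_<family>.fasta,
    groups_ortho.tsv / groups_phylo.tsv, trees, count matrices, dendrogram
    newicks, congruence.tsv, comparison.tsv and manifest.json.  Outputs are
    deterministic per config (no timestamps).
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    stage = "init"
    try:
        # ------------------------------------------------------------------
        stage = "inputs"
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation)
            tree, families, _records = simulate_dataset(sim)
            fixdir = os.path.join(outdir, "fixture")
            write_fixture(families, _records, tree, fixdir)
            strain_paths = [
                os.path.join(fixdir, f"{s}.fasta") for s in tree.leaf_names
            ]
            species_newick = tree.newick()
            truth = {gid: fam.true_groups[gid] for fam in families for gid in fam.origin}
            family_names = [fam.family for fam in families]
        else:
            strain_paths = list(config.strain_fastas)
            with open(config.species_tree_path) as fh:
                species_newick = fh.read().strip()
            truth = {}
            family_names = sorted(config.family_queries)

        db: list[ProteinRecord] = []
        for p in strain_paths:
            db.extend(read_fasta(p))
        db.sort(key=lambda r: r.gene_id)
        strains = sorted({r.strain for r in db})
        strain_of = {r.gene_id: r.strain for r in db}

        # queries per family
        stage = "queries"
        queries: dict[str, list[ProteinRecord]] = {}
        if config.simulation is not None:
            ref = strains[: config.n_query_strains]
            for fam in family_names:
                qs = [
                    r
                    for r in db
                    if r.strain in ref and r.gene_id.startswith(f"{fam}|")
                ]
                queries[fam] = sorted(qs, key=lambda r: r.gene_id)
        else:
            for fam in family_names:
                queries[fam] = read_fasta(config.family_queries[fam], strain="query")

        # ------------------------------------------------------------------
        stage = "search"
        curated: dict[str, list[ProteinRecord]] = {}
        hit_rows = []
        for fam in family_names:
            if not queries[fam]:
                curated[fam] = []
                continue
            seed_msa_obj = progressive_align(
                [(q.gene_id, q.sequence) for q in queries[fam]], config.search
            ) if len(queries[fam]) > 1 else None
            seed_msa = (
                [s for _, s in seed_msa_obj.records]
                if seed_msa_obj is not None
                else [queries[fam][0].sequence]
            )
            cfg = dataclasses.replace(
                config.search, shuffle_seed=stage_seed(config.seed, f"search:{fam}")
            )
            hits = identify_family_members(db, queries[fam], seed_msa, cfg, family=fam)
            for h in hits:
                hit_rows.append(
                    (
                        h.gene_id,
                        strain_of[h.gene_id],
                        fam,
                        f"{h.aln_bits:.2f}",
                        f"{h.aln_evalue:.3e}",
                        f"{h.prof_bits:.2f}",
                        f"{h.prof_evalue:.3e}",
                        int(h.passed),
                    )
                )
            curated[fam] = dedup_and_filter_fragments(hits, db, cfg)
        _write_tsv(
            os.path.join(outdir, "hits.tsv"),
            ["gene_id", "strain", "family", "aln_bits", "aln_evalue", "prof_bits", "prof_evalue", "passed"],
            hit_rows,
        )
        for fam in family_names:
            with open(os.path.join(outdir, f"curated_{fam}.fasta"), "w") as fh:
                for r in curated[fam]:
                    fh.write(f">{r.strain}|{r.gene_id}\n{r.sequence}\n")

        # ------------------------------------------------------------------
        stage = "group-ortho"
        ortho_groups: dict[str, list] = {}
        ortho_rows = []
        for fam in family_names:
            recs = curated[fam]
            if len(recs) < 2:
                ortho_groups[fam] = []
                continue
            cfg = dataclasses.replace(
                config.search, shuffle_seed=stage_seed(config.seed, f"ortho:{fam}")
            )
            edges = all_vs_all_similarity(recs, cfg)
            graph = build_orthomcl_graph(edges, {r.gene_id: r.strain for r in recs})
            mcl_cfg = dataclasses.replace(
                config.mcl,
                inflation=config.inflation_per_family.get(fam, config.mcl.inflation),
            )
            groups, _, _ = mcl_detailed(graph, mcl_cfg)
            groups = filter_small_groups(groups, config.min_group_size)
            ortho_groups[fam] = groups
            for g in groups:
                for gid in g.members:
                    ortho_rows.append((g.group_id, gid, strain_of[gid], fam))
        _write_tsv(
            os.path.join(outdir, "groups_ortho.tsv"),
            ["group_id", "gene_id", "strain", "family"],
            ortho_rows,
        )

        # ------------------------------------------------------------------
        stage = "group-phylo"
        clade_groups: dict[str, list] = {}
        phylo_rows = []
        for fam in family_names:
            recs = curated[fam]
            if len(recs) < 4:
                clade_groups[fam] = []
                continue
            msa = progressive_align([(r.gene_id, r.sequence) for r in recs], config.search)
            msa = trim_alignment(msa)
            stree = bootstrap_support(
                msa,
                replicates=config.bootstrap_replicates,
                seed=stage_seed(config.seed, f"phylo:{fam}"),
            )
            with open(os.path.join(outdir, f"tree_{fam}.nwk"), "w") as fh:
                fh.write(stree.newick() + "\n")
            groups, _unclassified = extract_supported_groups(
                stree, threshold=config.support_threshold, min_size=config.min_group_size
            )
            clade_groups[fam] = groups
            for g in groups:
                for gid in g.members:
                    phylo_rows.append((g.group_id, gid, strain_of[gid], fam))
        _write_tsv(
            os.path.join(outdir, "groups_phylo.tsv"),
            ["group_id", "gene_id", "strain", "family"],
            phylo_rows,
        )

        # ------------------------------------------------------------------
        stage = "cluster"
        results: dict[str, pd.DataFrame] = {}
        dendros = {}
        for label, groupset in (("ortho", ortho_groups), ("phylo", clade_groups)):
            matrix = build_count_matrix(groupset, strain_of, strains)
            _write_matrix(os.path.join(outdir, f"matrix_{label}.tsv"), matrix)
            results[label] = matrix
            if matrix.shape[1] == 0:
                dendros[label] = None
                continue
            dend = complete_linkage(euclidean_distances(matrix), strains)
            dendros[label] = dend
            with open(os.path.join(outdir, f"dendrogram_{label}.nwk"), "w") as fh:
                fh.write(dend.newick() + "\n")

        # ------------------------------------------------------------------
        stage = "congruence"
        Dsp, sp_labels = patristic_distances(species_newick)
        mats = {"species": (Dsp, sp_labels)}
        for label, dend in dendros.items():
            if dend is None:
                continue
            mats[label] = cophenetic_distances(dend)
        order = sorted(strains)
        aligned = {}
        for name, (D, labels) in mats.items():
            if set(labels) != set(order):
                continue  # non-overlapping object sets cannot be compared
            perm = [labels.index(s) for s in order]
            aligned[name] = D[np.ix_(perm, perm)]
        cong_rows = []
        names = sorted(aligned)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                res = cadm_test(
                    [aligned[a], aligned[b]],
                    permutations=config.permutations,
                    seed=stage_seed(config.seed, f"cadm:{a}:{b}"),
                )
                cong_rows.append(
                    (f"{a}-{b}", f"{res.W:.4f}", f"{res.p_value:.4f}", res.permutations, res.seed)
                )
        if len(aligned) > 2:
            res = cadm_test(
                [aligned[n] for n in names],
                permutations=config.permutations,
                seed=stage_seed(config.seed, "cadm:global"),
            )
            cong_rows.append(
                ("global", f"{res.W:.4f}", f"{res.p_value:.4f}", res.permutations, res.seed)
            )
        _write_tsv(
            os.path.join(outdir, "congruence.tsv"),
            ["comparison", "W", "p", "permutations", "seed"],
            cong_rows,
        )

        # ------------------------------------------------------------------
        stage = "compare"
        summary = compare_group_paths(ortho_groups, clade_groups)
        summary.to_csv(os.path.join(outdir, "comparison.tsv"), sep="\t", index=False)

        stage = "manifest"
        config_doc = _serialize(config)
        config_doc.pop("outdir", None)  # path metadata, not part of the run identity
        manifest = {
            "package": "phylofam",
            "version": __version__,
            "seed": config.seed,
            "config": config_doc,
            "truth_available": bool(truth),
        }
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    return outdir


def _serialize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialize(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def compare_group_paths(
    ortho_groups: Mapping[str, Sequence],
    clade_groups: Mapping[str, Sequence],
) -> pd.DataFrame:
    """Per-family comparison of the two grouping paths.

    Reports, per family: sequences classified by each path, group counts,
    and the Adjusted Rand Index between the two partitions restricted to
    the commonly classified sequences.
    """
    rows = []
    for fam in sorted(set(ortho_groups) | set(clade_groups)):
        og = list(ortho_groups.get(fam, []))
        cg = list(clade_groups.get(fam, []))
        o_assign = {gid: g.group_id for g in og for gid in g.members}
        c_assign = {gid: g.group_id for g in cg for gid in g.members}
        common = sorted(set(o_assign) & set(c_assign))
        if common:
            ari = adjusted_rand_score(
                [o_assign[g] for g in common], [c_assign[g] for g in common]
            )
        else:
            ari = float("nan")
        rows.append(
            {
                "family": fam,
                "ortho_classified": len(o_assign),
                "phylo_classified": len(c_assign),
                "ortho_groups": len(og),
                "phylo_groups": len(cg),
                "common": len(common),
                "ari_common": round(ari, 4) if common else "",
            }
        )
    return pd.DataFrame(rows)
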