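"""Identification-stage tests: FASTA IO, alignment, e-values, profiles,
retention and curation rules."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from phylofam.simulate import AMINO_ACIDS, ProteinRecord
from phylofam.search import (
    SearchConfig,
    build_profile,
    calibrate_evalue_model,
    calibrate_profile_model,
    dedup_and_filter_fragments,
    estimate_evalue,
    identify_family_members,
    local_align,
    profile_search,
    read_fasta,
)


class TestReadFasta:
    def test_reads_records_and_strain_from_header(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">S01|g1\nMKVLA\n>S01|g2\nMKWWA\n")
        recs = read_fasta(p)
        assert [(r.gene_id, r.strain) for r in recs] == [("g1", "S01"), ("g2", "S01")]

    def test_wrapped_sequence_is_concatenated(self, tmp_path):
        seq = "".join(AMINO_ACIDS[i % 20] for i in range(120))
        p = tmp_path / "S02.fasta"
        p.write_text(">g1\n" + seq[:60] + "\n" + seq[60:] + "\n")
        (rec,) = read_fasta(p)
        assert rec.sequence == seq and len(rec.sequence) == 120
        assert rec.strain == "S02"  # falls back to the filename stem

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)


class TestLocalAlign:
    def test_self_alignment_equals_diagonal_sum(self):
        m = substitution_matrices.load("BLOSUM62")
        seq = "MKVLAGWERTY"
        score, span = local_align(seq, seq)
        assert score == sum(m[c, c] for c in seq)
        assert span == (0, len(seq), 0, len(seq))

    def test_no_positive_pairs_scores_zero(self):
        score, span = local_align("AAAA", "WWWW")
        assert score == 0.0

    def test_rejects_foreign_residues(self):
        with pytest.raises(ValueError):
            local_align("MKV1", "MKV")

    def test_matches_bruteforce_oracle_on_short_pairs(self, dna4_matrix, brute_local_oracle):
        cfg = SearchConfig(substitution_matrix=dna4_matrix, gap_open=2.0, gap_extend=1.0)
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 9))))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(1, 9))))
            score, _ = local_align(a, b, cfg)
            assert score == pytest.approx(brute_local_oracle(a, b, dna4_matrix, 2.0, 1.0))


@pytest.fixture(scope="module")
def model(protein_factory):
    rng = np.random.default_rng(1)
    pool = [protein_factory(rng, 150) for _ in range(25)]
    return calibrate_evalue_model(pool, pool, SearchConfig(shuffle_count=200))


class TestEvalues:
    def test_monotone_decreasing_in_score(self, model):
        assert estimate_evalue(80, 150, 3000, model) < estimate_evalue(60, 150, 3000, model)

    def test_linear_in_database_length(self, model):
        e1 = estimate_evalue(70, 150, 3000, model)
        e2 = estimate_evalue(70, 150, 6000, model)
        assert e2 == pytest.approx(2 * e1)

    def test_refuses_underpowered_calibration(self, protein_factory):
        rng = np.random.default_rng(2)
        pool = [protein_factory(rng, 100) for _ in range(5)]
        with pytest.raises(ValueError):
            calibrate_evalue_model(pool, pool, SearchConfig(shuffle_count=50))

    def test_null_set_evalue_counts_are_calibrated(self, model, protein_factory):
        # on fresh shuffled pairs, P(E <= e) ~ 1 - exp(-e); with E computed
        # per pair the expected count at threshold e is N * (1 - exp(-e))
        cfg = SearchConfig()
        rng = np.random.default_rng(3)
        aligner = cfg.aligner("local")
        n_pairs = 300
        evals = []
        for _ in range(n_pairs):
            a, b = protein_factory(rng, 150), protein_factory(rng, 150)
            s = aligner.score(a, b)
            evals.append(estimate_evalue(float(s), 150, 150, model))
        evals = np.array(evals)
        for e in (0.2, 0.5, 1.0):
            expected = n_pairs * (1 - math.exp(-e))
            got = int((evals <= e).sum())
            sd = math.sqrt(expected)
            assert abs(got - expected) < 4 * sd + 5


class TestProfile:
    def test_pure_column_prefers_its_residue(self):
        p = build_profile(["AC", "AC", "AC"])
        a_idx = AMINO_ACIDS.index("A")
        assert np.argmax(p.scores[0]) == a_idx

    def test_background_column_scores_near_zero(self):
        # a column whose counts are exactly background-proportional is
        # uninformative regardless of pseudocounts
        from phylofam.search import BACKGROUND_FREQS

        n = 100000
        counts = np.round(BACKGROUND_FREQS * n)
        col_chars = []
        for aa, c in zip(AMINO_ACIDS, counts):
            col_chars.extend(aa * int(c))
        msa = ["".join([c]) for c in col_chars]
        p = build_profile(msa)
        assert np.max(np.abs(p.scores)) < 0.01

    def test_gap_heavy_columns_are_dropped(self):
        p = build_profile(["A-C", "A-C", "ACC", "A--"])
        assert p.columns == [0, 2]

    def test_single_sequence_profile_warns(self):
        with pytest.warns(UserWarning):
            build_profile(["ACDEF"])

    def test_own_sequence_outscores_random(self, protein_factory):
        rng = np.random.default_rng(4)
        seed = protein_factory(rng, 80)
        p = build_profile([seed] * 5)
        cfg = SearchConfig()
        own, _ = profile_search(p, seed, cfg, model=None)
        for _ in range(20):
            other, _ = profile_search(p, protein_factory(rng, 80), cfg, model=None)
            assert own > other

    def test_seed_sequence_passes_cutoff_and_appending_consensus_is_monotone(
        self, protein_factory
    ):
        rng = np.random.default_rng(5)
        seed = protein_factory(rng, 120)
        p = build_profile([seed] * 4)
        cfg = SearchConfig()
        model = calibrate_profile_model(p, [seed], cfg)
        score, ev = profile_search(p, seed, cfg, model=model)
        assert ev < cfg.evalue_cutoff
        longer, _ = profile_search(p, seed + seed[:10], cfg, model=model)
        assert longer >= score


@pytest.fixture(scope="module")
def toy(protein_factory):
    rng = np.random.default_rng(6)
    base = protein_factory(rng, 150)

    def mutate(s, k):
        s = list(s)
        for i in rng.choice(len(s), k, replace=False):
            s[i] = protein_factory(rng, 1)
        return "".join(s)

    family = [ProteinRecord(f"fam{i}", f"S{i:02d}", mutate(base, 15)) for i in range(3)]
    decoys = [
        ProteinRecord(f"rnd{i}", f"S{i:02d}", protein_factory(rng, 150)) for i in range(3)
    ]
    queries = [ProteinRecord("q1", "ref", base), ProteinRecord("q2", "ref", mutate(base, 10))]
    return family, decoys, queries


class TestIdentification:
    def test_family_members_retained_and_decoys_excluded(self, toy):
        family, decoys, queries = toy
        db = family + decoys + [queries[0]]
        hits = identify_family_members(db, queries, [q.sequence for q in queries])
        by_id = {h.gene_id: h for h in hits}
        assert by_id["q1"].passed  # verbatim query present in db
        for r in family:
            assert by_id[r.gene_id].passed
        for r in decoys:
            assert not by_id[r.gene_id].passed

    def test_intersection_is_subset_of_union(self, toy):
        family, decoys, queries = toy
        db = family + decoys
        seed_msa = [q.sequence for q in queries]
        inter = identify_family_members(db, queries, seed_msa, SearchConfig())
        union = identify_family_members(
            db, queries, seed_msa, SearchConfig(retention="union")
        )
        kept_i = {h.gene_id for h in inter if h.passed}
        kept_u = {h.gene_id for h in union if h.passed}
        assert kept_i <= kept_u

    def test_retention_monotone_in_cutoff(self, toy):
        family, decoys, queries = toy
        db = family + decoys
        seed_msa = [q.sequence for q in queries]
        strict = identify_family_members(db, queries, seed_msa, SearchConfig(evalue_cutoff=1e-10))
        loose = identify_family_members(db, queries, seed_msa, SearchConfig(evalue_cutoff=1e-3))
        assert {h.gene_id for h in strict if h.passed} <= {
            h.gene_id for h in loose if h.passed
        }


class TestCuration:
    def _hit(self, gid, family="fam", passed=True):
        from phylofam.search import FamilyHit

        return FamilyHit(gid, family, 100, 1e-30, 50, 1e-20, passed)

    def test_exact_duplicates_collapse_within_strain(self):
        db = [
            ProteinRecord("g1", "S01", "MKVLAGWERTMKVLAGWERT"),
            ProteinRecord("g2", "S01", "MKVLAGWERTMKVLAGWERT"),
            ProteinRecord("g3", "S02", "MKVLAGWERTMKVLAGWERT"),
        ]
        out = dedup_and_filter_fragments([self._hit(g) for g in ("g1", "g2", "g3")], db)
        assert [r.gene_id for r in out] == ["g1", "g3"]

    def test_fragments_below_half_median_removed(self):
        long = "MKVLAGWERT" * 10  # 100 residues
        frag = "MKVLAGWERT" * 4  # 40 residues < 0.5 * 100
        db = [
            ProteinRecord("a", "S01", long),
            ProteinRecord("b", "S02", long),
            ProteinRecord("c", "S03", long[:90]),
            ProteinRecord("d", "S04", frag),
        ]
        out = dedup_and_filter_fragments([self._hit(g) for g in "abcd"], db)
        assert [r.gene_id for r in out] == ["a", "b", "c"]

    def test_unique_full_length_set_unchanged(self):
        rng = np.random.default_rng(7)
        db = [
            ProteinRecord(f"g{i}", f"S{i:02d}", "".join(rng.choice(list(AMINO_ACIDS), 100)))
            for i in range(5)
        ]
        out = dedup_and_filter_fragments([self._hit(r.gene_id) for r in db], db)
        assert [r.gene_id for r in out] == [r.gene_id for r in db]
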