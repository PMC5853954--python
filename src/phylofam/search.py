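"""Family-member identification by a dual similarity criterion.

Each candidate protein is scored two ways against a curated gene family:

* best exact Smith--Waterman local alignment against the family's query
  sequences (affine gaps, BLOSUM62 by default), and
* best local match against a position-specific score profile built from an
  aligned seed set of the family.

Both scores are converted to e-values of Karlin--Altschul form
``E = K * m * n * exp(-lambda * S)`` with ``(K, lambda)`` calibrated once
per scoring scheme by a maximum-likelihood Gumbel fit to scores of
shuffled-sequence pairs.  A protein is retained when both e-values pass the
cut-off (intersection mode, the default) or when either does (union mode).
Retained sets are then curated automatically: exact duplicates within a
strain are collapsed and fragments shorter than half the family's median
length are dropped.
"""

from __future__ import annotations

import math
import os
import statistics
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.stats import gumbel_r

from ._dp import local_best_score
from .simulate import AMINO_ACIDS, ProteinRecord

# Robinson & Robinson amino-acid background frequencies, order ACDEFGHIKLMNPQRSTVWY
BACKGROUND_FREQS = np.array(
    [
        0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
        0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
        0.05841, 0.06441, 0.01330, 0.03216,
    ]
)
BACKGROUND_FREQS /= BACKGROUND_FREQS.sum()

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

__all__ = [
    "SearchConfig",
    "FamilyHit",
    "EvalueModel",
    "Profile",
    "read_fasta",
    "local_align",
    "calibrate_evalue_model",
    "estimate_evalue",
    "build_profile",
    "profile_search",
    "identify_family_members",
    "dedup_and_filter_fragments",
]


@dataclass
class SearchConfig:
    """Decision rule and scoring scheme for the identification stage."""

    evalue_cutoff: float = 1e-5
    retention: str = "intersection"  # or "union"
    fragment_fraction: float = 0.5
    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    shuffle_count: int = 200
    shuffle_seed: int = 0
    substitution_matrix: object | None = None  # overrides matrix_name if set

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be > 0")
        if not 0 < self.fragment_fraction <= 1:
            raise ValueError("fragment_fraction must be in (0, 1]")
        if self.retention not in ("intersection", "union"):
            raise ValueError("retention must be 'intersection' or 'union'")

    def matrix(self):
        if self.substitution_matrix is not None:
            return self.substitution_matrix
        return substitution_matrices.load(self.matrix_name)

    def aligner(self, mode: str = "local") -> PairwiseAligner:
        al = PairwiseAligner()
        al.mode = mode
        al.substitution_matrix = self.matrix()
        al.open_gap_score = -float(self.gap_open)
        al.extend_gap_score = -float(self.gap_extend)
        return al


@dataclass
class FamilyHit:
    """Scores of one database protein against one family's queries/profile."""

    gene_id: str
    family: str
    aln_bits: float
    aln_evalue: float
    prof_bits: float
    prof_evalue: float
    passed: bool


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, strain: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into records.

    Strain assignment convention: headers of the form ``strain|gene_id`` set
    both fields; otherwise the whole header is the gene id and the strain
    defaults to the file's basename stem (or the explicit ``strain``
    argument).  Raises on empty files.
    """
    path = os.fspath(path)
    default_strain = strain if strain is not None else os.path.splitext(os.path.basename(path))[0]
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(path, "fasta")):
        header = rec.id
        if not header:
            raise ValueError(f"{path}: malformed header at record {i + 1}")
        if "|" in header:
            st, gid = header.split("|", 1)
        else:
            st, gid = default_strain, header
        records.append(ProteinRecord(gene_id=gid, strain=st, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _validate_seq(seq: str, alphabet: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"residues outside alphabet: {sorted(bad)}")


# ---------------------------------------------------------------------------
# local alignment and e-values
# ---------------------------------------------------------------------------

def local_align(a: str, b: str, cfg: SearchConfig | None = None):
    """Optimal Smith--Waterman local alignment of two protein sequences.

    Returns ``(score, span)`` with span = (a_start, a_end, b_start, b_end)
    of the best local alignment (half-open coordinates).
    """
    cfg = cfg or SearchConfig()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    matrix = cfg.matrix()
    alphabet = str(matrix.alphabet)
    _validate_seq(a, alphabet)
    _validate_seq(b, alphabet)
    aligner = cfg.aligner("local")
    score = aligner.score(a, b)
    if score <= 0:
        return 0.0, (0, 0, 0, 0)
    aln = aligner.align(a, b)[0]
    blocks = aln.aligned
    span = (
        int(blocks[0][0][0]),
        int(blocks[0][-1][1]),
        int(blocks[1][0][0]),
        int(blocks[1][-1][1]),
    )
    return float(score), span


def local_score(a: str, b: str, aligner: PairwiseAligner) -> float:
    """Score-only Smith--Waterman (fast path for all-vs-all loops)."""
    s = aligner.score(a, b)
    return float(s) if s > 0 else 0.0


@dataclass
class EvalueModel:
    """Karlin--Altschul parameters calibrated for one scoring scheme."""

    lam: float
    K: float

    def evalue(self, score: float, query_len: int, db_len: int) -> float:
        return self.K * query_len * db_len * math.exp(-self.lam * score)

    def bits(self, score: float) -> float:
        return (self.lam * score - math.log(self.K)) / math.log(2.0)


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return arr.tobytes().decode()


def calibrate_evalue_model(
    pool_a: Sequence[str],
    pool_b: Sequence[str],
    cfg: SearchConfig,
    score_fn=None,
) -> EvalueModel:
    """Fit (K, lambda) by a Gumbel ML fit to shuffled-pair alignment scores.

    ``cfg.shuffle_count`` random (shuffled a, shuffled b) pairs are scored
    with ``score_fn`` (default: Smith--Waterman under ``cfg``); the Gumbel
    location/scale (mu, beta) fitted by ``scipy.stats.gumbel_r.fit`` give
    lambda = 1/beta and K = exp(mu/beta) / mean(m*n).
    """
    if cfg.shuffle_count < 100:
        raise ValueError("e-value calibration needs at least 100 shuffles")
    rng = np.random.default_rng(cfg.shuffle_seed)
    if score_fn is None:
        aligner = cfg.aligner("local")
        score_fn = lambda x, y: local_score(x, y, aligner)  # noqa: E731
    scores = np.empty(cfg.shuffle_count)
    mn = np.empty(cfg.shuffle_count)
    for i in range(cfg.shuffle_count):
        a = pool_a[int(rng.integers(len(pool_a)))]
        b = pool_b[int(rng.integers(len(pool_b)))]
        scores[i] = score_fn(_shuffled(a, rng), _shuffled(b, rng))
        mn[i] = len(a) * len(b)
    mu, beta = gumbel_r.fit(scores)
    lam = 1.0 / beta
    K = math.exp(mu / beta) / float(mn.mean())
    return EvalueModel(lam=lam, K=K)


def estimate_evalue(score: float, query_len: int, db_len: int, model: EvalueModel) -> float:
    """Karlin--Altschul e-value of an alignment score (monotone decreasing)."""
    if score < 0:
        raise ValueError("score must be >= 0")
    return model.evalue(score, query_len, db_len)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Position-specific log-odds scores over match columns of a seed MSA."""

    scores: np.ndarray  # (ncols, 20) log2 odds
    columns: list[int]  # original MSA column indices kept as match states

    @property
    def ncols(self) -> int:
        return self.scores.shape[0]


def build_profile(seed_msa: Sequence[str], pseudocount: float = 1.0) -> Profile:
    """Per-column log-odds profile with background-weighted pseudocounts.

    Columns with more than 50% gaps are excluded from match states.  Scores
    are log2((n_a + tau*q_a) / (N + tau) / q_a).  A single-sequence MSA is
    accepted with a warning (profile equals that sequence's log-odds).
    """
    if not seed_msa:
        raise ValueError("empty seed MSA")
    lengths = {len(s) for s in seed_msa}
    if len(lengths) != 1:
        raise ValueError("seed MSA sequences must have equal length")
    if len(seed_msa) == 1:
        warnings.warn("single-sequence seed MSA; profile equals its log-odds")
    ncols_in = lengths.pop()
    nseq = len(seed_msa)
    cols: list[int] = []
    rows: list[np.ndarray] = []
    for j in range(ncols_in):
        col = [s[j] for s in seed_msa]
        gaps = sum(1 for c in col if c == "-")
        if gaps / nseq > 0.5:
            continue
        counts = np.zeros(20)
        for c in col:
            idx = _AA_INDEX.get(c)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        freq = (counts + pseudocount * BACKGROUND_FREQS) / (total + pseudocount)
        rows.append(np.log2(freq / BACKGROUND_FREQS))
        cols.append(j)
    if not rows:
        raise ValueError("no match columns (all gap-heavy)")
    return Profile(scores=np.vstack(rows), columns=cols)


def _encode(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def profile_match_score(profile: Profile, protein: str, cfg: SearchConfig) -> float:
    """Best local match of ``protein`` against the profile (affine gaps)."""
    enc = _encode(protein)
    S = np.where(enc[:, None] >= 0, profile.scores[:, :].T[enc.clip(min=0), :], 0.0)
    # rows: protein positions; columns: profile match states
    S = np.ascontiguousarray(S, dtype=np.float64)
    # profile scores are in bits; scale gap penalties into the same ballpark
    go, ge = float(cfg.gap_open), float(cfg.gap_extend)
    return float(local_best_score(S, go, ge))


def profile_search(
    profile: Profile,
    protein: str,
    cfg: SearchConfig,
    model: EvalueModel | None = None,
):
    """Score a protein against a profile; returns (score, e-value).

    If no calibrated model is supplied, one is fitted on the fly from
    shuffles of the protein itself (same Gumbel calibration as sequence
    search).
    """
    score = profile_match_score(profile, protein, cfg)
    if model is None:
        model = calibrate_profile_model(profile, [protein], cfg)
    ev = model.evalue(score, len(protein), profile.ncols)
    return score, ev


def calibrate_profile_model(
    profile: Profile, pool: Sequence[str], cfg: SearchConfig
) -> EvalueModel:
    """Gumbel calibration of profile-match scores on shuffled sequences."""
    if cfg.shuffle_count < 100:
        raise ValueError("e-value calibration needs at least 100 shuffles")
    rng = np.random.default_rng(cfg.shuffle_seed + 1)
    scores = np.empty(cfg.shuffle_count)
    mn = np.empty(cfg.shuffle_count)
    for i in range(cfg.shuffle_count):
        s = pool[int(rng.integers(len(pool)))]
        scores[i] = profile_match_score(profile, _shuffled(s, rng), cfg)
        mn[i] = len(s) * profile.ncols
    mu, beta = gumbel_r.fit(scores)
    return EvalueModel(lam=1.0 / beta, K=math.exp(mu / beta) / float(mn.mean()))


# ---------------------------------------------------------------------------
# identification and curation
# ---------------------------------------------------------------------------

def identify_family_members(
    db: Sequence[ProteinRecord],
    queries: Sequence[ProteinRecord],
    seed_msa: Sequence[str],
    cfg: SearchConfig | None = None,
    family: str = "family",
    aln_model: EvalueModel | None = None,
    prof_model: EvalueModel | None = None,
) -> list[FamilyHit]:
    """Dual-criterion family search over a protein database.

    Each database protein receives its best query Smith--Waterman score and
    its best profile score; e-values use BLAST-style database semantics
    (n = total residues in the database).  ``passed`` applies the configured
    retention rule (both e-values <= cut-off by default).
    """
    if not db or not queries:
        raise ValueError("db and queries must be non-empty")
    cfg = cfg or SearchConfig()
    profile = build_profile(seed_msa)
    db_seqs = [r.sequence for r in db]
    query_seqs = [q.sequence for q in queries]
    if aln_model is None:
        aln_model = calibrate_evalue_model(query_seqs, db_seqs, cfg)
    if prof_model is None:
        prof_model = calibrate_profile_model(profile, db_seqs, cfg)
    db_len = sum(len(s) for s in db_seqs)
    aligner = cfg.aligner("local")
    hits: list[FamilyHit] = []
    for rec in db:
        best_s, best_q = 0.0, queries[0]
        for q in queries:
            s = local_score(q.sequence, rec.sequence, aligner)
            if s > best_s:
                best_s, best_q = s, q
        aln_ev = aln_model.evalue(best_s, len(best_q.sequence), db_len)
        prof_s = profile_match_score(profile, rec.sequence, cfg)
        prof_ev = prof_model.evalue(prof_s, len(rec.sequence), profile.ncols * len(db))
        a_ok = aln_ev <= cfg.evalue_cutoff
        p_ok = prof_ev <= cfg.evalue_cutoff
        passed = (a_ok and p_ok) if cfg.retention == "intersection" else (a_ok or p_ok)
        hits.append(
            FamilyHit(
                gene_id=rec.gene_id,
                family=family,
                aln_bits=aln_model.bits(best_s),
                aln_evalue=aln_ev,
                prof_bits=prof_model.bits(prof_s),
                prof_evalue=prof_ev,
                passed=passed,
            )
        )
    return hits


def dedup_and_filter_fragments(
    hits: Sequence[FamilyHit],
    db: Sequence[ProteinRecord],
    cfg: SearchConfig | None = None,
) -> list[ProteinRecord]:
    """Automated curation of retained hits.

    Within each (strain, family), exact-duplicate sequences collapse to the
    lexicographically smallest gene id; sequences shorter than
    ``fragment_fraction`` x (family median length, over the deduplicated
    retained set) are removed.  Order-independent by construction.
    """
    cfg = cfg or SearchConfig()
    by_id = {r.gene_id: r for r in db}
    passed = sorted((h for h in hits if h.passed), key=lambda h: h.gene_id)
    # collapse exact duplicates within strain+family
    seen: dict[tuple[str, str, str], str] = {}
    kept: dict[str, tuple[ProteinRecord, str]] = {}
    for h in passed:
        rec = by_id[h.gene_id]
        key = (rec.strain, h.family, rec.sequence)
        if key in seen:
            continue
        seen[key] = h.gene_id
        kept[h.gene_id] = (rec, h.family)
    # fragment filter against family median length
    by_family: dict[str, list[int]] = {}
    for rec, fam in kept.values():
        by_family.setdefault(fam, []).append(len(rec.sequence))
    medians = {fam: statistics.median(ls) for fam, ls in by_family.items()}
    out = [
        rec
        for gid, (rec, fam) in sorted(kept.items())
        if len(rec.sequence) >= cfg.fragment_fraction * medians[fam]
    ]
    return out
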