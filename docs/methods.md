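# Methods

This note documents the models and procedures implemented in `phylofam`, the
defaults and the reasoning behind them, the numerical conventions that affect
reproducibility, and the known limitations.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data generator (`phylofam.simulate`)

**Species tree.** A Yule (pure-birth) process with birth rate 1.0 per unit
time, run until `n_species` lineages exist and then extended by one further
exponential waiting time so that no terminal branch has zero length.  The
tree is exactly ultrametric by construction.  Default `n_species = 12`,
matching a moderately sized multi-strain comparison (real surveys of this
kind span roughly 10–31 strains).

**Gene families.** Each family starts as a single gene at the species root
and evolves along every species branch under a Poisson process with
duplication rate λ_d (default 0.3/unit time), loss rate μ_l (0.1) and
transfer rate λ_t (0, i.e. off by default).  A duplication splits the
lineage in place; a loss prunes it; a transfer moves it onto a uniformly
chosen contemporaneous species branch.  Surviving lineages split at every
speciation.  Extinct lineages are pruned and degree-2 nodes suppressed, so
the returned gene tree covers exactly the surviving genes.  The default
rates produce the mixture seen in real families of this kind: one or two
broadly conserved groups plus lineage-specific radiations.

**True ortholog groups.** Groups are defined by duplication age:
duplications older than `resolution_depth` × (tree height), default 0.5,
found new groups; younger duplications leave both copies in the parent
group.  This mirrors the biological reading of similarity-based groups as
"orthologs plus recent paralogs": deep duplicates behave as distinct
subfamilies, shallow ones as in-paralogs.  The cutoff is a config knob.

**Sequences.** An i.i.d. uniform root sequence of 300 residues (in the range
of real family means, which run roughly 240–570 aa) evolves down the gene
tree under a 20-state equal-rates model: along a branch of duration t each
site substitutes to a uniformly chosen different residue with probability
p(t) = (19/20)(1 − e^(−20rt/19)).  The closed form makes the generator
checkable (the suite verifies observed divergence against p(t) and gene
counts against the birth-process mean e^(λ_d T)).  No indels are generated,
so alignment difficulty is not part of what the benchmark measures.  When no
substitution rate is given, the rate is calibrated so two average strains
differ at `target_divergence` (default 0.2) of sites — the inverse of p(t)
at the mean leaf-pair patristic time.

**What the generator does not emulate:** indels and alignment uncertainty,
rate heterogeneity across sites and lineages, codon structure, fragmentary
transcripts, contamination, and database redundancy.  Passing tests
demonstrate the machinery is correct under the model's assumptions; they do
not bound performance on real transcriptome data.

## Family search (`phylofam.search`)

Candidate proteins are scored two ways: best exact Smith–Waterman local
alignment against the family queries (Biopython's `PairwiseAligner`,
BLOSUM62, gap open 11 / extend 1 — standard protein-search defaults), and
best local match against a per-column log-odds profile built from an aligned
seed set (columns with >50% gaps excluded; counts smoothed with
background-proportional pseudocounts against Robinson–Robinson frequencies).

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS).  (K, λ) are fitted
once per scoring scheme by maximum likelihood (`scipy.stats.gumbel_r.fit`)
on the scores of shuffled-sequence pairs — 200 shuffles by default, fixed
seed; calibration refuses to run with fewer than 100.  The search stage uses
BLAST-style database semantics (n = total residues in the database).  The
gap-cost convention everywhere in the package is: a gap of length L costs
`gap_open + (L−1)·gap_extend`.

Retention follows the dual criterion: by default a protein must pass the
e-value cut-off (1e−5) in **both** searches ("intersection"); a "union" mode
is provided because either reading of the criterion is defensible, and the
choice is recorded in the run manifest.  Curation is automated with explicit
rules: exact duplicate sequences within a strain and family collapse to the
lexicographically smallest gene id, and sequences shorter than 0.5 × the
family's median length (over the deduplicated retained set) are removed.
These rules are declared substitutes for manual curation, chosen for
order-independence and reproducibility.

## Similarity grouping (`phylofam.ortho`)

Edge weights are `min(−log10 E, 200)` for pairs with E ≤ 1 (the cap bounds
weights when E underflows; 200 is the conventional choice).  Edge classes:

* **ortholog** — reciprocal best cross-strain pairs: w(a,b) is within a tie
  margin (1e−9) of a's best hit into b's strain and b's best into a's.
* **in-paralog** — within-strain pairs scoring at least as high as the best
  cross-strain weight of *both* members (genes with no cross-strain hits
  qualify unconditionally), i.e. pairs more similar to each other than
  either is to any gene in another strain.

In-paralog weights are divided by the mean ortholog-edge weight of their
connected component; components without ortholog edges fall back to the
global mean with a logged warning.  All other candidate edges are dropped.

MCL is implemented from scratch on a dense column-stochastic matrix:
self-loops set to each node's maximum incident weight, expansion = matrix
square, inflation = elementwise power + renormalization (default 1.5),
pruning below 1e−5, iteration until the matrix change falls below 1e−6.
Clusters are read from attractor rows; overlapping attractor systems merge,
and a node reachable from several systems joins the one giving it the
largest weight (ties resolved toward the lexicographically first system).
Higher inflation yields finer clusters; the barbell-graph test pins this
monotonicity, which is the practical reason to raise inflation (e.g. to 4)
for families that otherwise form only a handful of coarse groups.

## Phylogenetic grouping (`phylofam.genetrees`)

*Alignment.* Pairwise global-alignment identity distances feed a
neighbor-joining guide tree (scikit-bio's NJ); profiles are merged in its
postorder by global affine-gap DP on average substitution scores, so a gap
introduced at one merge persists ("once a gap, always a gap").  Trimming
keeps columns with ≤50% gaps whose majority residue reaches 50% of non-gap
entries — a deliberately simple conserved-block filter.

*Parsimony.* Fitch two-pass scoring with gaps (and X) as missing data,
vectorized over columns with residue bitmasks (a numba kernel).  Tree search
is random-addition stepwise insertion followed by hill climbing that
alternates nearest-neighbor-interchange sweeps with subtree-prune-and-regraft
(SPR) first-improvement moves; NNI alone proved insufficient — it strands
the search in local optima on a few percent of small random alignments where
the exhaustive optimum is known.  Default 5 random-addition restarts; the
oracle-equivalence tests run 20 restarts, at which the search matched the
exhaustive minimum on every random 6–7-taxon instance tried.  Determinism:
the same seed always returns the same tree; ties between equally
parsimonious trees break on a canonical form.

*Bootstrap.* Column resampling is implemented as Fitch column weights
(multinomial counts), 100 replicates by default.  Replicate searches use 2
restarts and NNI only (supports aggregate over replicates and do not need
per-replicate exactness); the full-data tree gets the full search.  The
support of each bipartition of the full-data tree is the percentage of
replicate trees containing it.  The supported tree is rooted at the
topological midpoint — parsimony trees carry no branch lengths, so midpoint
rooting uses unit lengths, and the root is always placed *on an edge* (the
central edge of the diameter path) so both sides of the deepest split remain
clades.  Supports are re-attached to the rooted tree by bipartition lookup.

*Group extraction.* A group is the leaf set of a maximal clade whose
subtending node support exceeds the threshold (default 50) while its
parent's does not (or the parent is the root); nested qualifying clades
resolve to the maximal one, so groups are disjoint.  `strict=True`
additionally requires every internal node inside the clade to exceed the
threshold — the "grow from the leaves" reading.  Both readings are
defensible; the default is the permissive one, the flag is recorded in the
manifest.  Groups under 4 members are discarded and remaining leaves
reported as unclassified.  Which reading classifies more sequences depends
on the data: under the permissive rule a single barely-supported deep clade
can classify almost everything, under the strict rule weakly structured
families classify very little.

## Gene-content clustering (`phylofam.content`)

Counts are raw integers (no per-strain normalization — none is obviously
right for mixed genome/transcriptome inputs; a row-scaling option exists but
is off by default).  Columns are namespaced `family:group` and ordered by
(family, group id); strains with no grouped genes keep zero rows.
Complete-linkage agglomeration is written out explicitly because standard
implementations differ in tie handling: at each step the pair of clusters
with the smallest maximum pairwise distance merges, ties broken by the
lexicographically smallest cluster pair, so results are deterministic.  The
suite checks merge heights against `scipy.cluster.hierarchy` on random
inputs (agreement is exact off ties).

## Congruence (`phylofam.congruence`)

Cophenetic distance is the merge height of the smallest cluster containing
both leaves (not twice the height — conventions differ, so this is pinned).
Patristic distance is the leaf-pair path length; missing branch lengths fall
back to 1 with a warning.  Kendall's W is computed on the rank-transformed
unfolded lower triangles with the standard tie correction, clamped to [0,1]
against floating error.  W is reported raw: 1 means identical rankings and
1/p is the expectation for unrelated matrices.  The CADM permutation null
holds the first matrix fixed and permutes object labels (rows and columns
jointly) of every other matrix independently per replicate;
p = (exceedances + 1)/(permutations + 1), so 999 permutations bound p below
at 0.001.  Fewer than 19 permutations are refused (p resolution too coarse).
The test is exercised for calibration in the suite: p-values are uniform
under independent random matrices (KS test over 200 runs).

## Pipeline and reproducibility (`phylofam.pipeline`, `phylofam.cli`)

One global seed fans out to per-stage seeds by hashing stage names (CRC32
mixed with the seed), so a stage re-run in isolation reproduces its
in-pipeline result.  Outputs carry no timestamps; two runs with the same
configuration are byte-identical (the manifest records the configuration
minus the output path).  Stage failures abort with the stage name.  In
fixture mode the family query sets are the true members from the first 4
strains — emulating query sets curated from a few reference genomes — and
each family's profile comes from the progressive alignment of its queries.

Problem sizes used by the suite and the acceptance script — 12 strains, 4
families, ~300-residue proteins, 100 bootstrap replicates, 999 permutations,
5 benchmark replicates — were chosen as the smallest sizes at which every
stage's behavior is measurable and stable.

## Known limitations

* **Similarity grouping recovers duplication-age truth only partially in
  duplication-dense regimes.**  The benchmark's truth is defined by a sharp
  duplication-age cutoff, but sequence divergence is continuous: copies from
  duplications near the cutoff are intrinsically ambiguous, and a
  reciprocal-best-hit graph cannot bridge subfamilies born at mid-depth
  duplications in strains that retain both copies.  The acceptance benchmark
  reports the achieved Adjusted Rand Index (run `scripts/acceptance.py` for
  current numbers); under sparse duplication and low divergence the same
  machinery recovers truth nearly perfectly (this regime is pinned in the
  unit suite).  This mirrors the behavior of similarity-based orthology on
  real data, where groups are "orthologs plus recent paralogs", not clades
  at a fixed age.
* E-value calibration assumes Gumbel-distributed local-alignment null
  scores; the approximation is good for the score ranges used here, but
  calibrated e-values are internally consistent rather than comparable with
  BLAST's.
* The profile search has match states only (no insert/delete states or
  Forward-algorithm statistics); it is a log-odds PSSM scan, adequate for
  the retention decision it supports.
* Parsimony bootstrap supports are mapped onto the single best full-data
  tree, not a consensus; trees with many equally parsimonious optima will
  show unstable supports.
* CADM compares whole matrices; it does not localize which strains drive
  congruence or conflict.
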