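# Methods

## Scope and data model

All statistics operate on *dereplicated unique sequences*: identical reads
(after gap removal, uppercasing, and U→T rewriting) collapse into one unit
carrying its read abundance and member ids.  Clustering and pair counting
are unweighted by abundance — a unique sequence is one object regardless
of its read count; abundances enter only through greedy-clustering scan
order, the AGC centroid choice, read-level subsampling, and rarefaction.
Representative ids are first-occurrence ids, and units sort by decreasing
abundance with lexicographic id tie-breaks, so the abundance-ordered
greedy scan is reproducible without a seed.

## Distances

Pairwise distances are fractions of differing alignment columns in [0, 1].
Two routes produce them:

- **Pairwise global alignment.** Needleman–Wunsch with affine gap scoring
  (Gotoh three-state recursion): match +1, mismatch −1, gap open −2, gap
  extend −1, terminal gaps penalized.  A gap of length *k* costs
  `gap_open + (k−1)·gap_extend`.  Traceback ties are broken
  deterministically — diagonal, then up, then left — so alignments are
  stable across runs and platforms.
- **Shared multiple alignment.** Column-wise comparison of uniformly
  aligned sequences.  Gap-free uniform-length inputs use a vectorized
  Hamming path that is exactly the column calculator.

The distance calculator follows the mothur conventions: columns where both
sequences are gapped are skipped; with `gap_mode="one_gap_per_run"` (the
default) a maximal run of gap columns counts as one difference and one
unit of compared length; `count_end_gaps` (default true) controls whether
terminal gap columns are compared at all.  Both are configurable because
published pipelines differ here.

Matrices are sparse: pairs above `storage_cutoff` (default 0.10, well
above the 0.03 working threshold plus merge headroom) are dropped and
treated downstream as "definitely different" — they can never support a
merge, count on the within-threshold side, or make a query assignable.

## De novo clustering

**Hierarchical (SL/AL/CL).** Agglomerative merging while the minimum
linkage is at or below the threshold (inclusive comparisons, matching the
0.03 ≡ 97%-similarity convention).  Linkage is the minimum (SL), mean
(AL), or maximum (CL) inter-cluster pair distance.  The implementation
initializes a dense linkage matrix from the sparse distances and applies
Lance–Williams-style updates (min / max / pair-count-weighted mean), which
reproduces the naive recomputation exactly.  Missing sparse pairs are
unmergeable for CL; for AL they contribute the storage cutoff to the mean
by default (conservative: biases against merging) or veto the merge under
`al_missing="unmergeable"` — both behaviors exist because real pipelines
are ambiguous on this point.  Exact linkage ties are broken by a seeded
RNG; on tie-free matrices the seed is irrelevant.

**Greedy (AGC/DGC).** Sequences are scanned in decreasing-abundance order
(or a given order, for input-order experiments).  Candidates are existing
centroids within the threshold; DGC joins the closest (ties: larger
abundance, then id), AGC the most abundant (ties: smaller distance, then
id); with no candidate the sequence seeds a new centroid.  Centroid
sequences are fixed at creation.

## Reference-based assignment

Closed-reference assignment is the exhaustive oracle: the distance from
each query to *every* reference is computed, and the query is assigned to
the minimum-distance reference if that distance is within the threshold.
Search heuristics (k-mer candidate selection à la USEARCH/VSEARCH) are
deliberately not implemented: the interesting phenomena — order-dependent
labels, heuristic misses — are measured against this oracle, and emulating
a specific heuristic would be unverifiable.  Exact ties are resolved by
`first_in_db_order` (default, which is what makes OTU *labels* sensitive
to reference order while the induced query *partition* is not) or
`lexicographic_id`.  Open-reference assignment runs DGC on the unassigned
remainder and prefixes OTU labels `ref:`/`denovo:`.

The audit dereplicates references over the compared region, counts record
pairs more than 97% similar (distance strictly below 0.03; identical pairs
qualify), groups identical region sequences, and flags groups carrying
more than one distinct taxonomy string (whole-string comparison after
whitespace normalization — no rank-aware logic).  Region extraction uses
0-based half-open alignment columns and requires non-gap characters before,
inside, and after the region; the CLI converts from 1-based inclusive
coordinates.  Label sharing between two reference permutations is
`|L_i ∩ L_j| / mean(|L_i|, |L_j|)` over the sets of assigned reference
labels; for the exhaustive matcher the set sizes coincide across
permutations, so the normalization choice only scales the statistic.

## Evaluation statistics

Confusion counts are over unordered pairs of unique sequences and always
total C(m, 2).  The **quality** construction compares OTU co-membership
with the distance relation at the threshold (pairs at exactly the
threshold count on the co-cluster side by default; `inclusive=False`
flips the boundary).  The **stability** construction compares co-membership
in a subsample's clustering against the full dataset's, restricted to the
subsample universe — the only self-consistent choice when the two
clusterings cover different sequence sets.  MCC, sensitivity, and
specificity substitute 0 when their denominators vanish, keeping
experiment tables total.

The threshold scan evaluates quality MCC on the grid 0–5% in 1% steps and
returns the argmax, ties going to the smallest threshold.

Rarefaction is the exact hypergeometric expectation
E[S] = Σᵢ (1 − C(N−Nᵢ, n)/C(N, n)) over OTU read counts Nᵢ, with a seeded
multivariate-hypergeometric Monte-Carlo mode as a cross-check.

The experiment drivers subsample *reads* (multivariate hypergeometric over
unit abundances, equivalent to read-level sampling without replacement)
and re-dereplicate; subsample units keep the full dataset's representative
ids so the two partitions share an id space.  The stability driver
clusters the full dataset once per input-order permutation and compares
every subsample clustering against every full clustering — 30 × 30 = 900
MCC values per fraction at the defaults (fractions 0.2/0.4/0.6/0.8).  The
quality driver scores each subsample against its own distance matrix and
summarizes with the mean and empirical 2.5/97.5 percentiles (no normality
assumption).  All replicate randomness derives from one seed via a seed
sequence.

## Synthetic data

The community generator emulates a dereplicated amplicon dataset with
planted structure.  Cluster templates are rejection-sampled mutations of a
random ancestor, kept at least `inter_divergence` apart (plus a margin of
twice the satellite radius, so satellite drift never erodes the bound).
Satellites mutate `k = ⌊intra·L/2⌋` positions, disjoint across the
satellites of a cluster, making every planted distance an exact Hamming
fraction: template–satellite `k/L`, satellite–satellite `2k/L ≤ intra`.
Reads follow a cluster-level abundance model (uniform, lognormal(μ=0,σ=1),
or power-law rank-abundance), with one read guaranteed per variant and
i.i.d. per-base substitution errors (default 0.02%, the error rate
reported for well-curated MiSeq amplicon data).  Substitution-only errors
keep planted distances analytic; there is no indel, chimera, or
platform-specific error model, so tests passing on these communities show
algorithmic correctness, not robustness to real error profiles — real
data adds alignment ambiguity, chimeras, and abundance-correlated error
that these fixtures deliberately omit.

Default community: 10 clusters × 3 variants, 250-nt sequences (V4-like),
2,000 reads, lognormal abundances.  These sizes keep every experiment —
including the 900-comparison stability design — in seconds at desk scale
while exercising all code paths; they are three orders of magnitude below
survey-scale datasets, so absolute OTU counts and runtimes do not
extrapolate.

The reference generator emits flank+region+flank sequences (no gap
characters, so the identity alignment applies), mutually <97% similar over
the full length, with planted duplicate groups identical over the region
and carrying a specified number of distinct taxonomy strings — the exact
structure that makes closed-reference OTU labels order-sensitive.

## Numerical and design choices

- Boundary conventions are inclusive throughout (merge/join/assign at
  distance ≤ threshold; quality pairs at the threshold are co-cluster
  side), except the audit's "more than 97% similar" census which is
  strict; all are parameterized.
- Linkage ties use a seeded RNG with a 1e-12 comparison tolerance; greedy
  ties are resolved deterministically by abundance/distance/id as above.
- MCC uses exact integer confusion counts; the denominator is evaluated in
  floating point (counts up to ~10⁸ pairs are far below precision loss).
- Degenerate inputs: empty record lists dereplicate to an empty set;
  empty greedy input yields an empty partition; zero-denominator MCC,
  sensitivity, and specificity are 0; an all-gap comparison window is an
  error rather than a silent zero.

## Known limitations

- Hierarchical clustering holds a dense n×n linkage matrix: fine for the
  10³–10⁴ unique sequences this package targets, not for survey-scale runs.
- The exhaustive reference matcher is quadratic by design; it is the
  measurement standard, not a production assigner.
- Stability comparisons require the subsample's unique sequences to be a
  subset of the full dataset's (guaranteed for read-level subsampling;
  not for noisy re-sequencing).
- Multiple-alignment construction, chimera detection, and denoising are
  out of scope; aligned inputs are taken as given.
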