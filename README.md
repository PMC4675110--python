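# otubench

Assigning 16S rRNA gene sequences to operational taxonomic units (OTUs) is
the first step of most amplicon-based microbiome analyses, and the many
available clustering methods — hierarchical de novo clustering, greedy
centroid clustering, and reference-database assignment — can disagree
substantially at the conventional 97%-similarity (3% distance) threshold.
`otubench` implements these methods together with the pair-counting
statistics needed to judge them objectively, for microbial ecologists and
method developers who want to measure, rather than assume, how well a
clustering represents their data.

## What it computes

Given a set of dereplicated unique sequences with read abundances, the
package provides:

- **De novo clustering** — single, average, and complete linkage
  (nearest/average/furthest neighbor) cut at a distance threshold, and
  abundance-based / distance-based greedy centroid clustering (AGC/DGC).
- **Reference-based clustering** — exhaustive closed-reference assignment
  (every query scored against every reference, no search heuristic),
  open-reference assignment, reference-order randomization, and a
  reference-database audit for duplicated sequences with discordant
  taxonomies.
- **Evaluation** — confusion counts over unordered sequence pairs and the
  Matthews correlation coefficient

      MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

  in two constructions: **quality** (OTU co-membership versus the pairwise
  distance relation at the threshold) and **stability** (co-membership in a
  subsampled dataset versus the full dataset's clustering).  Plus a
  threshold scan (argmax MCC over a 0–5% grid), hypergeometric rarefaction
  of OTU counts, and subsampling experiment drivers (by default 30
  subsample replicates × 30 input-order permutations = 900 comparisons per
  sampling fraction).
- **Synthetic data** — planted-cluster communities with controllable
  within/between-cluster divergence, abundance models, and sequencing
  error, and reference databases with planted region-duplicates, so every
  stage can be tested against known ground truth.

Distances come from global Needleman–Wunsch alignment with affine gap
penalties (match +1, mismatch −1, gap open −2, gap extend −1) or
column-wise from a shared alignment, with mothur-compatible gap-run
counting, and are stored sparsely below a cutoff (default 0.10).

## Worked example

```python
from otubench.synthetic import CommunitySpec, generate_community
from otubench.distance import distance_matrix
from otubench.denovo import method_cluster_fn
from otubench.evaluation import mcc, quality_confusion, threshold_scan

spec = CommunitySpec(n_clusters=5, intra_divergence=0.01,
                     inter_divergence=0.10, n_reads=500,
                     error_rate=0.0, seed=7)
units, truth = generate_community(spec)
dm = distance_matrix(units, mode="from_alignment", storage_cutoff=0.10)
for m in ("SL", "AL", "CL", "AGC", "DGC"):
    part = method_cluster_fn(m, threshold=0.03)(units, seed=1)
    q = mcc(quality_confusion(part, dm, 0.03))
    print(m, part.n_otus, round(q.mcc, 3))
best, _ = threshold_scan(truth.planted_partition, dm)
print("optimal threshold:", best)
```

prints

```
SL 5 1.0
AL 5 1.0
CL 5 1.0
AGC 5 1.0
DGC 5 1.0
optimal threshold: 0.01
```

Five planted clusters, 500 error-free reads: every method recovers the
planted partition exactly (5 OTUs, quality MCC 1.0 at the 3% threshold),
and the MCC scan picks 1% — the smallest grid threshold covering the
community's within-cluster divergence.  Raising the planted intra-cluster
divergence to 0.03 moves the scan optimum to 3%.

A command-line interface mirrors the library
(`otubench simulate|derep|dist|cluster|closedref|openref|auditdb|eval|scan|rarefy|experiment`);
see `otubench --help`.

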