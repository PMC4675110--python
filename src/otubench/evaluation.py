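"""Pair-counting evaluation of OTU partitions: quality, stability, MCC.

Two confusion-matrix constructions over unordered pairs of unique
sequences:

* **quality** — OTU co-membership against the distance matrix at a
  threshold: pairs in the same OTU within the threshold are TP, pairs in
  different OTUs beyond it are TN, co-clustered distant pairs are FP, and
  split close pairs are FN.
* **stability** — OTU co-membership in a subsampled dataset against the
  clustering of the full dataset, restricted to the subsample universe.

Both feed the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with 0 substituted when the denominator vanishes.  The module also
provides the threshold scan used to score externally produced partitions,
hypergeometric rarefaction of OTU counts, and the subsampling experiment
drivers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .denovo import permute_input
from .distance import DistanceMatrix, distance_matrix
from .seqio import DereplicatedSet, DereplicatedUnit, OTUPartition, degap

__all__ = [
    "ConfusionCounts",
    "MCCResult",
    "mcc",
    "quality_confusion",
    "stability_confusion",
    "threshold_scan",
    "rarefy_otu_count",
    "otu_abundances",
    "subsample_reads",
    "run_stability_experiment",
    "run_quality_experiment",
    "summarize_experiment",
]

DEFAULT_GRID = (0.00, 0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN over unordered sequence pairs."""

    tp: int
    tn: int
    fp: int
    fn: int
    mode: str = "quality"

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MCCResult:
    mcc: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts


def mcc(counts: ConfusionCounts) -> MCCResult:
    """Matthews correlation coefficient with the denominator-zero -> 0 rule.

    Sensitivity and specificity likewise report 0 when their denominators
    are zero, so experiment tables stay total.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    value = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    return MCCResult(value, sens, spec, counts)


def quality_confusion(
    partition: OTUPartition,
    dm: DistanceMatrix,
    threshold: float = 0.03,
    inclusive: bool = True,
) -> ConfusionCounts:
    """Confusion counts of OTU co-membership against pairwise distances.

    A pair at distance exactly equal to the threshold counts on the
    "should co-cluster" side when ``inclusive`` (the default, matching the
    0.03 = 97%-similarity convention).  Pairs absent from the sparse
    matrix are treated as beyond the threshold.
    """
    missing = [sid for sid in partition.universe if sid not in dm]
    if missing:
        raise ValueError(f"ids missing from distance matrix: {sorted(missing)[:5]}")
    if threshold > dm.storage_cutoff:
        raise ValueError(
            f"threshold {threshold} exceeds storage cutoff {dm.storage_cutoff}"
        )
    member = partition.membership()
    m = len(partition.universe)
    total = m * (m - 1) // 2
    same_otu_total = sum(len(o) * (len(o) - 1) // 2 for o in partition.otus)
    close = 0  # pairs within threshold
    tp = 0
    for a, b, d in dm.items():
        if a not in member or b not in member:
            continue
        is_close = d <= threshold if inclusive else d < threshold
        if is_close:
            close += 1
            if member[a] == member[b]:
                tp += 1
    fn = close - tp
    fp = same_otu_total - tp
    tn = total - tp - fn - fp
    return ConfusionCounts(tp, tn, fp, fn, mode="quality")


def stability_confusion(sub: OTUPartition, full: OTUPartition) -> ConfusionCounts:
    """Confusion counts of a subsample clustering against the full clustering.

    Pairs are counted over the subsample universe only (the only
    self-consistent choice): same OTU in both partitions -> TP, different
    in both -> TN, together only in the subsample -> FP, together only in
    the full data -> FN.
    """
    extra = sub.universe - full.universe
    if extra:
        raise ValueError(
            f"subsample ids absent from full partition: {sorted(extra)[:5]}"
        )
    full_member = full.membership()
    cells: Counter[tuple[int, int]] = Counter()
    rows: Counter[int] = Counter()
    cols: Counter[int] = Counter()
    for si, otu in enumerate(sub.otus):
        for sid in otu:
            fi = full_member[sid]
            cells[(si, fi)] += 1
            rows[si] += 1
            cols[fi] += 1
    tp = sum(n * (n - 1) // 2 for n in cells.values())
    same_sub = sum(n * (n - 1) // 2 for n in rows.values())
    same_full = sum(n * (n - 1) // 2 for n in cols.values())
    m = len(sub.universe)
    total = m * (m - 1) // 2
    fp = same_sub - tp
    fn = same_full - tp
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, tn, fp, fn, mode="stability")


def threshold_scan(
    partition: OTUPartition,
    dm: DistanceMatrix,
    thresholds: Sequence[float] = DEFAULT_GRID,
    inclusive: bool = True,
) -> tuple[float, dict[float, MCCResult]]:
    """Quality-MCC curve over a threshold grid; best = argmax, ties -> smallest."""
    if not thresholds:
        raise ValueError("threshold grid is empty")
    if max(thresholds) > dm.storage_cutoff:
        raise ValueError("grid exceeds the matrix storage cutoff")
    curve = {
        t: mcc(quality_confusion(partition, dm, t, inclusive))
        for t in thresholds
    }
    best = min(sorted(curve), key=lambda t: -curve[t].mcc)
    return best, curve


def otu_abundances(
    partition: OTUPartition, units: DereplicatedSet
) -> dict[str, int]:
    """Read abundance per OTU (unique-sequence abundances summed)."""
    by_id = {u.id: u.abundance for u in units.units}
    out: dict[str, int] = {}
    for lbl, otu in zip(partition.otu_labels, partition.otus):
        out[lbl] = sum(by_id[sid] for sid in otu)
    return out


def rarefy_otu_count(
    abundances: Mapping[str, int] | Sequence[int],
    n: int,
    mode: str = "analytic",
    reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Expected number of OTUs observed in a subsample of ``n`` reads.

    Analytic mode evaluates the hypergeometric expectation
    ``E[S] = sum_i (1 - C(N - N_i, n) / C(N, n))``; Monte-Carlo mode
    averages observed OTU counts over seeded draws without replacement.
    """
    sizes = np.asarray(
        list(abundances.values()) if isinstance(abundances, Mapping) else abundances,
        dtype=np.int64,
    )
    if sizes.size == 0 or (sizes <= 0).any():
        raise ValueError("OTU abundances must be positive")
    N = int(sizes.sum())
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if n > N:
        raise ValueError(f"subsample size {n} exceeds total reads {N}")
    if mode == "analytic":
        p_unseen = hypergeom.pmf(0, N, sizes, n)
        return float((1.0 - p_unseen).sum())
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_hypergeometric(sizes, n, size=reps)
        return float((draws > 0).sum(axis=1).mean())
    raise ValueError(f"unknown mode {mode!r}")


def subsample_reads(
    units: DereplicatedSet, n: int, rng: np.random.Generator
) -> DereplicatedSet:
    """Draw ``n`` reads without replacement and re-dereplicate.

    Sampling is read-level (abundance-weighted); because every read's
    sequence equals its unit's, the re-dereplicated subsample keeps the
    full dataset's representative ids, so partitions of subsample and full
    data share an id space.
    """
    N = units.total_reads
    if not 0 < n <= N:
        raise ValueError(f"subsample size {n} outside (0, {N}]")
    sizes = np.array([u.abundance for u in units.units], dtype=np.int64)
    counts = rng.multivariate_hypergeometric(sizes, n)
    new_units = []
    for u, c in zip(units.units, counts):
        if c > 0:
            new_units.append(
                DereplicatedUnit(u.id, u.seq, int(c), u.member_ids[: int(c)])
            )
    new_units.sort(key=lambda u: (-u.abundance, u.id))
    return DereplicatedSet(new_units)


ClusterFn = Callable[[DereplicatedSet, int], OTUPartition]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_stability_experiment(
    units: DereplicatedSet,
    cluster_fn: ClusterFn,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    n_subsample_reps: int = 30,
    n_full_perms: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Stability MCCs of subsample clusterings against full-data clusterings.

    The full dataset is clustered once per input-order permutation
    (``n_full_perms`` of them).  For each fraction, ``n_subsample_reps``
    read-level subsamples are drawn, re-dereplicated and clustered, and
    each is compared against every full-data clustering — at the defaults
    30 x 30 = 900 MCC values per fraction.  Returns a tidy frame with one
    row per (fraction, subsample_rep, full_perm) comparison.
    """
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    seeds = _child_seeds(seed, 2 * n_full_perms + 2 * n_subsample_reps * len(fractions))
    it = iter(seeds)
    full_parts = []
    for _ in range(n_full_perms):
        permuted = permute_input(units, next(it))
        full_parts.append(cluster_fn(permuted, next(it)))
    N = units.total_reads
    rows = []
    for frac in fractions:
        n = max(1, round(frac * N))
        for rep in range(n_subsample_reps):
            rng = np.random.default_rng(next(it))
            sub_units = subsample_reads(units, n, rng)
            sub_part = cluster_fn(sub_units, next(it))
            for p, full_part in enumerate(full_parts):
                res = mcc(stability_confusion(sub_part, full_part))
                rows.append(
                    {
                        "fraction": frac,
                        "subsample_rep": rep,
                        "full_perm": p,
                        "mcc": res.mcc,
                        "tp": res.counts.tp,
                        "tn": res.counts.tn,
                        "fp": res.counts.fp,
                        "fn": res.counts.fn,
                    }
                )
    return pd.DataFrame(rows)


def run_quality_experiment(
    units: DereplicatedSet,
    cluster_fn: ClusterFn,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    reps: int = 30,
    threshold: float = 0.03,
    seed: int = 0,
    dm_builder: Callable[[DereplicatedSet], DistanceMatrix] | None = None,
) -> pd.DataFrame:
    """Quality MCC of each subsample's clustering against its own distances.

    For every fraction x replicate the subsample is clustered and scored
    against the distance matrix of the subsample itself at the working
    threshold.  One row per replicate; summarize with
    :func:`summarize_experiment`.
    """
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"fraction {f} outside (0, 1]")
    if dm_builder is None:
        def dm_builder(sub: DereplicatedSet) -> DistanceMatrix:
            lengths = {len(u.seq) for u in sub.units}
            mode = "from_alignment" if len(lengths) == 1 else "pairwise_nw"
            return distance_matrix(sub, mode=mode, storage_cutoff=0.10)
    seeds = _child_seeds(seed, 2 * len(fractions) * reps)
    it = iter(seeds)
    N = units.total_reads
    rows = []
    for frac in fractions:
        n = max(1, round(frac * N))
        for rep in range(reps):
            rng = np.random.default_rng(next(it))
            sub_units = subsample_reads(units, n, rng)
            part = cluster_fn(sub_units, next(it))
            dm = dm_builder(sub_units)
            res = mcc(quality_confusion(part, dm, threshold))
            rows.append(
                {
                    "fraction": frac,
                    "rep": rep,
                    "mcc": res.mcc,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "n_otus": part.n_otus,
                    "n_unique": len(sub_units),
                }
            )
    return pd.DataFrame(rows)


def summarize_experiment(df: pd.DataFrame, value: str = "mcc") -> pd.DataFrame:
    """Mean and empirical 95% interval (2.5/97.5 percentiles) per fraction."""
    def q(p):
        return lambda s: float(np.percentile(s, p))

    out = df.groupby("fraction")[value].agg(
        mean="mean", lo=q(2.5), hi=q(97.5), n="count"
    )
    return out.reset_index()
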