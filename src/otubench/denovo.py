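"""De novo OTU clustering: hierarchical linkage and greedy centroid methods.

Hierarchical clustering (single, average, complete linkage — mothur's
nearest/average/furthest neighbor) agglomerates while the minimum linkage
stays at or below the distance threshold.  Greedy clustering (AGC/DGC)
scans sequences in decreasing-abundance order, joining the most abundant
(AGC) or closest (DGC) existing centroid within the threshold, or seeding
a new centroid.  Both families operate on unique sequences only; read
abundances matter solely for greedy ordering and the AGC choice.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

from .distance import DistanceMatrix
from .seqio import DereplicatedSet, DereplicatedUnit, OTUPartition, degap

__all__ = [
    "cluster_hierarchical",
    "cluster_greedy",
    "permute_input",
    "method_cluster_fn",
    "OTUPartition",
]

_INF = math.inf

HIERARCHICAL_METHODS = ("SL", "AL", "CL")
GREEDY_METHODS = ("AGC", "DGC")


def _initial_linkage(
    dm: DistanceMatrix, method: str, al_missing: str
) -> np.ndarray:
    """Dense singleton-pair linkage matrix; inf marks unmergeable pairs.

    Missing sparse pairs start at inf, except for AL under the ``cutoff``
    policy where they contribute the storage cutoff to the mean
    (conservative — biases against merging).
    """
    n = dm.n
    if method == "AL" and al_missing == "cutoff":
        L = np.full((n, n), dm.storage_cutoff)
    else:
        L = np.full((n, n), _INF)
    for (i, j), d in dm._d.items():
        L[i, j] = L[j, i] = d
    np.fill_diagonal(L, _INF)
    return L


def cluster_hierarchical(
    dm: DistanceMatrix,
    method: str = "AL",
    threshold: float = 0.03,
    seed: int = 0,
    al_missing: str = "cutoff",
    label: str | None = None,
) -> OTUPartition:
    """Agglomerative clustering cut at a distance threshold.

    Repeatedly merges the cluster pair with minimum linkage while that
    minimum is <= ``threshold`` (inclusive, matching the 0.03 = "97%
    similarity" convention).  Linkage is the min (SL), mean (AL), or max
    (CL) inter-cluster pair distance; pairs missing from the sparse matrix
    are treated per ``al_missing`` for AL and veto CL merges.  Exact
    linkage ties are broken by a seeded RNG.
    """
    method = method.upper()
    if method not in HIERARCHICAL_METHODS:
        raise ValueError(f"unknown hierarchical method {method!r}")
    if threshold > dm.storage_cutoff:
        raise ValueError(
            f"threshold {threshold} exceeds storage cutoff {dm.storage_cutoff}; "
            "distances needed for linkage may be missing"
        )
    if al_missing not in ("cutoff", "unmergeable"):
        raise ValueError(f"unknown al_missing policy {al_missing!r}")

    rng = np.random.default_rng(seed)
    n = dm.n
    L = _initial_linkage(dm, method, al_missing)
    sizes = np.ones(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    members: list[list[int]] = [[i] for i in range(n)]

    # Lance–Williams updates: the merged cluster's linkage to every other
    # cluster is the min (SL), max (CL), or pair-count-weighted mean (AL)
    # of its parts' linkages, which is exactly the naive recomputation.
    while alive.sum() > 1:
        sub = np.where(alive)[0]
        block = L[np.ix_(sub, sub)]
        iu = np.triu_indices(len(sub), k=1)
        vals = block[iu]
        best = vals.min()
        if not np.isfinite(best) or best > threshold:
            break
        tied = np.nonzero(vals <= best + 1e-12)[0]
        pick = tied[int(rng.integers(len(tied)))]
        i, j = int(sub[iu[0][pick]]), int(sub[iu[1][pick]])
        others = alive.copy()
        others[i] = others[j] = False
        if method == "SL":
            L[i, others] = np.minimum(L[i, others], L[j, others])
        elif method == "CL":
            L[i, others] = np.maximum(L[i, others], L[j, others])
        else:  # AL: weight by inter-cluster pair counts
            si, sj = sizes[i], sizes[j]
            L[i, others] = (si * L[i, others] + sj * L[j, others]) / (si + sj)
        L[others, i] = L[i, others]
        sizes[i] += sizes[j]
        members[i].extend(members[j])
        alive[j] = False

    otus = [frozenset(dm.ids[k] for k in members[c]) for c in np.where(alive)[0]]
    return OTUPartition(label if label is not None else f"{threshold:g}", otus)


def cluster_greedy(
    units: DereplicatedSet,
    dm_or_fn: DistanceMatrix | Callable[[str, str], float],
    mode: str = "DGC",
    threshold: float = 0.03,
    order: str = "abundance",
    label: str | None = None,
) -> OTUPartition:
    """Greedy centroid clustering (abundance- or distance-based).

    Sequences are scanned in decreasing-abundance order (ties by id) or in
    the given input order.  Each sequence is compared against every
    existing centroid; among centroids within ``threshold`` DGC joins the
    closest (ties: larger abundance, then id) and AGC the most abundant
    (ties: smaller distance, then id).  With no candidate the sequence
    seeds a new centroid; centroid sequences never change after creation.

    ``dm_or_fn`` is either a sparse :class:`DistanceMatrix` over the unit
    ids (missing pairs count as above-threshold) or a callable on degapped
    sequence strings.
    """
    mode = mode.upper()
    if mode not in GREEDY_METHODS:
        raise ValueError(f"unknown greedy mode {mode!r}")
    if order == "abundance":
        scan = sorted(units.units, key=lambda u: (-u.abundance, u.id))
    elif order == "given":
        scan = list(units.units)
    else:
        raise ValueError(f"unknown order {order!r}")

    if isinstance(dm_or_fn, DistanceMatrix):
        def dist(u: DereplicatedUnit, c: DereplicatedUnit) -> float:
            d = dm_or_fn.get(u.id, c.id)
            return _INF if d is None else d
    else:
        cache: dict[tuple[str, str], float] = {}

        def dist(u: DereplicatedUnit, c: DereplicatedUnit) -> float:
            key = (u.id, c.id)
            if key not in cache:
                cache[key] = dm_or_fn(degap(u.seq), degap(c.seq))
            return cache[key]

    centroids: list[DereplicatedUnit] = []
    members: list[set[str]] = []
    for u in scan:
        candidates = [
            (dist(u, c), c, k) for k, c in enumerate(centroids)
        ]
        candidates = [(d, c, k) for d, c, k in candidates if d <= threshold]
        if not candidates:
            centroids.append(u)
            members.append({u.id})
            continue
        if mode == "DGC":
            d, c, k = min(candidates, key=lambda t: (t[0], -t[1].abundance, t[1].id))
        else:  # AGC
            d, c, k = min(candidates, key=lambda t: (-t[1].abundance, t[0], t[1].id))
        members[k].add(u.id)

    otus = [frozenset(m) for m in members]
    return OTUPartition(
        label if label is not None else f"{mode.lower()}_{threshold:g}",
        otus,
        otu_labels=[c.id for c in centroids] or None,
    )


def permute_input(units: DereplicatedSet, seed: int) -> DereplicatedSet:
    """Return the same units in a seeded random order (Fisher–Yates shuffle)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(units.units))
    return DereplicatedSet([units.units[i] for i in perm])


def method_cluster_fn(
    method: str,
    threshold: float = 0.03,
    storage_cutoff: float = 0.10,
    dm_mode: str = "from_alignment",
    distance_fn: Callable[[str, str], float] | None = None,
) -> Callable[[DereplicatedSet, int], OTUPartition]:
    """Bind a named method to a ``cluster_fn(units, seed) -> OTUPartition``.

    Hierarchical methods build a distance matrix from the units first
    (``dm_mode`` as in :func:`otubench.distance.distance_matrix`); greedy
    methods compare sequences directly via ``distance_fn`` (default:
    Hamming for uniform-length inputs, NW alignment otherwise).
    """
    from .distance import distance_matrix, hamming_distance, nw_distance

    method = method.upper()
    if method in HIERARCHICAL_METHODS:
        def fn(units: DereplicatedSet, seed: int) -> OTUPartition:
            dm = distance_matrix(units, mode=dm_mode, storage_cutoff=storage_cutoff)
            return cluster_hierarchical(dm, method, threshold, seed=seed)
        return fn
    if method in GREEDY_METHODS:
        def fn(units: DereplicatedSet, seed: int) -> OTUPartition:
            if distance_fn is not None:
                dfn = distance_fn
            else:
                lengths = {len(degap(u.seq)) for u in units.units}
                dfn = hamming_distance if len(lengths) <= 1 else nw_distance
            return cluster_greedy(units, dfn, mode=method, threshold=threshold)
        return fn
    raise ValueError(
        f"unknown method {method!r}; valid: "
        f"{', '.join(HIERARCHICAL_METHODS + GREEDY_METHODS)}"
    )
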