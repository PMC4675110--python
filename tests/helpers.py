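"""Shared brute-force oracles and random-instance builders for the tests.

The oracles here deliberately use the naive double-loop / graph-library
formulations so they stay independent of the package's optimized paths.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from otubench.distance import DistanceMatrix
from otubench.seqio import DereplicatedSet, DereplicatedUnit, OTUPartition


def random_sparse_dm(
    rng: np.random.Generator,
    n: int,
    storage_cutoff: float = 0.10,
    p_close: float = 0.4,
) -> DistanceMatrix:
    """Random symmetric sparse matrix; a fraction of pairs lands below cutoff."""
    ids = [f"s{i:03d}" for i in range(n)]
    dm = DistanceMatrix(ids, storage_cutoff)
    for a, b in itertools.combinations(ids, 2):
        if rng.random() < p_close:
            dm.set(a, b, rng.uniform(0, storage_cutoff))
        else:
            dm.set(a, b, rng.uniform(storage_cutoff, 1.0))  # dropped by sparsity
    return dm


def random_partition(rng: np.random.Generator, ids: list[str]) -> OTUPartition:
    """Random assignment of ids to up to len(ids) OTUs."""
    k = int(rng.integers(1, len(ids) + 1))
    labels = rng.integers(0, k, size=len(ids))
    groups: dict[int, set[str]] = {}
    for sid, lbl in zip(ids, labels):
        groups.setdefault(int(lbl), set()).add(sid)
    return OTUPartition("rand", list(groups.values()))


def random_units(rng: np.random.Generator, n: int, length: int = 60) -> DereplicatedSet:
    """Random distinct gap-free sequences with random abundances."""
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: set[str] = set()
    units = []
    i = 0
    while len(units) < n:
        s = rng.choice(bases, size=length).tobytes().decode()
        if s in seqs:
            continue
        seqs.add(s)
        ab = int(rng.integers(1, 20))
        rid = f"u{i:03d}"
        units.append(
            DereplicatedUnit(rid, s, ab, [rid] + [f"{rid}.{k}" for k in range(2, ab + 1)])
        )
        i += 1
    units.sort(key=lambda u: (-u.abundance, u.id))
    return DereplicatedSet(units)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def brute_quality(partition: OTUPartition, dm: DistanceMatrix, threshold: float):
    """Pair-by-pair double loop over the whole universe."""
    member = partition.membership()
    tp = tn = fp = fn = 0
    for a, b in itertools.combinations(sorted(partition.universe), 2):
        d = dm.get(a, b)
        close = d is not None and d <= threshold
        same = member[a] == member[b]
        if same and close:
            tp += 1
        elif not same and not close:
            tn += 1
        elif same:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def brute_stability(sub: OTUPartition, full: OTUPartition):
    ms, mf = sub.membership(), full.membership()
    tp = tn = fp = fn = 0
    for a, b in itertools.combinations(sorted(sub.universe), 2):
        same_s = ms[a] == ms[b]
        same_f = mf[a] == mf[b]
        if same_s and same_f:
            tp += 1
        elif not same_s and not same_f:
            tn += 1
        elif same_s:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn


def threshold_graph(dm: DistanceMatrix, threshold: float) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(dm.ids)
    for a, b, d in dm.items():
        if d <= threshold:
            g.add_edge(a, b)
    return g


def components_partition(dm: DistanceMatrix, threshold: float) -> OTUPartition:
    """Connected components of the threshold graph (single-linkage oracle)."""
    g = threshold_graph(dm, threshold)
    return OTUPartition("cc", [set(c) for c in nx.connected_components(g)])


def graph_is_transitive(g: nx.Graph) -> bool:
    """Every connected component is a clique."""
    for comp in nx.connected_components(g):
        comp = list(comp)
        for a, b in itertools.combinations(comp, 2):
            if not g.has_edge(a, b):
                return False
    return True
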