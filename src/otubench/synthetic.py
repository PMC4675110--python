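"""Synthetic communities and reference databases with known ground truth.

The community generator emulates the structure of a dereplicated amplicon
dataset: a set of cluster templates separated by at least
``inter_divergence``, satellite variants within ``intra_divergence`` of
each template, and reads drawn from an abundance model with i.i.d.
per-base substitution errors.  Mutated positions are disjoint across the
satellites of a cluster, so all planted distances are exact Hamming
fractions: template-to-satellite distance is ``k/L`` and
satellite-to-satellite ``2k/L`` with ``k = floor(intra * L / 2)``, keeping
every within-cluster pair at or below the declared intra divergence.

The reference generator plants duplicate groups that are identical over
an extracted subregion while remaining well separated over the full
length — the property that makes closed-reference OTU labels sensitive to
reference order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .reference import ReferenceDB
from .seqio import (
    DereplicatedSet,
    OTUPartition,
    SequenceRecord,
    dereplicate,
)

__all__ = [
    "CommunitySpec",
    "SyntheticTruth",
    "generate_community",
    "generate_reference_db",
    "reference_query_set",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Parameters of a planted-cluster synthetic community.

    Defaults describe a small MiSeq-like V4 community: 10 planted OTUs of
    3 variants each over 250-nt sequences, 2,000 reads with lognormal
    cluster abundances, and a per-base substitution error rate of 0.02%
    (the error rate reported for well-curated MiSeq amplicon data).
    """

    n_clusters: int = 10
    variants_per_cluster: int = 3
    intra_divergence: float = 0.01
    inter_divergence: float = 0.10
    seq_length: int = 250
    abundance_model: str = "lognormal"  # uniform | lognormal | powerlaw
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    powerlaw_alpha: float = 1.5
    n_reads: int = 2000
    error_rate: float = 0.0002
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.variants_per_cluster < 1:
            raise ValueError("need at least one cluster and one variant")
        if not self.inter_divergence > self.intra_divergence >= 0:
            raise ValueError("require inter_divergence > intra_divergence >= 0")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.abundance_model not in ("uniform", "lognormal", "powerlaw"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if self.seq_length < 20:
            raise ValueError("seq_length too short to satisfy divergence bounds")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic community."""

    planted_partition: OTUPartition  # over dereplicated representative ids
    template_of: dict[str, str]  # read id -> template id
    cluster_of_unit: dict[str, int]  # representative id -> cluster index
    templates: dict[str, str]  # template id -> sequence
    variant_seqs: dict[str, str] = field(default_factory=dict)
    reference_assignment: dict[str, str] | None = None  # template -> reference id


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def _mutate(
    seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each given position with a different base."""
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def _make_templates(
    rng: np.random.Generator, k: int, L: int, min_dist: int, max_attempts: int = 200
) -> list[np.ndarray]:
    """Rejection-sample templates from a random ancestor, pairwise >= min_dist."""
    ancestor = rng.choice(_BASES, size=L)
    n_mut = min(L, max(min_dist, math.ceil(1.5 * min_dist)))
    templates: list[np.ndarray] = []
    for _ in range(k):
        for attempt in range(max_attempts):
            pos = rng.choice(L, size=n_mut, replace=False)
            cand = _mutate(ancestor, pos, rng)
            if all(int((cand != t).sum()) >= min_dist for t in templates):
                templates.append(cand)
                break
        else:
            raise ValueError(
                "could not satisfy divergence constraints; "
                "try a longer seq_length or smaller inter_divergence"
            )
    return templates


def _cluster_weights(spec: CommunitySpec, rng: np.random.Generator) -> np.ndarray:
    k = spec.n_clusters
    if spec.abundance_model == "uniform":
        w = np.ones(k)
    elif spec.abundance_model == "lognormal":
        w = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=k)
    else:  # powerlaw rank-abundance: w_i ~ rank^-alpha
        w = np.arange(1, k + 1, dtype=float) ** (-spec.powerlaw_alpha)
        rng.shuffle(w)
    return w / w.sum()


def generate_community(spec: CommunitySpec) -> tuple[DereplicatedSet, SyntheticTruth]:
    """Generate reads from planted clusters and dereplicate them.

    Deterministic given ``spec.seed``: randomness is split into
    per-component streams (templates, abundances, errors) from a single
    seed sequence.  Every variant receives at least one read so the
    planted partition is fully represented; remaining reads are drawn
    multinomially from the abundance model.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_tpl, rng_ab, rng_err = [np.random.default_rng(s) for s in ss.spawn(3)]
    L = spec.seq_length
    k = spec.n_clusters

    # Satellites must not erode the inter-cluster bound: templates are
    # separated by an extra margin of twice the satellite radius.
    radius = int(spec.intra_divergence * L / 2)
    min_inter = math.ceil(spec.inter_divergence * L) + 2 * radius
    templates = _make_templates(rng_tpl, k, L, min_inter)

    variant_arrs: list[np.ndarray] = []
    variant_ids: list[str] = []
    variant_cluster: list[int] = []
    variant_template: list[str] = []
    templates_by_id: dict[str, str] = {}
    for c, tpl in enumerate(templates):
        tid = f"t{c:03d}"
        templates_by_id[tid] = _decode(tpl)
        variant_arrs.append(tpl)
        variant_ids.append(tid)
        variant_cluster.append(c)
        variant_template.append(tid)
        n_sat = spec.variants_per_cluster - 1 if radius >= 1 else 0
        if n_sat:
            pool = rng_tpl.choice(L, size=n_sat * radius, replace=False)
            for v in range(n_sat):
                pos = pool[v * radius : (v + 1) * radius]
                sat = _mutate(tpl, pos, rng_tpl)
                variant_arrs.append(sat)
                variant_ids.append(f"{tid}.v{v + 1}")
                variant_cluster.append(c)
                variant_template.append(tid)

    n_units = len(variant_arrs)
    if spec.n_reads < n_units:
        raise ValueError(
            f"n_reads={spec.n_reads} below the {n_units} planted variants"
        )
    cw = _cluster_weights(spec, rng_ab)
    unit_w = np.array(
        [cw[c] / variant_cluster.count(c) for c in variant_cluster]
    )
    unit_w = unit_w / unit_w.sum()
    counts = np.ones(n_units, dtype=np.int64)
    counts += rng_ab.multinomial(spec.n_reads - n_units, unit_w)

    records: list[SequenceRecord] = []
    template_of: dict[str, str] = {}
    read_cluster: dict[str, int] = {}
    read_no = 0
    for v in range(n_units):
        base = variant_arrs[v]
        for _ in range(int(counts[v])):
            rid = f"r{read_no:06d}"
            read_no += 1
            n_err = rng_err.binomial(L, spec.error_rate)
            seq = base
            if n_err:
                pos = rng_err.choice(L, size=n_err, replace=False)
                seq = _mutate(base, pos, rng_err)
            records.append(SequenceRecord(rid, _decode(seq)))
            template_of[rid] = variant_template[v]
            read_cluster[rid] = variant_cluster[v]

    derep = dereplicate(records)
    cluster_of_unit = {u.id: read_cluster[u.member_ids[0]] for u in derep.units}
    groups: dict[int, set[str]] = {}
    for uid, c in cluster_of_unit.items():
        groups.setdefault(c, set()).add(uid)
    planted = OTUPartition(
        "planted",
        [groups[c] for c in sorted(groups)],
        otu_labels=[f"cluster{c:03d}" for c in sorted(groups)],
    )
    truth = SyntheticTruth(
        planted_partition=planted,
        template_of=template_of,
        cluster_of_unit=cluster_of_unit,
        templates=templates_by_id,
        variant_seqs={
            vid: _decode(arr) for vid, arr in zip(variant_ids, variant_arrs)
        },
    )
    return derep, truth


def generate_reference_db(
    n_refs: int = 30,
    duplicate_groups: Sequence[tuple[int, int]] = (),
    region_length: int = 150,
    flank_length: int = 50,
    seed: int = 0,
    min_region_separation: float = 0.20,
    max_full_similarity: float = 0.97,
) -> tuple[ReferenceDB, dict]:
    """Generate an aligned full-length reference DB with planted duplicates.

    Each reference is flank + region + flank (no gap characters, so the
    trivial alignment is the identity).  References are mutually less than
    ``max_full_similarity`` similar over the full length, but each planted
    duplicate group of ``(size, n_taxonomies)`` shares one region sequence
    — identical over the extracted region — carrying the stated number of
    distinct taxonomy strings.  Non-group region sequences are separated
    by at least ``min_region_separation`` so best hits against them are
    unambiguous.

    Returns the DB (with ``region`` set to the planted column interval)
    and a truth dict with the group memberships.
    """
    g_total = sum(size for size, _ in duplicate_groups)
    if g_total > n_refs:
        raise ValueError("duplicate group sizes exceed n_refs")
    for size, ntax in duplicate_groups:
        if size < 2:
            raise ValueError("duplicate groups need size >= 2")
        if not 1 <= ntax <= size:
            raise ValueError("n_taxonomies must be between 1 and group size")
    rng = np.random.default_rng(seed)
    L_region = region_length
    n_region_seqs = n_refs - g_total + len(duplicate_groups)

    region_seqs: list[np.ndarray] = []
    min_sep = math.ceil(min_region_separation * L_region)
    for _ in range(n_region_seqs):
        for attempt in range(200):
            cand = rng.choice(_BASES, size=L_region)
            if all(int((cand != s).sum()) >= min_sep for s in region_seqs):
                region_seqs.append(cand)
                break
        else:
            raise ValueError("could not separate region sequences; lengthen region")

    # region sequence index per reference: groups first, then singletons
    assignment: list[tuple[int, int | None]] = []  # (region index, group index)
    idx = 0
    for gi, (size, _) in enumerate(duplicate_groups):
        for _ in range(size):
            assignment.append((idx, gi))
        idx += 1
    while len(assignment) < n_refs:
        assignment.append((idx, None))
        idx += 1

    max_dist_needed = 1.0 - max_full_similarity
    L_full = 2 * flank_length + L_region
    records: list[SequenceRecord] = []
    taxonomy: dict[str, str] = {}
    group_members: list[list[str]] = [[] for _ in duplicate_groups]
    group_tax_cycle = [
        [f"k__Bacteria;p__Dup{gi};g__G{gi};s__S{gi}_{t}" for t in range(ntax)]
        for gi, (_, ntax) in enumerate(duplicate_groups)
    ]
    seqs_so_far: list[np.ndarray] = []
    for i, (ri, gi) in enumerate(assignment):
        rid = f"ref{i:04d}"
        for attempt in range(200):
            flank5 = rng.choice(_BASES, size=flank_length)
            flank3 = rng.choice(_BASES, size=flank_length)
            full = np.concatenate([flank5, region_seqs[ri], flank3])
            dists = [int((full != s).sum()) / L_full for s in seqs_so_far]
            if all(d > max_dist_needed for d in dists):
                break
        else:
            raise ValueError("could not separate full-length references")
        seqs_so_far.append(full)
        records.append(SequenceRecord(rid, _decode(full)))
        if gi is not None:
            members = group_members[gi]
            taxonomy[rid] = group_tax_cycle[gi][len(members) % len(group_tax_cycle[gi])]
            members.append(rid)
        else:
            taxonomy[rid] = f"k__Bacteria;p__P{i};g__G{i};s__S{i}"

    db = ReferenceDB(records, taxonomy, region=(flank_length, flank_length + L_region))
    truth = {
        "region": (flank_length, flank_length + L_region),
        "duplicate_groups": [
            {"ids": ids, "n_taxonomies": ntax}
            for ids, (_, ntax) in zip(group_members, duplicate_groups)
        ],
    }
    return db, truth


def reference_query_set(db: ReferenceDB, prefix: str = "q") -> DereplicatedSet:
    """One query per distinct region sequence of a reference DB.

    Queries are exact copies of the (region-extracted) reference
    sequences, so each has a best hit at distance zero — tied among all
    members of a duplicate group, unique otherwise.  Useful for probing
    label stability under reference reordering.
    """
    if db.region is None:
        raise ValueError("reference DB has no region set")
    start, end = db.region
    seen: dict[str, str] = {}
    records = []
    for rec in db.records:
        sub = rec.seq[start:end] if len(rec.seq) > end else rec.seq
        if sub not in seen:
            qid = f"{prefix}{len(seen):04d}"
            seen[sub] = qid
            records.append(SequenceRecord(qid, sub))
    return dereplicate(records)
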