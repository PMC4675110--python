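"""Sequence I/O, dereplication, and the core in-memory containers.

Everything downstream (distances, clustering, evaluation) operates on
:class:`DereplicatedSet` — unique sequences with read abundances — and on
:class:`OTUPartition` — a disjoint assignment of sequence ids to OTUs.
On-disk formats follow the mothur conventions (names file, count table,
list file, taxonomy file) so results interoperate with that ecosystem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP_CHARS = frozenset("-.")
#: characters accepted on read, after uppercasing (U is rewritten to T)
VALID_CHARS = frozenset("ACGTN-.")


def degap(seq: str) -> str:
    """Strip alignment gap characters ('-' and '.') from a sequence."""
    return seq.translate({ord("-"): None, ord("."): None})


def _normalize_seq(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_CHARS
    if bad:
        raise ValueError(
            f"record {record_id!r} contains illegal characters: {sorted(bad)}"
        )
    if not s:
        raise ValueError(f"record {record_id!r} has an empty sequence")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A single named nucleotide sequence (possibly gapped when aligned)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")


@dataclass
class DereplicatedUnit:
    """One unique sequence: representative id, abundance, member read ids."""

    id: str
    seq: str
    abundance: int
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError(f"unit {self.id!r}: abundance must be positive")
        if self.abundance != len(self.member_ids):
            raise ValueError(
                f"unit {self.id!r}: abundance {self.abundance} != "
                f"{len(self.member_ids)} member ids"
            )
        if self.id not in self.member_ids:
            raise ValueError(f"unit {self.id!r}: representative not a member")


@dataclass
class DereplicatedSet:
    """Unique sequences with abundances; the unit all clustering operates on."""

    units: list[DereplicatedUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [degap(u.seq) for u in self.units]
        if len(set(keys)) != len(keys):
            raise ValueError("dereplicated sequences are not pairwise distinct")
        ids = [u.id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate representative ids")

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    @property
    def ids(self) -> list[str]:
        return [u.id for u in self.units]

    @property
    def total_reads(self) -> int:
        return sum(u.abundance for u in self.units)

    def unit_by_id(self, unit_id: str) -> DereplicatedUnit:
        for u in self.units:
            if u.id == unit_id:
                return u
        raise KeyError(unit_id)

    def expand(self) -> list[SequenceRecord]:
        """Re-expand to one record per read (members carry the unit sequence)."""
        return [
            SequenceRecord(rid, u.seq) for u in self.units for rid in u.member_ids
        ]

    def records(self) -> list[SequenceRecord]:
        """One record per unique sequence, named by its representative."""
        return [SequenceRecord(u.id, u.seq) for u in self.units]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, in file order.

    The id is the header token before the first whitespace; descriptions are
    dropped.  Sequences are uppercased and U is rewritten to T.  Duplicate
    ids, illegal characters, and empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _normalize_seq(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(_BioSeq(r.seq), id=r.id, description="") for r in records
    ]
    _BioSeqIO.write(bio, str(path), "fasta")


def dereplicate(records: Sequence[SequenceRecord]) -> DereplicatedSet:
    """Collapse identical sequences into unique units with abundances.

    The dereplication key ignores gap characters (so aligned inputs collapse
    on the underlying sequence) but the aligned string of the first
    occurrence is retained for column-wise distance calculation.  The
    representative id is the id of the first occurrence; units are sorted by
    decreasing abundance, ties broken lexicographically by representative id
    so downstream greedy clustering is reproducible without a seed.
    """
    gapped = [r for r in records if set(r.seq) & GAP_CHARS]
    if gapped and len({len(r.seq) for r in records}) != 1:
        raise ValueError("aligned input must have uniform sequence length")
    by_key: dict[str, DereplicatedUnit] = {}
    for rec in records:
        key = degap(rec.seq)
        if not key:
            raise ValueError(f"record {rec.id!r} is all gaps")
        unit = by_key.get(key)
        if unit is None:
            by_key[key] = DereplicatedUnit(rec.id, rec.seq, 1, [rec.id])
        else:
            unit.abundance += 1
            unit.member_ids.append(rec.id)
    units = sorted(by_key.values(), key=lambda u: (-u.abundance, u.id))
    return DereplicatedSet(units)


# ---------------------------------------------------------------------------
# OTU partitions and the mothur list-file convention
# ---------------------------------------------------------------------------


class OTUPartition:
    """A disjoint assignment of sequence ids to labeled OTUs.

    Parameters
    ----------
    label:
        Threshold or method tag (the first column of a mothur list file).
    otus:
        Iterable of non-empty id collections; converted to frozensets.
    otu_labels:
        Optional per-OTU labels (e.g. ``"ref:gg_001"``); defaults to
        ``Otu0001``-style names.
    """

    def __init__(
        self,
        label: str,
        otus: Iterable[Iterable[str]],
        otu_labels: Sequence[str] | None = None,
    ) -> None:
        self.label = str(label)
        self.otus: list[frozenset[str]] = [frozenset(o) for o in otus]
        if any(not o for o in self.otus):
            raise ValueError("OTUs must be non-empty")
        total = sum(len(o) for o in self.otus)
        universe: set[str] = set().union(*self.otus) if self.otus else set()
        if len(universe) != total:
            raise ValueError("OTUs are not pairwise disjoint")
        self.universe: frozenset[str] = frozenset(universe)
        if otu_labels is not None:
            if len(otu_labels) != len(self.otus):
                raise ValueError("otu_labels length mismatch")
            self.otu_labels = list(otu_labels)
        else:
            width = max(4, len(str(len(self.otus))))
            self.otu_labels = [f"Otu{i + 1:0{width}d}" for i in range(len(self.otus))]

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def membership(self) -> dict[str, int]:
        """Map each id to the index of its OTU."""
        out: dict[str, int] = {}
        for i, otu in enumerate(self.otus):
            for sid in otu:
                out[sid] = i
        return out

    def as_sets(self) -> frozenset[frozenset[str]]:
        """Label-free view, for comparing clusterings up to OTU order."""
        return frozenset(self.otus)

    def same_clustering(self, other: "OTUPartition") -> bool:
        return self.universe == other.universe and self.as_sets() == other.as_sets()

    def sizes(self) -> list[int]:
        return sorted((len(o) for o in self.otus), reverse=True)

    def __repr__(self) -> str:
        return (
            f"OTUPartition(label={self.label!r}, n_otus={self.n_otus}, "
            f"n_seqs={len(self.universe)})"
        )


def write_list_file(partitions: Sequence[OTUPartition], path: str | Path) -> None:
    """Write partitions in mothur list format.

    One line per partition: label, OTU count, then one tab-separated field
    per OTU with comma-joined member ids.  Member ids and OTUs are written
    in sorted order so output is deterministic.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for part in partitions:
            otus = sorted(",".join(sorted(o)) for o in part.otus)
            fh.write("\t".join([part.label, str(part.n_otus), *otus]) + "\n")


def read_list_file(path: str | Path) -> list[OTUPartition]:
    partitions: list[OTUPartition] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed list line")
            label, count_s, *otu_fields = fields
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: OTU count {count_s!r} is not an integer"
                ) from None
            if count != len(otu_fields):
                raise ValueError(
                    f"{path}:{lineno}: declared {count} OTUs but found "
                    f"{len(otu_fields)}"
                )
            otus = []
            for f in otu_fields:
                members = [m for m in f.split(",") if m]
                if not members:
                    raise ValueError(f"{path}:{lineno}: empty OTU field")
                otus.append(members)
            partitions.append(OTUPartition(label, otus))
    return partitions


# ---------------------------------------------------------------------------
# Two-column tables: taxonomy, counts, names
# ---------------------------------------------------------------------------


def _read_two_column(path: str | Path) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            rows.append((parts[0], parts[1].strip()))
    return rows


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read an id<TAB>taxonomy table (semicolon-delimited ranks)."""
    table: dict[str, str] = {}
    for key, value in _read_two_column(path):
        if key in table:
            raise ValueError(f"repeated taxonomy key {key!r} in {path}")
        table[key] = value
    return table


def write_taxonomy(table: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in table:
            fh.write(f"{key}\t{table[key]}\n")


def read_count_table(path: str | Path) -> dict[str, int]:
    """Read an id<TAB>count table with positive integer counts."""
    counts: dict[str, int] = {}
    for key, value in _read_two_column(path):
        if key in counts:
            raise ValueError(f"repeated count key {key!r} in {path}")
        try:
            n = int(value)
        except ValueError:
            raise ValueError(f"count for {key!r} is not an integer: {value!r}") from None
        if n <= 0:
            raise ValueError(f"count for {key!r} must be positive, got {n}")
        counts[key] = n
    return counts


def write_count_table(derep: DereplicatedSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in derep.units:
            fh.write(f"{u.id}\t{u.abundance}\n")


def read_names_file(path: str | Path) -> dict[str, list[str]]:
    """Read a mothur names file: rep_id<TAB>comma-joined member ids."""
    names: dict[str, list[str]] = {}
    for key, value in _read_two_column(path):
        if key in names:
            raise ValueError(f"repeated representative {key!r} in {path}")
        members = [m for m in value.split(",") if m]
        if key not in members:
            raise ValueError(f"representative {key!r} missing from its members")
        names[key] = members
    return names


def write_names_file(derep: DereplicatedSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u in derep.units:
            fh.write(f"{u.id}\t{','.join(u.member_ids)}\n")


def derep_from_tables(
    records: Sequence[SequenceRecord], counts: Mapping[str, int]
) -> DereplicatedSet:
    """Build a DereplicatedSet from unique-sequence records plus a count table.

    Member read ids are synthesized (``rep``, ``rep.2`` ...) since the count
    table does not retain them; totals and ordering follow the usual rules.
    """
    units = []
    for rec in records:
        n = counts.get(rec.id)
        if n is None:
            raise ValueError(f"no count for sequence {rec.id!r}")
        members = [rec.id] + [f"{rec.id}.{i}" for i in range(2, n + 1)]
        units.append(DereplicatedUnit(rec.id, rec.seq, n, members))
    units.sort(key=lambda u: (-u.abundance, u.id))
    return DereplicatedSet(units)
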