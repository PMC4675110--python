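"""Pairwise distances between unique sequences.

Distances come from either global Needleman–Wunsch alignment of unaligned
pairs (affine gap penalties, deterministic traceback) or column-wise
comparison of sequences sharing a multiple alignment.  The distance
calculator mirrors mothur's ``pairwise.seqs`` defaults: a maximal run of
gap columns counts as a single difference (``one_gap_per_run``) and
terminal gap columns are counted (``count_end_gaps=True``); both are
configurable.  Matrices are stored sparsely: pairs above ``storage_cutoff``
are omitted and treated as "definitely different" downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import DereplicatedSet, GAP_CHARS, SequenceRecord, degap

__all__ = [
    "AlignmentParams",
    "DistanceMatrix",
    "nw_align",
    "pair_distance",
    "hamming_distance",
    "distance_matrix",
    "write_column_format",
    "read_column_format",
    "write_phylip",
    "read_phylip",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and distance-calculator options.

    Defaults follow mothur's documented pairwise defaults: match +1,
    mismatch −1, gap open −2, gap extend −1.  A gap of length *k* costs
    ``gap_open + (k-1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    gap_mode: str = "one_gap_per_run"  # or "each_gap_column"
    count_end_gaps: bool = True

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.gap_mode not in ("one_gap_per_run", "each_gap_column"):
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


DEFAULT_PARAMS = AlignmentParams()

_NEG = float("-inf")


def nw_align(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> tuple[str, str, float]:
    """Globally align two gap-free sequences under affine gap scoring (Gotoh).

    Returns the aligned pair and the optimal score.  Traceback ties are
    broken deterministically, preferring diagonal, then up (gap in ``b``),
    then left (gap in ``a``), so results are order- and platform-stable.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if set(a) & GAP_CHARS or set(b) & GAP_CHARS:
        raise ValueError("input sequences must be gap-free")
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    ma, mi = params.match, params.mismatch

    # M: column ends in a match/mismatch; X: gap in b (vertical, consumes a);
    # Y: gap in a (horizontal, consumes b).  Pointer codes 0=M, 1=X, 2=Y.
    # Row-wise pure-Python DP: an order of magnitude faster than per-cell
    # array indexing at amplicon lengths.
    width = m + 1
    Mprev = [_NEG] * width
    Xprev = [_NEG] * width
    Yprev = [_NEG] * width
    Mprev[0] = 0.0
    for j in range(1, width):
        Yprev[j] = go + (j - 1) * ge
    PM = [bytearray(width) for _ in range(n + 1)]
    PX = [bytearray(width) for _ in range(n + 1)]
    PY = [bytearray(width) for _ in range(n + 1)]
    for row in PY:
        for j in range(1, width):
            row[j] = 2
    for i in range(1, n + 1):
        PX[i][0] = 1

    for i in range(1, n + 1):
        ai = a[i - 1]
        Mcur = [_NEG] * width
        Xcur = [_NEG] * width
        Ycur = [_NEG] * width
        Xcur[0] = go + (i - 1) * ge
        pm, px, py = PM[i], PX[i], PY[i]
        for j in range(1, width):
            s = ma if ai == b[j - 1] else mi
            # prefer M > X > Y at every tie
            vm, vx, vy = Mprev[j - 1], Xprev[j - 1], Yprev[j - 1]
            if vm >= vx and vm >= vy:
                Mcur[j] = vm + s
            elif vx >= vy:
                Mcur[j] = vx + s
                pm[j] = 1
            else:
                Mcur[j] = vy + s
                pm[j] = 2

            vm, vx, vy = Mprev[j] + go, Xprev[j] + ge, Yprev[j] + go
            if vm >= vx and vm >= vy:
                Xcur[j] = vm
            elif vx >= vy:
                Xcur[j] = vx
                px[j] = 1
            else:
                Xcur[j] = vy
                px[j] = 2

            vm, vx, vy = Mcur[j - 1] + go, Xcur[j - 1] + go, Ycur[j - 1] + ge
            if vm >= vx and vm >= vy:
                Ycur[j] = vm
            elif vx >= vy:
                Ycur[j] = vx
                py[j] = 1
            else:
                Ycur[j] = vy
                py[j] = 2
        Mprev, Xprev, Yprev = Mcur, Xcur, Ycur

    finals = (Mprev[m], Xprev[m], Yprev[m])
    state = 0 if finals[0] >= finals[1] and finals[0] >= finals[2] else (
        1 if finals[1] >= finals[2] else 2
    )
    score = float(finals[state])

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            prev = PM[i][j]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            prev = PX[i][j]
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            prev = PY[i][j]
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = int(prev)
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


def pair_distance(
    aligned_a: str, aligned_b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Distance between two equal-length aligned strings, in [0, 1].

    distance = differences / compared length.  Columns where both sequences
    have gaps are skipped.  With ``gap_mode='one_gap_per_run'`` a maximal
    run of gap columns (same sequence gapped) counts as one difference and
    one unit of length.  With ``count_end_gaps=False`` leading and trailing
    gap columns are excluded from the comparison.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    cols = [
        (x, y)
        for x, y in zip(aligned_a, aligned_b)
        if not (x in GAP_CHARS and y in GAP_CHARS)
    ]
    if not params.count_end_gaps:
        lo, hi = 0, len(cols)
        while lo < hi and (cols[lo][0] in GAP_CHARS or cols[lo][1] in GAP_CHARS):
            lo += 1
        while hi > lo and (cols[hi - 1][0] in GAP_CHARS or cols[hi - 1][1] in GAP_CHARS):
            hi -= 1
        cols = cols[lo:hi]
    diffs = 0
    length = 0
    run: str | None = None  # which sequence the current gap run belongs to
    for x, y in cols:
        if x in GAP_CHARS or y in GAP_CHARS:
            which = "a" if x in GAP_CHARS else "b"
            if params.gap_mode == "each_gap_column" or run != which:
                diffs += 1
                length += 1
            run = which
        else:
            run = None
            length += 1
            if x != y:
                diffs += 1
    if length == 0:
        raise ValueError("zero compared length between aligned pair")
    return diffs / length


def hamming_distance(a: str, b: str) -> float:
    """Proportion of mismatching positions between equal-length gap-free seqs."""
    if len(a) != len(b):
        raise ValueError("hamming_distance requires equal-length sequences")
    if not a:
        raise ValueError("empty sequences")
    return sum(x != y for x, y in zip(a, b)) / len(a)


def nw_distance(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Align two gap-free sequences and return their pair distance."""
    if a == b:
        return 0.0
    aa, bb, _ = nw_align(a, b, params)
    return pair_distance(aa, bb, params)


class DistanceMatrix:
    """Sparse symmetric matrix of pairwise distances between sequence ids.

    Pairs with distance above ``storage_cutoff`` are not stored;
    :meth:`get` returns ``None`` for them, which downstream code interprets
    as "definitely farther than any working threshold".
    """

    def __init__(self, ids: Sequence[str], storage_cutoff: float = 0.10) -> None:
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in distance matrix")
        if not 0 < storage_cutoff <= 1:
            raise ValueError("storage_cutoff must be in (0, 1]")
        self.storage_cutoff = float(storage_cutoff)
        self._index = {sid: i for i, sid in enumerate(self.ids)}
        self._d: dict[tuple[int, int], float] = {}

    @property
    def n(self) -> int:
        return len(self.ids)

    def __contains__(self, sid: str) -> bool:
        return sid in self._index

    def _key(self, a: str, b: str) -> tuple[int, int]:
        i, j = self._index[a], self._index[b]
        return (i, j) if i < j else (j, i)

    def set(self, a: str, b: str, d: float) -> None:
        if a == b:
            raise ValueError("self-pairs are not stored")
        if not 0 <= d <= 1:
            raise ValueError(f"distance {d} outside [0, 1]")
        if d <= self.storage_cutoff:
            self._d[self._key(a, b)] = float(d)

    def get(self, a: str, b: str) -> float | None:
        """Stored distance, 0.0 for a self-pair, or None if above cutoff."""
        if a == b:
            if a not in self._index:
                raise KeyError(a)
            return 0.0
        return self._d.get(self._key(a, b))

    def items(self) -> Iterator[tuple[str, str, float]]:
        for (i, j), d in self._d.items():
            yield self.ids[i], self.ids[j], d

    def n_stored(self) -> int:
        return len(self._d)


def _extract_id_seqs(
    seqs: DereplicatedSet | Sequence[SequenceRecord],
) -> list[tuple[str, str]]:
    if isinstance(seqs, DereplicatedSet):
        return [(u.id, u.seq) for u in seqs.units]
    return [(r.id, r.seq) for r in seqs]


def distance_matrix(
    seqs: DereplicatedSet | Sequence[SequenceRecord],
    mode: str = "pairwise_nw",
    params: AlignmentParams = DEFAULT_PARAMS,
    storage_cutoff: float = 0.10,
) -> DistanceMatrix:
    """Compute all pairwise distances, storing only those <= storage_cutoff.

    ``pairwise_nw`` aligns each (degapped) pair globally; ``from_alignment``
    compares the stored aligned strings column-wise and requires uniform
    length.  Gap-free uniform-length inputs take a vectorized Hamming path
    (identical result by construction).
    """
    pairs = _extract_id_seqs(seqs)
    ids = [sid for sid, _ in pairs]
    dm = DistanceMatrix(ids, storage_cutoff)
    if len(pairs) < 2:
        return dm

    if mode == "from_alignment":
        lengths = {len(s) for _, s in pairs}
        if len(lengths) != 1:
            raise ValueError("from_alignment mode requires uniform aligned length")
        gap_free = not any(set(s) & GAP_CHARS for _, s in pairs)
        if gap_free:
            arr = np.frombuffer(
                "".join(s for _, s in pairs).encode(), dtype=np.uint8
            ).reshape(len(pairs), -1)
            L = arr.shape[1]
            for i in range(len(pairs) - 1):
                d = (arr[i] != arr[i + 1 :]).sum(axis=1) / L
                for off in np.nonzero(d <= storage_cutoff)[0]:
                    dm.set(ids[i], ids[i + 1 + off], float(d[off]))
            return dm
        for (ia, sa), (ib, sb) in itertools.combinations(pairs, 2):
            dm.set(ia, ib, pair_distance(sa, sb, params))
        return dm

    if mode == "pairwise_nw":
        degapped = [(sid, degap(s)) for sid, s in pairs]
        for (ia, sa), (ib, sb) in itertools.combinations(degapped, 2):
            dm.set(ia, ib, nw_distance(sa, sb, params))
        return dm

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------


def write_column_format(dm: DistanceMatrix, path: str | Path) -> None:
    """Write stored pairs as mothur column format: ``idA idB dist``."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, d in sorted(dm.items()):
            fh.write(f"{a}\t{b}\t{d:.6f}\n")


def read_column_format(
    path: str | Path, ids: Sequence[str] | None = None, storage_cutoff: float = 0.10
) -> DistanceMatrix:
    """Read mothur column format; ids default to those seen in the file."""
    rows: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'idA idB dist'")
            rows.append((parts[0], parts[1], float(parts[2])))
    if ids is None:
        seen: dict[str, None] = {}
        for a, b, _ in rows:
            seen.setdefault(a)
            seen.setdefault(b)
        ids = list(seen)
    dm = DistanceMatrix(ids, storage_cutoff)
    for a, b, d in rows:
        dm.set(a, b, d)
    return dm


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP matrix; unstored pairs print the cutoff value."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{dm.n}\n")
        for a in dm.ids:
            vals = []
            for b in dm.ids:
                d = dm.get(a, b)
                vals.append(dm.storage_cutoff if d is None else d)
            fh.write(a + "\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")


def read_phylip(path: str | Path, storage_cutoff: float = 0.10) -> DistanceMatrix:
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty PHYLIP file")
    n = int(lines[0].split()[0])
    if len(lines) != n + 1:
        raise ValueError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    ids = []
    rows = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(f"{path}: malformed PHYLIP row {parts[0]!r}")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    dm = DistanceMatrix(ids, storage_cutoff)
    for i in range(n):
        for j in range(i + 1, n):
            dm.set(ids[i], ids[j], rows[i][j])
    return dm
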