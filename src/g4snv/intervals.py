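"""Native genomic-interval arithmetic and BED I/O.

All coordinates are 0-based, half-open (BED dialect). Single-nucleotide
variants are represented as length-1 intervals. The operations here mirror
the classic interval toolbox (nearest feature, overlap counting, window
tiling, random placement) but return *signed* nearest distances so that
upstream (5', lower coordinate) neighbours can be told apart from
downstream ones.

Sign convention for nearest distances, relative to reference-genome
orientation: 0 when query and reference overlap (or are book-ended),
negative when the query lies left (5') of the reference, positive when it
lies right (3'). The magnitude is the gap in bp between the closest edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "sort_intervals",
    "closest_distance",
    "intersect_count",
    "make_windows",
    "random_intervals",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """Ordered collection of :class:`GenomicInterval` with cached per-chromosome arrays."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), sorted_flag: bool = False):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.sorted_flag = sorted_flag
        self._by_chrom: dict[str, dict[str, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def _chrom_arrays(self) -> dict[str, dict[str, np.ndarray]]:
        """Per-chromosome start/end arrays plus original indices, start-sorted."""
        if self._by_chrom is None:
            groups: dict[str, list[int]] = {}
            for i, iv in enumerate(self.intervals):
                groups.setdefault(iv.chrom, []).append(i)
            out: dict[str, dict[str, np.ndarray]] = {}
            for chrom, idx in groups.items():
                idx_a = np.asarray(idx, dtype=np.int64)
                starts = np.array([self.intervals[i].start for i in idx], dtype=np.int64)
                ends = np.array([self.intervals[i].end for i in idx], dtype=np.int64)
                order = np.lexsort((ends, starts))
                out[chrom] = {
                    "idx": idx_a[order],
                    "starts": starts[order],
                    "ends": ends[order],
                }
            self._by_chrom = out
        return self._by_chrom


class BedParseError(ValueError):
    pass


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3+ into an :class:`IntervalSet`.

    Strand is taken from column 6 when present; `track`/`browser`/comment
    lines are skipped. Malformed coordinates raise :class:`BedParseError`
    naming the offending line.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            label = fields[3] if len(fields) >= 4 and fields[3] != "." else None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand, label))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(interval_set: IntervalSet, path: str | Path) -> None:
    """Write BED; emits 6 columns when any interval carries strand or label."""
    six = any(iv.strand != "." or iv.label is not None for iv in interval_set)
    with open(path, "w") as fh:
        for iv in interval_set:
            if six:
                name = iv.label if iv.label is not None else "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def sort_intervals(interval_set: IntervalSet) -> IntervalSet:
    """Stable sort by (chrom, start, end); chromosomes ordered lexicographically."""
    ordered = sorted(interval_set, key=lambda iv: (iv.chrom, iv.start, iv.end))
    return IntervalSet(ordered, sorted_flag=True)


@dataclass(frozen=True)
class SignedDistance:
    """Signed bp gap from a query to its nearest reference (0 on overlap)."""

    value: int
    ref_index: int  # index into the reference IntervalSet, -1 when no neighbour
    ref_label: str | None = None

    @property
    def has_neighbor(self) -> bool:
        return self.ref_index >= 0


def closest_distance(
    queries: IntervalSet,
    references: IntervalSet,
    strand_aware: bool = False,
) -> list[SignedDistance]:
    """Signed distance from each query to the nearest reference on its chromosome.

    Distance is 0 on any overlap; otherwise the gap between closest edges,
    negative when the query lies 5' of the reference. Ties (equal gap left
    and right, or several overlapping references) break toward the leftmost
    reference. Queries on chromosomes with no reference come back with
    ``ref_index == -1``.

    With ``strand_aware`` the sign is flipped for references on the '-'
    strand, so "downstream" means downstream of the *feature* rather than
    of the reference genome.
    """
    if len(references) == 0:
        raise ValueError("reference set is empty")
    ref_arrays = references._chrom_arrays()
    out: list[SignedDistance | None] = [None] * len(queries)

    q_groups: dict[str, list[int]] = {}
    for i, iv in enumerate(queries):
        q_groups.setdefault(iv.chrom, []).append(i)

    for chrom, q_idx in q_groups.items():
        if chrom not in ref_arrays:
            for i in q_idx:
                out[i] = SignedDistance(0, -1, None)
            continue
        arr = ref_arrays[chrom]
        starts, ends, ridx = arr["starts"], arr["ends"], arr["idx"]
        cummax_end = np.maximum.accumulate(ends)
        # end-sorted view for the nearest-left-edge candidate; within equal
        # ends keep the leftmost (smallest start) reachable via rightmost
        # position of the (end, -start) ordering
        end_order = np.lexsort((-starts, ends))
        ends_sorted = ends[end_order]

        qs = np.array([queries[i].start for i in q_idx], dtype=np.int64)
        qe = np.array([queries[i].end for i in q_idx], dtype=np.int64)

        # overlap: exists ref with start < qe and end > qs.
        j = np.searchsorted(starts, qe, side="left")  # refs [0, j) start before qe
        # leftmost overlapping ref: first position where cummax_end > qs
        first_over = np.searchsorted(cummax_end, qs, side="right")
        has_overlap = (j > 0) & (first_over < j)

        # left candidate: reference with greatest end <= qs
        kl = np.searchsorted(ends_sorted, qs, side="right") - 1
        has_left = kl >= 0
        left_gap = np.where(has_left, qs - ends_sorted[np.clip(kl, 0, None)], np.iinfo(np.int64).max)
        # right candidate: reference with smallest start >= qe (leftmost in start order)
        kr = np.searchsorted(starts, qe, side="left")
        has_right = kr < len(starts)
        right_gap = np.where(
            has_right, starts[np.clip(kr, None, len(starts) - 1)] - qe, np.iinfo(np.int64).max
        )

        for k, i in enumerate(q_idx):
            if has_overlap[k]:
                r = int(ridx[first_over[k]])
                out[i] = SignedDistance(0, r, references[r].label)
                continue
            lg = int(left_gap[k]) if has_left[k] else None
            rg = int(right_gap[k]) if has_right[k] else None
            if lg is None and rg is None:  # pragma: no cover - chrom handled above
                out[i] = SignedDistance(0, -1, None)
                continue
            # prefer the smaller gap; on a tie the left reference is the
            # leftmost of the two candidates
            if rg is None or (lg is not None and lg <= rg):
                # nearest reference lies left of the query: query is 3' -> positive
                r = int(ridx[end_order[kl[k]]])
                value = lg
            else:
                # nearest reference lies right of the query: query is 5' -> negative
                r = int(ridx[kr[k]])
                value = -rg
            if strand_aware and references[r].strand == "-":
                value = -value
            out[i] = SignedDistance(value, r, references[r].label)
    return [d for d in out]  # type: ignore[misc]


def intersect_count(queries: IntervalSet, references: IntervalSet) -> np.ndarray:
    """Number of references overlapping each query (half-open semantics)."""
    ref_arrays = references._chrom_arrays()
    counts = np.zeros(len(queries), dtype=np.int64)
    q_groups: dict[str, list[int]] = {}
    for i, iv in enumerate(queries):
        q_groups.setdefault(iv.chrom, []).append(i)
    for chrom, q_idx in q_groups.items():
        if chrom not in ref_arrays:
            continue
        arr = ref_arrays[chrom]
        starts = arr["starts"]
        ends_sorted = np.sort(arr["ends"])
        qs = np.array([queries[i].start for i in q_idx], dtype=np.int64)
        qe = np.array([queries[i].end for i in q_idx], dtype=np.int64)
        n_start_before = np.searchsorted(starts, qe, side="left")
        n_end_before = np.searchsorted(ends_sorted, qs, side="right")
        counts[np.asarray(q_idx)] = n_start_before - n_end_before
    return counts


def make_windows(regions: IntervalSet, size: int, step: int | None = None) -> IntervalSet:
    """Tile regions into windows.

    Fixed-end mode (``step is None``): consecutive non-overlapping tiles of
    ``size`` bp, with a truncated final tile when the region length is not a
    multiple of ``size``. Sliding mode: a window every ``step`` bp, each of
    length ``size`` truncated at the region end.
    """
    if size <= 0:
        raise ValueError("window size must be > 0")
    if step is not None and step <= 0:
        raise ValueError("step must be > 0")
    eff_step = size if step is None else step
    windows: list[GenomicInterval] = []
    for region in regions:
        for s in range(region.start, region.end, eff_step):
            e = min(s + size, region.end)
            windows.append(GenomicInterval(region.chrom, s, e, label=region.label))
    return IntervalSet(windows)


def random_intervals(
    mask: IntervalSet,
    length: int,
    n: int,
    seed: int | np.random.Generator,
) -> IntervalSet:
    """Place ``n`` intervals of exactly ``length`` bp uniformly within a mask.

    Each mask interval is weighted by its number of valid start positions
    (``len - length + 1``); intervals shorter than ``length`` contribute
    none. Deterministic under ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    usable = [iv for iv in mask if len(iv) >= length]
    if not usable:
        raise ValueError(f"mask has no interval of at least {length} bp")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_starts = np.array([len(iv) - length + 1 for iv in usable], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(n_starts)])
    total = int(cum[-1])
    draws = rng.integers(0, total, size=n)
    which = np.searchsorted(cum, draws, side="right") - 1
    offsets = draws - cum[which]
    out = [
        GenomicInterval(
            usable[w].chrom,
            usable[w].start + int(off),
            usable[w].start + int(off) + length,
        )
        for w, off in zip(which, offsets)
    ]
    return IntervalSet(out)


def write_distances_tsv(
    queries: IntervalSet,
    distances: Sequence[SignedDistance],
    path: str | Path,
) -> None:
    """Write per-query signed nearest distances as TSV."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\tref_label\tsigned_distance\n")
        for q, d in zip(queries, distances):
            ref = d.ref_label if d.has_neighbor and d.ref_label is not None else "."
            value = d.value if d.has_neighbor else "NA"
            fh.write(f"{q.chrom}\t{q.start}\t{q.end}\t{q.label or '.'}\t{ref}\t{value}\n")


def merge_intervals(interval_set: IntervalSet) -> IntervalSet:
    """Union of intervals: overlapping or book-ended spans are fused."""
    merged: list[GenomicInterval] = []
    for iv in sort_intervals(interval_set):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged, sorted_flag=True)


def intersect_pieces(
    queries: IntervalSet, references: IntervalSet
) -> list[tuple[int, GenomicInterval]]:
    """Clip references against queries; yields (query index, clipped piece)."""
    ref_arrays = references._chrom_arrays()
    pieces: list[tuple[int, GenomicInterval]] = []
    for i, q in enumerate(queries.intervals):
        arr = ref_arrays.get(q.chrom)
        if arr is None:
            continue
        starts, ends = arr["starts"], arr["ends"]
        # candidate refs: start < q.end; check overlap individually (rare
        # long-interval containment is caught because ends are not assumed
        # sorted -- scan the candidate prefix lazily via cummax)
        j = int(np.searchsorted(starts, q.end, side="left"))
        if j == 0:
            continue
        sel = ends[:j] > q.start
        for s, e in zip(starts[:j][sel], ends[:j][sel]):
            pieces.append((i, GenomicInterval(q.chrom, max(int(s), q.start), min(int(e), q.end))))
    return pieces
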