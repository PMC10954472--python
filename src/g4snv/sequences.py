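"""FASTA access, per-interval GC counting and consensus PQS scanning.

The potential-quadruplex-sequence (PQS) scanner implements the classic
intramolecular G4 consensus G(x)N(y)G(x)N(y)G(x)N(y)G(x): four runs of at
least ``min_g_run`` guanines separated by three loops of ``min_loop`` to
``max_loop`` nucleotides. Scanning is greedy left-to-right and reports
maximal non-overlapping matches; the reverse strand is scanned on the
reverse complement and mapped back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .intervals import GenomicInterval, IntervalSet, sort_intervals

__all__ = [
    "SequenceRecord",
    "PqsMotifParams",
    "read_fasta",
    "write_fasta",
    "gc_count",
    "gc_fraction",
    "scan_pqs",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named uppercase DNA sequence over {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {self.name!r} contains invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PqsMotifParams:
    """Consensus-motif parameters: G-run length x >= 3 and loop range 1..7 by default."""

    min_g_run: int = 3
    min_loop: int = 1
    max_loop: int = 7

    def __post_init__(self) -> None:
        if self.min_g_run < 2:
            raise ValueError("min_g_run must be >= 2")
        if not (1 <= self.min_loop <= self.max_loop):
            raise ValueError("require 1 <= min_loop <= max_loop")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA into uppercase :class:`SequenceRecord` entries."""
    try:
        records = [
            SequenceRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_count(record: SequenceRecord, interval: GenomicInterval) -> int:
    """Number of G or C bases in ``[start, end)``; N contributes nothing."""
    if interval.chrom != record.name:
        raise ValueError(f"interval chrom {interval.chrom!r} != record {record.name!r}")
    if interval.end > len(record.sequence):
        raise ValueError(
            f"interval {interval.start}-{interval.end} outside sequence of length {len(record)}"
        )
    sub = record.sequence[interval.start : interval.end]
    return sub.count("G") + sub.count("C")


def gc_fraction(record: SequenceRecord, interval: GenomicInterval) -> float:
    return gc_count(record, interval) / len(interval)


def _motif_pattern(params: PqsMotifParams, allow_n_in_loops: bool) -> re.Pattern[str]:
    loop_alphabet = "[ACGTN]" if allow_n_in_loops else "[ACGT]"
    g = params.min_g_run
    loop = f"{loop_alphabet}{{{params.min_loop},{params.max_loop}}}"
    # greedy runs and loops: leftmost match, preferring longer spans, the
    # convention of the classic quadparser-style scanners
    return re.compile(f"G{{{g},}}(?:{loop}G{{{g},}}){{3}}")


def scan_pqs(
    record: SequenceRecord,
    params: PqsMotifParams = PqsMotifParams(),
    both_strands: bool = False,
    allow_overlaps: bool = False,
    allow_n_in_loops: bool = False,
) -> IntervalSet:
    """Scan a sequence for consensus PQS motifs.

    Returns BED-style intervals on the record's coordinate system, strand
    '+' for direct matches and '-' for matches found on the reverse
    complement. By default matches are maximal, non-overlapping (scanning
    resumes after each match) and may not contain N anywhere.
    """
    pattern = _motif_pattern(params, allow_n_in_loops)
    hits: list[GenomicInterval] = []
    n = len(record.sequence)

    def collect(seq: str, strand: str) -> None:
        pos = 0
        while True:
            m = pattern.search(seq, pos)
            if m is None:
                break
            s, e = m.span()
            if strand == "+":
                hits.append(GenomicInterval(record.name, s, e, "+", label=f"pqs_{len(hits)}"))
            else:
                hits.append(
                    GenomicInterval(record.name, n - e, n - s, "-", label=f"pqs_{len(hits)}")
                )
            pos = s + 1 if allow_overlaps else e

    collect(record.sequence, "+")
    if both_strands:
        collect(reverse_complement(record.sequence), "-")
    return sort_intervals(IntervalSet(hits))
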