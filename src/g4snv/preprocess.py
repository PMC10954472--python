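"""Cohort-cleaning rules applied before any density statistic.

Three filters are applied to the somatic cohort and the window set:

* germline removal -- somatic SNVs whose (chrom, pos) coincides with a
  common-variant position are discarded;
* cancer-type exclusion -- cancer types with fewer than ``min_samples``
  distinct patients are dropped entirely;
* window capping -- genomic windows with more than ``max_g4`` G4s are
  removed (too few such windows for stable statistics).

Each filter returns the retained table together with a conserved-count
report so no record is silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    make_windows,
    merge_intervals,
    sort_intervals,
)

__all__ = [
    "CohortFilterReport",
    "filter_germline",
    "filter_cancer_types",
    "cap_window_g4",
    "restrict_windows_to_genes",
    "read_snv_table",
    "write_snv_table",
]

SNV_COLUMNS = ["chrom", "pos", "patient_id", "cancer_type", "tissue"]


@dataclass
class CohortFilterReport:
    """Partition of the input cohort: input = germline-removed + type-excluded + retained."""

    n_input: int
    n_germline_removed: int = 0
    n_type_excluded: int = 0
    excluded_types: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_germline_removed - self.n_type_excluded

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_germline_removed": self.n_germline_removed,
            "n_type_excluded": self.n_type_excluded,
            "n_retained": self.n_retained,
            "excluded_types": list(self.excluded_types),
        }


def read_snv_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    missing = [c for c in SNV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNV table {path} lacks columns {missing}")
    if (df["pos"] < 0).any():
        raise ValueError(f"SNV table {path} has negative positions")
    return df


def write_snv_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SNV_COLUMNS)


def filter_germline(
    csnvs: pd.DataFrame, dbsnvs: pd.DataFrame
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Drop somatic SNVs coinciding with any common-variant (chrom, pos)."""
    germline = set(zip(dbsnvs["chrom"], dbsnvs["pos"]))
    mask = np.fromiter(
        ((c, p) not in germline for c, p in zip(csnvs["chrom"], csnvs["pos"])),
        dtype=bool,
        count=len(csnvs),
    )
    retained = csnvs[mask].reset_index(drop=True)
    report = CohortFilterReport(
        n_input=len(csnvs), n_germline_removed=int((~mask).sum())
    )
    return retained, report


def filter_cancer_types(
    csnvs: pd.DataFrame,
    patients: pd.DataFrame,
    min_samples: int = 10,
) -> tuple[pd.DataFrame, CohortFilterReport]:
    """Drop cancer types with fewer than ``min_samples`` distinct patients.

    The boundary is strict: a type with exactly ``min_samples`` patients is
    retained. Somatic records whose patient is absent from the patient
    table are an error.
    """
    known = set(patients["patient_id"])
    orphans = sorted(set(csnvs["patient_id"]) - known)
    if orphans:
        raise ValueError(f"cSNV patients missing from patient table: {orphans[:10]}")
    counts = patients.groupby("cancer_type")["patient_id"].nunique()
    small = sorted(counts[counts < min_samples].index.tolist())
    mask = ~csnvs["cancer_type"].isin(small)
    retained = csnvs[mask].reset_index(drop=True)
    report = CohortFilterReport(
        n_input=len(csnvs),
        n_type_excluded=int((~mask).sum()),
        excluded_types=small,
    )
    return retained, report


def cap_window_g4(window_table: pd.DataFrame, max_g4: int = 15) -> pd.DataFrame:
    """Remove windows carrying more than ``max_g4`` G4s (strictly more)."""
    return window_table[window_table["g4_count"] <= max_g4].reset_index(drop=True)


def restrict_windows_to_genes(
    genes: IntervalSet,
    exons: IntervalSet,
    size: int,
    step: int | None = None,
    flank: int = 2000,
) -> IntervalSet:
    """Tile windows over genes plus flanks, keeping only exon-informative ones.

    Windows are tiled (fixed-end or sliding) over the union of genes
    extended by ``flank`` bp on both sides (clipped at 0), so overlapping
    flanks never yield overlapping fixed-end windows. Each window is
    labelled with the gene it overlaps most (for gene-class annotation). A
    window is discarded when the gap between consecutive exons overlapping
    it exceeds the window size, or when it overlaps no exon at all -- such
    windows cannot contribute exonic counts.
    """
    regions = merge_intervals(
        IntervalSet(
            [
                GenomicInterval(g.chrom, max(0, g.start - flank), g.end + flank)
                for g in genes
            ]
        )
    )
    tiled = make_windows(regions, size, step)

    gene_by_chrom: dict[str, list[GenomicInterval]] = {}
    for g in sort_intervals(genes):
        gene_by_chrom.setdefault(g.chrom, []).append(g)

    def best_gene_label(window: GenomicInterval) -> str | None:
        best, best_ov = None, 0
        for g in gene_by_chrom.get(window.chrom, []):
            ov = min(window.end, g.end) - max(window.start, g.start)
            if ov > best_ov:
                best, best_ov = g.label, ov
        return best

    windows = IntervalSet(
        [
            GenomicInterval(w.chrom, w.start, w.end, label=best_gene_label(w))
            for w in tiled
        ]
    )

    exon_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in sort_intervals(exons):
        exon_by_chrom.setdefault(iv.chrom, []).append(iv)

    keep: list[GenomicInterval] = []
    for window in windows:
        candidates = exon_by_chrom.get(window.chrom, [])
        overlapping = [
            e for e in candidates if e.start < window.end and e.end > window.start
        ]
        if not overlapping:
            continue
        gaps_ok = all(
            nxt.start - prev.end <= size
            for prev, nxt in zip(overlapping, overlapping[1:])
        )
        if gaps_ok:
            keep.append(window)
    return sort_intervals(IntervalSet(keep))
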