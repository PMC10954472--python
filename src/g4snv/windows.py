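"""Per-window feature counting and G4-stratified enrichment statistics.

The central object is the *window table*, a DataFrame with one row per
genomic window and columns::

    chrom, start, end, g4_count, csnv_count, dbsnv_count, gc_bp, gene_class

Only features inside exonic sequence within each window are counted.
Downstream statistics stratify windows by their G4 content (zero / non-zero
/ ten-or-more, or per exact count), compare SNV loads across strata with
Welch's t and a presence/absence chi-squared test, normalize G4 content to
the window's GC base count, and estimate the G4-cSNV partial correlation
controlling for GC fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    GenomicInterval,
    IntervalSet,
    intersect_count,
    intersect_pieces,
    merge_intervals,
)
from .sequences import SequenceRecord, gc_count
from .spatial import snv_intervals, window_pearson

__all__ = [
    "WINDOW_COLUMNS",
    "EnrichmentResult",
    "PartialCorrelation",
    "count_features",
    "stratify_enrichment",
    "gc_normalized_counts",
    "partial_correlation",
    "gene_exon_analysis",
    "gene_class_comparison",
]

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "g4_count",
    "csnv_count",
    "dbsnv_count",
    "gc_bp",
    "gene_class",
]


@dataclass
class EnrichmentResult:
    """Summary of one G4 stratum and (optionally) its test against the 0-G4 stratum."""

    group: str
    n_windows: int
    mean: float
    median: float
    statistic: float | None = None
    p_value: float | None = None
    test: str | None = None

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "n_windows": self.n_windows,
            "mean": self.mean,
            "median": self.median,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "test": self.test,
        }


@dataclass
class PartialCorrelation:
    """First-order partial correlation r(x, y | z) with its pairwise inputs."""

    r_xy: float
    r_xz: float
    r_yz: float
    r_xy_given_z: float
    p_value: float
    n: int


def _count_in_pieces(
    windows: IntervalSet,
    pieces_by_window: dict[int, list[GenomicInterval]],
    features: IntervalSet,
) -> np.ndarray:
    """Count features overlapping each window's exonic pieces."""
    flat: list[GenomicInterval] = []
    owner: list[int] = []
    for wi, plist in pieces_by_window.items():
        for piece in plist:
            flat.append(piece)
            owner.append(wi)
    counts = np.zeros(len(windows), dtype=np.int64)
    if not flat or len(features) == 0:
        return counts
    piece_counts = intersect_count(IntervalSet(flat), features)
    for wi, c in zip(owner, piece_counts):
        counts[wi] += c
    return counts


def count_features(
    windows: IntervalSet,
    g4s: IntervalSet,
    csnvs: pd.DataFrame | None,
    dbsnvs: pd.DataFrame | None,
    exons: IntervalSet,
    genome: dict[str, SequenceRecord] | None = None,
    gene_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the window table: exonic feature counts plus GC content per window.

    A feature is counted for a window when it overlaps the intersection of
    the window with exonic sequence; G4s or SNVs in intronic or intergenic
    sequence never count. ``gc_bp`` is the G+C base count of the whole
    window (0 when no genome is supplied). ``gene_class`` is taken from the
    window's region label when a gene-class map is given.
    """
    if genome is not None:
        for w in windows:
            if w.chrom not in genome:
                raise ValueError(f"window chromosome {w.chrom!r} absent from genome")
            if w.end > len(genome[w.chrom].sequence):
                raise ValueError(
                    f"window {w.chrom}:{w.start}-{w.end} outside genome sequence"
                )
    # exon union: overlapping exon annotations must not double-count
    pieces_by_window: dict[int, list[GenomicInterval]] = {}
    for wi, piece in intersect_pieces(windows, merge_intervals(exons)):
        pieces_by_window.setdefault(wi, []).append(piece)

    g4_counts = _count_in_pieces(windows, pieces_by_window, g4s)
    csnv_counts = (
        _count_in_pieces(windows, pieces_by_window, snv_intervals(csnvs))
        if csnvs is not None and len(csnvs)
        else np.zeros(len(windows), dtype=np.int64)
    )
    dbsnv_counts = (
        _count_in_pieces(windows, pieces_by_window, snv_intervals(dbsnvs))
        if dbsnvs is not None and len(dbsnvs)
        else np.zeros(len(windows), dtype=np.int64)
    )
    gc = np.zeros(len(windows), dtype=np.int64)
    if genome is not None:
        for wi, w in enumerate(windows):
            gc[wi] = gc_count(genome[w.chrom], w)
    classes = [
        (gene_classes or {}).get(w.label, "none") if w.label else "none" for w in windows
    ]
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "g4_count": g4_counts,
            "csnv_count": csnv_counts,
            "dbsnv_count": dbsnv_counts,
            "gc_bp": gc,
            "gene_class": classes,
        }
    )


def _strata(table: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "0": table.loc[table["g4_count"] == 0],
        "1+": table.loc[table["g4_count"] >= 1],
        "10+": table.loc[table["g4_count"] >= 10],
    }


def stratify_enrichment(
    table: pd.DataFrame,
    snv_kind: str = "cSNV",
    grouping: str = "three_group",
    test: str = "welch_t",
) -> list[EnrichmentResult]:
    """Mean/median SNV load per G4 stratum with tests against the 0-G4 group.

    ``three_group`` uses the strata {0, 1+, 10+} (1+ contains 10+);
    ``per_count`` summarises every exact G4 count without tests. The
    primary test is Welch's two-sample t (``test="student_t"`` switches to
    the pooled-variance variant); a chi-squared contingency test on SNV
    presence/absence is reported alongside.
    """
    if table.empty:
        raise ValueError("empty window table")
    col = "csnv_count" if snv_kind == "cSNV" else "dbsnv_count"
    results: list[EnrichmentResult] = []
    if grouping == "per_count":
        for c, grp in table.groupby("g4_count"):
            v = grp[col]
            results.append(
                EnrichmentResult(str(int(c)), len(v), float(v.mean()), float(v.median()))
            )
        return results
    if grouping != "three_group":
        raise ValueError(f"unknown grouping {grouping!r}")
    strata = _strata(table)
    zero = strata["0"][col].to_numpy()
    for name, grp in strata.items():
        v = grp[col].to_numpy()
        if len(v) == 0:
            warnings.warn(f"stratum {name} is empty; comparison skipped")
            continue
        res = EnrichmentResult(name, len(v), float(v.mean()), float(np.median(v)))
        if name != "0" and len(zero) > 1 and len(v) > 1:
            t_stat, t_p = stats.ttest_ind(zero, v, equal_var=(test == "student_t"))
            res.statistic, res.p_value = float(t_stat), float(t_p)
            res.test = "student_t" if test == "student_t" else "welch_t"
        results.append(res)
        if name != "0" and len(zero) and len(v):
            contingency = np.array(
                [
                    [(zero > 0).sum(), (zero == 0).sum()],
                    [(v > 0).sum(), (v == 0).sum()],
                ]
            )
            if (contingency.sum(axis=1) > 0).all() and (contingency.sum(axis=0) > 0).all():
                chi2, chi_p, _, _ = stats.chi2_contingency(contingency)
                results.append(
                    EnrichmentResult(
                        f"{name}_presence",
                        int(contingency[1].sum()),
                        float(v.mean()),
                        float(np.median(v)),
                        statistic=float(chi2),
                        p_value=float(chi_p),
                        test="chi_squared",
                    )
                )
    return results


def gc_normalized_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``g4_per_gc`` = g4_count / gc_bp; zero-GC windows are flagged NaN."""
    out = table.copy()
    gc = out["gc_bp"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(gc > 0, out["g4_count"].to_numpy(dtype=float) / gc, np.nan)
    out["g4_per_gc"] = rate
    out["gc_flagged"] = gc <= 0
    return out


def partial_correlation(x, y, z) -> PartialCorrelation:
    """First-order partial correlation of x and y controlling for z.

    Uses the closed form
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))`` with a
    two-sided p-value from the t transform on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise ValueError("need three equal-length vectors with n >= 4")
    for name, v in (("x", x), ("y", y), ("z", z)):
        if np.std(v) == 0:
            raise ValueError(f"zero variance in {name}")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("control variable is collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r_xy, r_xz, r_yz, r, p, n)


def gene_exon_analysis(
    exons: IntervalSet,
    g4s: IntervalSet,
    csnvs: pd.DataFrame,
) -> tuple[pd.DataFrame, float | None]:
    """Per-exon cSNV density versus G4 count within one gene.

    Returns the per-exon table (csnv_count, csnv_per_bp, g4_count) and
    Pearson's r of csnv_per_bp against g4_count across exons (None when
    fewer than 3 exons or a zero-variance side makes r undefined).
    """
    snvs = snv_intervals(csnvs) if len(csnvs) else IntervalSet()
    csnv_counts = (
        intersect_count(exons, snvs) if len(snvs) else np.zeros(len(exons), dtype=int)
    )
    g4_counts = (
        intersect_count(exons, g4s) if len(g4s) else np.zeros(len(exons), dtype=int)
    )
    lengths = np.array([len(e) for e in exons], dtype=float)
    table = pd.DataFrame(
        {
            "exon": [e.label or f"exon_{i}" for i, e in enumerate(exons)],
            "chrom": [e.chrom for e in exons],
            "start": [e.start for e in exons],
            "end": [e.end for e in exons],
            "length_bp": lengths.astype(int),
            "csnv_count": csnv_counts,
            "csnv_per_bp": csnv_counts / lengths,
            "g4_count": g4_counts,
        }
    )
    r: float | None = None
    if len(exons) >= 3:
        try:
            r, _ = window_pearson(table["csnv_per_bp"], table["g4_count"])
        except ValueError:
            r = None
    return table, r


def gene_class_comparison(
    table: pd.DataFrame,
    snv_kind: str = "cSNV",
    genes: pd.DataFrame | None = None,
) -> dict:
    """Compare SNV loads across {0, 10+} G4 strata within each gene class.

    For every gene class present in the window table: per-stratum mean and
    median SNV counts plus Welch-t and presence/absence chi-squared between
    the strata. When a per-gene table (columns gene, gene_class, g4_count,
    length_bp) is given, per-class G4-content summaries (raw and per kbp)
    are included.
    """
    col = "csnv_count" if snv_kind == "cSNV" else "dbsnv_count"
    out: dict = {"classes": {}, "gene_g4_content": {}}
    for cls, grp in table.groupby("gene_class"):
        if cls == "none":
            continue
        zero = grp.loc[grp["g4_count"] == 0, col].to_numpy()
        high = grp.loc[grp["g4_count"] >= 10, col].to_numpy()
        entry: dict = {
            "n_windows": int(len(grp)),
            "stratum_0": {
                "n": int(len(zero)),
                "mean": float(zero.mean()) if len(zero) else None,
                "median": float(np.median(zero)) if len(zero) else None,
            },
            "stratum_10+": {
                "n": int(len(high)),
                "mean": float(high.mean()) if len(high) else None,
                "median": float(np.median(high)) if len(high) else None,
            },
        }
        if len(zero) > 1 and len(high) > 1:
            t_stat, t_p = stats.ttest_ind(zero, high, equal_var=False)
            entry["welch_t"] = {"statistic": float(t_stat), "p_value": float(t_p)}
            contingency = np.array(
                [
                    [(zero > 0).sum(), (zero == 0).sum()],
                    [(high > 0).sum(), (high == 0).sum()],
                ]
            )
            if (contingency.sum(axis=0) > 0).all():
                chi2, chi_p, _, _ = stats.chi2_contingency(contingency)
                entry["chi_squared"] = {"statistic": float(chi2), "p_value": float(chi_p)}
        else:
            warnings.warn(f"gene class {cls!r}: a stratum is too small, tests skipped")
        out["classes"][cls] = entry

    if genes is not None and len(genes):
        for cls, grp in genes.groupby("gene_class"):
            counts = grp["g4_count"].to_numpy(dtype=float)
            per_kbp = counts / (grp["length_bp"].to_numpy(dtype=float) / 1000.0)
            out["gene_g4_content"][cls] = {
                "n_genes": int(len(grp)),
                "median": float(np.median(counts)),
                "mean": float(counts.mean()),
                "median_per_kbp": float(np.median(per_kbp)),
                "mean_per_kbp": float(per_kbp.mean()),
            }
    return out
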