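"""Synthetic study generator with planted ground truth.

Generates a complete miniature study: a random genome with gene/exon
structure, an exonic G4 map, somatic (cSNV) and common (dbSNV) variant
cohorts with planted spatial structure, patient metadata, and survival
outcomes driven by a proportional-hazards model on the patient G4-average.

The planted structure mirrors the observables the downstream stages are
meant to recover:

* cSNVs carry a Gaussian positional offset downstream of G4s (default
  N(+227, 84) bp) while dbSNVs carry a broader upstream offset (default
  N(-1295, 433) bp); the two cohorts separate cleanly in distance profiles
  and the fitted sigma ratio is ~5.2, with the 95% mass of the somatic
  cohort strictly downstream and of the common cohort strictly upstream.
* window-level cSNV intensity follows a linear law in the window's G4
  count (default expected count = 2 + 3 * g4_count per 5 kb window),
  planted by weighting SNV placement by window intensity.
* survival times are exponential with hazard
  baseline_hazard * exp(cox_beta * G4-average).

Every generator is deterministic under the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, sort_intervals
from .sequences import SequenceRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_genome",
    "place_g4s",
    "place_snvs",
    "simulate_survival",
    "simulate_dataset",
    "simulate_window_table",
    "spatial_study_config",
]

SNV_COLUMNS = ["chrom", "pos", "patient_id", "cancer_type", "tissue"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults are the reference conditions."""

    # genome architecture
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    gc_fraction: float = 0.45
    n_genes: int = 40
    exons_per_gene: int = 5
    exon_length: int = 8_000
    intron_length: int = 500

    # G4 map; clustering mirrors the elevated G4 content of cancer genes
    # and populates the high-count (10+) window strata
    n_g4: int = 800
    g4_length_mean: int = 30
    g4_min_spacing: int = 0
    g4_edge_margin: int = 100
    g4_cluster_fraction: float = 0.5  # fraction of G4s directed to cancer genes
    cancer_gene_fraction: float = 0.2

    # SNV cohorts
    csnv_per_patient_mean: float = 10.0
    n_patients: int = 300
    n_cancer_types: int = 8
    cancer_type_skew: float = 0.0
    type_affinity_spread: float = 0.5  # per-type spread of the G4 association
    n_dbsnv: int = 30_000
    assoc_fraction: float = 0.7
    offset_mean_csnv: float = 227.0
    offset_sd_csnv: float = 84.0
    offset_mean_dbsnv: float = -1295.0
    offset_sd_dbsnv: float = 433.0

    # planted window-level linear law (per 5 kb window)
    linear_slope: float = 3.0
    linear_intercept: float = 2.0
    window_size: int = 5_000

    # survival
    cox_beta: float = 0.32
    baseline_hazard: float = 1e-3
    censor_rate: float = 0.3
    noncancer_death_rate: float = 0.05
    missing_survival_rate: float = 0.02

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "exons_per_gene", "exon_length",
                     "n_patients", "n_cancer_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValueError("assoc_fraction must be in [0, 1]")
        if self.offset_sd_csnv <= 0 or self.offset_sd_dbsnv <= 0:
            raise ValueError("offset standard deviations must be > 0")
        if self.n_g4 < 0:
            raise ValueError("n_g4 must be >= 0")

    def gene_span(self) -> int:
        return self.exons_per_gene * self.exon_length + (self.exons_per_gene - 1) * self.intron_length


def spatial_study_config(seed: int = 0) -> SyntheticConfig:
    """Geometry for clean distance-profile recovery.

    Single-exon genes and widely spaced G4s keep the planted Gaussian
    offsets unclipped and guarantee that the nearest G4 to each SNV is the
    one it was placed against (spacing 9 kb versus offset tails < 4 kb).
    """
    return SyntheticConfig(
        n_chroms=2,
        chrom_length=2_000_000,
        n_genes=40,
        exons_per_gene=1,
        exon_length=40_000,
        intron_length=0,
        n_g4=120,
        g4_min_spacing=9_000,
        g4_edge_margin=4_000,
        assoc_fraction=1.0,
        type_affinity_spread=0.0,
        n_patients=500,
        csnv_per_patient_mean=100.0,
        n_dbsnv=50_000,
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    """All artefacts of one synthetic study plus the planted truth record."""

    config: SyntheticConfig
    genome: list[SequenceRecord] = field(default_factory=list)
    genes: IntervalSet = field(default_factory=IntervalSet)
    exons: IntervalSet = field(default_factory=IntervalSet)
    gene_classes: dict[str, str] = field(default_factory=dict)
    g4s: IntervalSet = field(default_factory=IntervalSet)
    csnvs: pd.DataFrame | None = None
    dbsnvs: pd.DataFrame | None = None
    patients: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    def genome_by_name(self) -> dict[str, SequenceRecord]:
        return {rec.name: rec for rec in self.genome}


def _rng_for(config: SyntheticConfig, stage: str) -> np.random.Generator:
    """Independent, reproducible stream per generator stage."""
    stage_key = int.from_bytes(stage.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), stage_key]))


def simulate_genome(config: SyntheticConfig) -> SyntheticDataset:
    """Random genome with non-overlapping genes and tiled exons."""
    rng = _rng_for(config, "genome")
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")

    per_chrom = config.n_genes // config.n_chroms
    extra = config.n_genes - per_chrom * config.n_chroms
    span = config.gene_span()

    genome: list[SequenceRecord] = []
    genes: list[GenomicInterval] = []
    exons: list[GenomicInterval] = []
    for c in range(config.n_chroms):
        name = f"chr{c + 1}"
        seq = rng.choice(bases, size=config.chrom_length, p=probs).tobytes().decode()
        genome.append(SequenceRecord(name, seq))
        k = per_chrom + (1 if c < extra else 0)
        if k == 0:
            continue
        slot = config.chrom_length // k
        if span > slot:
            raise ValueError(
                f"{k} genes of span {span} bp do not fit a {config.chrom_length} bp chromosome"
            )
        for g in range(k):
            jitter = int(rng.integers(0, slot - span + 1))
            start = g * slot + jitter
            gid = f"gene_{len(genes)}"
            genes.append(GenomicInterval(name, start, start + span, label=gid))
            for e in range(config.exons_per_gene):
                es = start + e * (config.exon_length + config.intron_length)
                exons.append(
                    GenomicInterval(name, es, es + config.exon_length, label=f"{gid}_exon{e}")
                )

    rng_cls = _rng_for(config, "gene_class")
    n_cancer = int(round(config.cancer_gene_fraction * len(genes)))
    cancer_idx = set(rng_cls.choice(len(genes), size=n_cancer, replace=False).tolist())
    classes = {
        iv.label: ("cancer" if i in cancer_idx else "non-cancer") for i, iv in enumerate(genes)
    }

    ds = SyntheticDataset(
        config=config,
        genome=genome,
        genes=sort_intervals(IntervalSet(genes)),
        exons=sort_intervals(IntervalSet(exons)),
        gene_classes=classes,
    )
    ds.truth = {"config": dataclasses.asdict(config)}
    return ds


def place_g4s(dataset: SyntheticDataset, config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Place G4 intervals within exons.

    With ``g4_cluster_fraction`` > 0 that fraction of G4s is directed into
    cancer-class genes (the rest are placed uniformly over exonic bases),
    emulating elevated G4 content of cancer genes. ``g4_min_spacing``
    enforces a minimum same-chromosome separation by rejection.
    """
    config = config or dataset.config
    if config.n_g4 == 0:
        dataset.g4s = IntervalSet([], sorted_flag=True)
        dataset.truth["n_g4"] = 0
        return dataset
    rng = _rng_for(config, "g4")
    exons = list(dataset.exons)
    if not exons:
        raise ValueError("no exons to place G4s in")
    exon_class = np.array(
        [dataset.gene_classes.get("_".join((iv.label or "").split("_")[:2]), "non-cancer")
         for iv in exons]
    )
    lengths = np.array([len(iv) for iv in exons], dtype=float)
    margin = config.g4_edge_margin
    usable = np.maximum(lengths - 2 * margin - config.g4_length_mean, 1.0)

    weights_all = usable / usable.sum()
    cancer_mask = exon_class == "cancer"
    clustered = config.g4_cluster_fraction > 0 and cancer_mask.any() and (~cancer_mask).any()
    if clustered:
        # exclusive split: the clustered fraction goes to cancer genes, the
        # remainder to non-cancer genes only
        w_cancer = np.where(cancer_mask, usable, 0.0)
        w_cancer = w_cancer / w_cancer.sum()
        w_other = np.where(~cancer_mask, usable, 0.0)
        w_other = w_other / w_other.sum()
    else:
        w_cancer = w_other = weights_all

    placed: list[GenomicInterval] = []
    by_chrom_pos: dict[str, list[int]] = {}
    attempts = 0
    max_attempts = 200 * config.n_g4
    while len(placed) < config.n_g4:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not place requested G4s; reduce n_g4 or g4_min_spacing"
            )
        to_cancer = clustered and rng.random() < config.g4_cluster_fraction
        w = w_cancer if to_cancer else (w_other if clustered else weights_all)
        ei = int(rng.choice(len(exons), p=w))
        exon = exons[ei]
        length = max(10, int(rng.poisson(config.g4_length_mean)))
        lo = exon.start + margin
        hi = exon.end - margin - length
        if hi <= lo:
            continue
        start = int(rng.integers(lo, hi))
        if config.g4_min_spacing > 0:
            near = by_chrom_pos.get(exon.chrom, [])
            if any(abs(start - p) < config.g4_min_spacing for p in near):
                continue
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append(
            GenomicInterval(exon.chrom, start, start + length, strand, label=f"g4_{len(placed)}")
        )
        by_chrom_pos.setdefault(exon.chrom, []).append(start)

    dataset.g4s = sort_intervals(IntervalSet(placed))
    dataset.truth["n_g4"] = len(placed)
    return dataset


def _exon_lookup(dataset: SyntheticDataset) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in dataset.exons.chroms():
        ivs = [iv for iv in dataset.exons if iv.chrom == chrom]
        starts = np.array(sorted(iv.start for iv in ivs), dtype=np.int64)
        ends = np.array(sorted(iv.end for iv in ivs), dtype=np.int64)
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def _in_exon(lookup: dict[str, tuple[np.ndarray, np.ndarray]], chrom: str, pos: int) -> bool:
    if chrom not in lookup:
        return False
    starts, ends = lookup[chrom]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


def _window_weights(dataset: SyntheticDataset, config: SyntheticConfig, kind: str):
    """5 kb windows over genes with intensity weights planting the linear law."""
    from .intervals import intersect_count, make_windows

    windows = make_windows(dataset.genes, config.window_size)
    g4_counts = intersect_count(windows, dataset.g4s) if len(dataset.g4s) else np.zeros(len(windows), dtype=int)
    if kind == "cSNV":
        weights = config.linear_intercept + config.linear_slope * g4_counts.astype(float)
    else:
        weights = np.ones(len(windows), dtype=float)
    weights = np.maximum(weights, 0.0)
    return windows, g4_counts, weights


def place_snvs(
    dataset: SyntheticDataset,
    config: SyntheticConfig | None = None,
    kind: Literal["cSNV", "dbSNV"] = "cSNV",
) -> SyntheticDataset:
    """Plant an SNV cohort with the two-layer spatial model.

    Per SNV: with probability ``assoc_fraction`` a G4 is chosen (weighted
    by the intensity of its window) and the SNV lands at a Gaussian signed
    offset from it -- downstream of the G4 end for positive draws, upstream
    of its start for negative draws; otherwise the SNV is placed uniformly
    in exon space, with windows weighted by the planted linear intensity
    (cSNV kind) or uniformly (dbSNV kind). Offsets that would leave exon
    space are redrawn.
    """
    config = config or dataset.config
    if config.assoc_fraction > 0 and len(dataset.g4s) == 0:
        raise ValueError("assoc_fraction > 0 requires a non-empty G4 set")
    rng = _rng_for(config, f"snv_{kind}")
    lookup = _exon_lookup(dataset)
    windows, g4_counts, weights = _window_weights(dataset, config, kind)

    # exon pieces per window, for uniform-in-exon placement inside a window
    from .intervals import intersect_pieces

    pieces = intersect_pieces(windows, dataset.exons)
    win_pieces: dict[int, list[GenomicInterval]] = {}
    for wi, piece in pieces:
        win_pieces.setdefault(wi, []).append(piece)
    eligible = np.array([wi in win_pieces for wi in range(len(windows))])
    w_window = np.where(eligible, weights, 0.0)
    w_window = w_window / w_window.sum()

    # per-G4 weight = intensity of the window containing its start
    if len(dataset.g4s):
        g4_window = np.empty(len(dataset.g4s), dtype=int)
        win_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for wi, w in enumerate(windows):
            win_by_chrom.setdefault(w.chrom, []).append((w.start, w.end, wi))
        for gi, g4 in enumerate(dataset.g4s):
            g4_window[gi] = -1
            for s, e, wi in win_by_chrom.get(g4.chrom, []):
                if s <= g4.start < e:
                    g4_window[gi] = wi
                    break
        # a window's association mass must stay proportional to its planted
        # intensity, so each of its G4s carries intensity / (G4s in window)
        win_g4_total = np.bincount(
            g4_window[g4_window >= 0], minlength=len(windows)
        ).astype(float)
        w_g4 = np.array(
            [
                weights[w] / win_g4_total[w] if w >= 0 and win_g4_total[w] > 0 else 0.0
                for w in g4_window
            ],
            dtype=float,
        )
        if w_g4.sum() == 0:
            w_g4 = np.ones(len(dataset.g4s))
        w_g4 = w_g4 / w_g4.sum()

    if kind == "cSNV":
        if dataset.patients is None:
            dataset = assign_patients(dataset, config)
        patients = dataset.patients
        counts = rng.poisson(config.csnv_per_patient_mean, size=len(patients))
        patient_rows = np.repeat(np.arange(len(patients)), counts)
        n_snv = int(counts.sum())
        # per-cancer-type G4-association affinity (plants type disparities)
        k = config.n_cancer_types
        spread = config.type_affinity_spread
        type_assoc = {
            f"type_{t}": float(
                np.clip(config.assoc_fraction * (1 - spread / 2 + spread * (t / max(k - 1, 1))), 0, 1)
            )
            for t in range(k)
        }
        assoc_p = patients["cancer_type"].map(type_assoc).to_numpy()[patient_rows]
    else:
        n_snv = config.n_dbsnv
        patient_rows = None
        assoc_p = np.full(n_snv, config.assoc_fraction)

    offset_mean = config.offset_mean_csnv if kind == "cSNV" else config.offset_mean_dbsnv
    offset_sd = config.offset_sd_csnv if kind == "cSNV" else config.offset_sd_dbsnv

    chroms: list[str] = []
    positions: list[int] = []
    is_assoc = rng.random(n_snv) < assoc_p
    g4_list = list(dataset.g4s)
    for i in range(n_snv):
        if is_assoc[i]:
            gi = int(rng.choice(len(g4_list), p=w_g4))
            g4 = g4_list[gi]
            pos = -1
            for _ in range(60):
                d = int(round(rng.normal(offset_mean, offset_sd)))
                cand = g4.end + d if d >= 0 else g4.start + d - 1
                if _in_exon(lookup, g4.chrom, cand):
                    pos = cand
                    break
            if pos < 0:
                # fall back to uniform placement in the G4's exon neighbourhood
                pos = int(rng.integers(g4.start, g4.end))
            chroms.append(g4.chrom)
            positions.append(pos)
        else:
            wi = int(rng.choice(len(windows), p=w_window))
            plist = win_pieces[wi]
            lens = np.array([len(p) for p in plist], dtype=float)
            pi = int(rng.choice(len(plist), p=lens / lens.sum()))
            piece = plist[pi]
            chroms.append(piece.chrom)
            positions.append(int(rng.integers(piece.start, piece.end)))

    if kind == "cSNV":
        pt = dataset.patients
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "patient_id": pt["patient_id"].to_numpy()[patient_rows],
                "cancer_type": pt["cancer_type"].to_numpy()[patient_rows],
                "tissue": pt["tissue"].to_numpy()[patient_rows],
            }
        )
        dataset.csnvs = df
    else:
        df = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": positions,
                "patient_id": "population",
                "cancer_type": "common",
                "tissue": "population",
            }
        )
        dataset.dbsnvs = df
    dataset.truth[f"n_{kind.lower()}"] = n_snv
    dataset.truth[f"offset_mean_{kind.lower()}"] = offset_mean
    dataset.truth[f"offset_sd_{kind.lower()}"] = offset_sd
    return dataset


def assign_patients(dataset: SyntheticDataset, config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Assign patients to cancer types and tissues (skew > 0 unbalances types)."""
    config = config or dataset.config
    rng = _rng_for(config, "patients")
    k = config.n_cancer_types
    if config.cancer_type_skew > 0:
        p = (1 - config.cancer_type_skew) ** np.arange(k)
        p = p / p.sum()
    else:
        p = np.full(k, 1.0 / k)
    types = rng.choice(k, size=config.n_patients, p=p)
    dataset.patients = pd.DataFrame(
        {
            "patient_id": [f"patient_{i}" for i in range(config.n_patients)],
            "cancer_type": [f"type_{t}" for t in types],
            "tissue": [f"tissue_{t // 2}" for t in types],
        }
    )
    return dataset


def simulate_survival(dataset: SyntheticDataset, config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw survival outcomes from the planted proportional-hazards model.

    The per-patient covariate is the G4-average over that patient's
    cSNV-bearing 5 kb windows (computed exactly as the analysis stage
    does). Event times are exponential with hazard
    ``baseline_hazard * exp(cox_beta * g4_average)``; censoring is an
    independent exponential calibrated to the requested censor fraction. A
    small fraction of patients is marked as non-cancer deaths or given
    missing times to exercise the cohort-selection filter.
    """
    config = config or dataset.config
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    if dataset.csnvs is None:
        raise ValueError("cSNVs must be placed before simulating survival")
    from .intervals import make_windows
    from .survival import patient_g4_metrics
    from .windows import count_features

    rng = _rng_for(config, "survival")
    windows = make_windows(dataset.genes, config.window_size)
    table = count_features(
        windows, dataset.g4s, dataset.csnvs, dataset.dbsnvs, dataset.exons,
        dataset.genome_by_name(), gene_classes=dataset.gene_classes,
    )
    metrics = patient_g4_metrics(table, dataset.csnvs, windows)
    metrics = metrics.set_index("patient_id")

    pt = dataset.patients.copy()
    x = pt["patient_id"].map(metrics["g4_average"]).to_numpy(dtype=float)
    valid = ~np.isnan(x)

    hazard = config.baseline_hazard * np.exp(config.cox_beta * np.where(valid, x, 0.0))
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_rate > 0:
        mean_h = float(hazard[valid].mean()) if valid.any() else config.baseline_hazard
        rate_c = mean_h * config.censor_rate / max(1e-12, 1 - config.censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, size=len(pt))
    else:
        t_cens = np.full(len(pt), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    cause = np.where(event == 1, "cancer", "")
    vital = np.where(event == 1, "dead", "alive")
    # contaminate: non-cancer deaths and missing records
    u = rng.random(len(pt))
    noncancer = (u < config.noncancer_death_rate) & (event == 1)
    cause = np.where(noncancer, "other", cause)
    missing = rng.random(len(pt)) < config.missing_survival_rate
    time = np.where(missing, np.nan, time)

    pt["g4_average"] = x
    pt["survival_time"] = time
    pt["event"] = np.where(valid, event, np.nan)
    pt["vital_status"] = vital
    pt["cause_of_death"] = cause
    pt.loc[~valid, ["survival_time", "vital_status", "cause_of_death"]] = [np.nan, "", ""]
    dataset.patients = pt
    dataset.truth["cox_beta"] = config.cox_beta
    dataset.truth["baseline_hazard"] = config.baseline_hazard
    return dataset


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Run all generator stages in order."""
    ds = simulate_genome(config)
    ds = place_g4s(ds, config)
    ds = assign_patients(ds, config)
    ds = place_snvs(ds, config, "cSNV")
    ds = place_snvs(ds, config, "dbSNV")
    ds = simulate_survival(ds, config)
    return ds


def simulate_window_table(
    intercept: float = 2.0,
    slope: float = 3.0,
    max_g4: int = 15,
    base_windows: int = 2000,
    decay: float = 0.75,
    min_windows: int = 30,
    dbsnv_mean: float = 8.0,
    window_size: int = 5_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Directly planted window table: E[cSNV | g4 = c] = intercept + slope * c.

    Counts are Poisson; the dbSNV column has constant mean (no planted
    relation). Category sizes decay geometrically with the G4 count,
    emulating the strong sample-size disparity that motivates incomplete
    categorical bootstrapping.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pos = 0
    for c in range(max_g4 + 1):
        n_c = max(min_windows, int(round(base_windows * decay**c)))
        mu = intercept + slope * c
        csnv = rng.poisson(mu, size=n_c)
        dbsnv = rng.poisson(dbsnv_mean, size=n_c)
        for j in range(n_c):
            rows.append(
                {
                    "chrom": "chrS",
                    "start": pos,
                    "end": pos + window_size,
                    "g4_count": c,
                    "csnv_count": int(csnv[j]),
                    "dbsnv_count": int(dbsnv[j]),
                    "gc_bp": int(round(window_size * 0.45)),
                    "gene_class": "none",
                }
            )
            pos += window_size
    return pd.DataFrame(rows)
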