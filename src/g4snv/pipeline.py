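"""End-to-end orchestration: simulate -> analyze -> report.

``run_simulate`` materialises a synthetic study on disk (FASTA genome, BED
feature sets, TSV cohorts, JSON truth record with checksums).
``run_analyze`` executes the full analysis in the canonical order --
cohort preprocessing, window construction and counting, spatial profiling
with Gaussian fits, stratified enrichment with GC control, bootstrap
regression, patient metrics and Cox survival -- and writes a single
summary JSON. ``run_report`` renders the summary into flat TSV tables.

Every stochastic stage derives its stream from the single pipeline seed,
so a re-run with the same config is byte-identical (no timestamps enter
the summary).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bootstrap as bt
from . import preprocess as pp
from . import spatial as sp
from . import survival as sv
from . import windows as ws
from .intervals import IntervalSet, read_bed, write_bed
from .sequences import read_fasta, write_fasta
from .simulate import (
    SyntheticConfig,
    SyntheticDataset,
    simulate_dataset,
)

__all__ = ["PipelineConfig", "run_simulate", "load_dataset", "run_analyze", "run_report"]

log = logging.getLogger("g4snv")


@dataclass
class PipelineConfig:
    """Analysis-stage knobs; the synthetic config governs data generation."""

    window_size: int = 5000
    window_step: int | None = None  # None = fixed-end tiling
    flank: int = 2000
    max_g4_per_window: int = 15
    min_samples_per_type: int = 10
    profile_range: int = 5000
    profile_binwidth: int = 50
    profile_normalization: str = "unit_area"
    bootstrap_profile: str = "small"
    seed: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_simulate(
    config: SyntheticConfig, out_dir: str | Path, force: bool = False
) -> SyntheticDataset:
    """Generate a synthetic study and write all artefacts plus a manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    ds = simulate_dataset(config)
    write_fasta(ds.genome, out / "genome.fa")
    write_bed(ds.genes, out / "genes.bed")
    write_bed(ds.exons, out / "exons.bed")
    write_bed(ds.g4s, out / "g4s.bed")
    pp.write_snv_table(ds.csnvs, out / "csnvs.tsv")
    pp.write_snv_table(ds.dbsnvs, out / "dbsnvs.tsv")
    ds.patients.to_csv(out / "patients.tsv", sep="\t", index=False)
    with open(out / "gene_classes.tsv", "w") as fh:
        fh.write("gene\tgene_class\n")
        for gene, cls in sorted(ds.gene_classes.items()):
            fh.write(f"{gene}\t{cls}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=2, sort_keys=True, default=str)
    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {name: _sha256(out / name) for name in files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("simulated dataset written to %s (%d files)", out, len(files) + 1)
    return ds


def load_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Re-read a dataset previously written by :func:`run_simulate`."""
    d = Path(data_dir)
    with open(d / "truth.json") as fh:
        truth = json.load(fh)
    raw_cfg = dict(truth.get("config", {}))
    field_names = {f.name for f in dataclasses.fields(SyntheticConfig)}
    cfg = SyntheticConfig(**{k: v for k, v in raw_cfg.items() if k in field_names})
    classes: dict[str, str] = {}
    gc_path = d / "gene_classes.tsv"
    if gc_path.exists():
        for line in gc_path.read_text().splitlines()[1:]:
            gene, cls = line.split("\t")
            classes[gene] = cls
    ds = SyntheticDataset(
        config=cfg,
        genome=read_fasta(d / "genome.fa"),
        genes=read_bed(d / "genes.bed"),
        exons=read_bed(d / "exons.bed"),
        gene_classes=classes,
        g4s=read_bed(d / "g4s.bed"),
        csnvs=pp.read_snv_table(d / "csnvs.tsv"),
        dbsnvs=pp.read_snv_table(d / "dbsnvs.tsv"),
        patients=pd.read_csv(d / "patients.tsv", sep="\t"),
        truth=truth,
    )
    return ds


def run_analyze(
    dataset: SyntheticDataset,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis and return (and optionally write) the summary."""
    cfg = config or PipelineConfig()
    summary: dict = {"pipeline_config": cfg.as_dict()}

    # --- preprocessing -------------------------------------------------
    log.info("stage preprocess: %d cSNVs in", len(dataset.csnvs))
    csnvs, germ_report = pp.filter_germline(dataset.csnvs, dataset.dbsnvs)
    csnvs, type_report = pp.filter_cancer_types(
        csnvs, dataset.patients, min_samples=cfg.min_samples_per_type
    )
    summary["preprocess"] = {
        "germline": germ_report.as_dict(),
        "cancer_types": type_report.as_dict(),
    }

    # --- windows -------------------------------------------------------
    windows = pp.restrict_windows_to_genes(
        dataset.genes, dataset.exons, cfg.window_size, cfg.window_step, cfg.flank
    )
    genome = dataset.genome_by_name() or None
    table = ws.count_features(
        windows,
        dataset.g4s,
        csnvs,
        dataset.dbsnvs,
        dataset.exons,
        genome,
        gene_classes=dataset.gene_classes,
    )
    table = pp.cap_window_g4(table, cfg.max_g4_per_window)
    summary["windows"] = {
        "n_windows": int(len(table)),
        "mean_g4": float(table["g4_count"].mean()) if len(table) else None,
    }

    # --- spatial association -------------------------------------------
    spatial: dict = {}
    if len(dataset.g4s) and len(csnvs):
        prof_c = sp.distance_profile(
            csnvs, dataset.g4s, cfg.profile_range, cfg.profile_binwidth,
            cfg.profile_normalization,
        )
        fit_c = sp.fit_gaussian(prof_c)
        spatial["csnv_fit"] = fit_c.as_dict()
        if dataset.dbsnvs is not None and len(dataset.dbsnvs):
            prof_d = sp.distance_profile(
                dataset.dbsnvs, dataset.g4s, cfg.profile_range, cfg.profile_binwidth,
                cfg.profile_normalization,
            )
            fit_d = sp.fit_gaussian(prof_d)
            comp = sp.compare_fits(fit_c, fit_d)
            spatial["dbsnv_fit"] = fit_d.as_dict()
            spatial["sigma_ratio"] = comp.sigma_ratio
            spatial["mu_delta"] = comp.mu_delta
        r, p = sp.window_pearson(table["g4_count"], table["csnv_count"])
        spatial["window_pearson_csnv"] = {"r": r, "p": p}
        r_db, p_db = sp.window_pearson(table["g4_count"], table["dbsnv_count"])
        spatial["window_pearson_dbsnv"] = {"r": r_db, "p": p_db}
    else:
        log.info("stage spatial skipped (no G4s or no cSNVs)")
    summary["spatial"] = spatial

    # --- enrichment + GC control ---------------------------------------
    enrichment: dict = {}
    for kind in ("cSNV", "dbSNV"):
        enrichment[kind] = [r.as_dict() for r in ws.stratify_enrichment(table, kind)]
    table = ws.gc_normalized_counts(table)
    ok = table["gc_bp"] > 0
    if ok.sum() >= 4:
        try:
            pc = ws.partial_correlation(
                table.loc[ok, "g4_count"],
                table.loc[ok, "csnv_count"],
                table.loc[ok, "gc_bp"] / (table.loc[ok, "end"] - table.loc[ok, "start"]),
            )
            enrichment["partial_correlation"] = {
                "r_xy": pc.r_xy,
                "r_xy_given_z": pc.r_xy_given_z,
                "p_value": pc.p_value,
            }
        except ValueError as exc:
            log.info("partial correlation skipped: %s", exc)
    enrichment["gene_class"] = ws.gene_class_comparison(table, "cSNV")
    summary["enrichment"] = enrichment

    # --- bootstrap regression ------------------------------------------
    preset = bt.PRESETS[cfg.bootstrap_profile]
    bt_cfg = dataclasses.replace(preset, seed=cfg.seed)
    sweep: dict = {}
    for kind in ("cSNV", "dbSNV"):
        res = bt.bootstrap_sweep(table, kind, bt_cfg)
        trace = res.median_trace()
        final = trace.iloc[-1]
        sweep[kind] = {
            "i_max": int(final["i"]),
            "median_slope_at_i_max": float(final["slope"]),
            "median_intercept_at_i_max": float(final["intercept"]),
            "median_r2_at_i_max": float(final["r_squared"]),
            "trace": trace.to_dict(orient="list"),
        }
    try:
        whole = bt.whole_table_regression(table, "cSNV", seed=cfg.seed)
        sweep["whole_table_csnv"] = whole.as_dict()
    except ValueError as exc:
        log.info("whole-table regression skipped: %s", exc)
    summary["bootstrap"] = sweep

    # --- patient metrics and survival ----------------------------------
    patient: dict = {}
    metrics = sv.patient_g4_metrics(table, csnvs)
    patient["n_patients_with_metrics"] = int(len(metrics))
    patient["intra_cancer_variance"] = [
        g.as_dict() for g in sv.intra_cancer_variance(metrics)
    ]
    if dataset.patients is not None and "vital_status" in dataset.patients:
        cohort, sel_report = sv.select_survival_cohort(dataset.patients)
        patient["cohort_selection"] = sel_report
        # the analysis recomputes patient metrics; any generator-side
        # columns of the same name must not shadow them
        cohort = cohort.drop(
            columns=["g4_average", "normalized_g4_average", "csnv_average"],
            errors="ignore",
        )
        merged = cohort.merge(
            metrics[["patient_id", "g4_average", "normalized_g4_average", "csnv_average"]],
            on="patient_id",
            how="inner",
        )
        if len(merged) and merged["event"].sum() >= 2:
            cox = sv.fit_cox(merged, ["g4_average", "csnv_average"])
            patient["cox"] = cox.as_dict()
            # the hazard-scale reading of the primary coefficient
            patient["cox"]["g4_average_hazard_increase_pct"] = float(
                100 * (np.exp(cox.coefficients[0]) - 1)
            )
        else:
            log.info("stage survival skipped (not enough events)")
    summary["patient"] = patient

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "window_table.tsv", sep="\t", index=False)
        metrics.to_csv(out / "patient_metrics.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("analysis summary written to %s", out / "summary.json")
    return summary


def run_report(summary_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Render a summary JSON into flat TSV tables."""
    with open(summary_path) as fh:
        summary = json.load(fh)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if summary.get("spatial"):
        rows = []
        for name in ("csnv_fit", "dbsnv_fit"):
            if name in summary["spatial"]:
                rows.append({"cohort": name.split("_")[0], **summary["spatial"][name]})
        if rows:
            p = out / "gaussian_fits.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)

    if summary.get("enrichment"):
        rows = []
        for kind in ("cSNV", "dbSNV"):
            for entry in summary["enrichment"].get(kind, []):
                rows.append({"snv_kind": kind, **entry})
        if rows:
            p = out / "enrichment.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)

    patient = summary.get("patient", {})
    if patient.get("intra_cancer_variance"):
        p = out / "intra_cancer_variance.tsv"
        pd.DataFrame(patient["intra_cancer_variance"]).to_csv(p, sep="\t", index=False)
        written.append(p)
    if "cox" in patient:
        cox = patient["cox"]
        p = out / "cox_model.tsv"
        pd.DataFrame(
            {
                "covariate": cox["covariates"],
                "coefficient": cox["coefficients"],
                "hazard_ratio": cox["hazard_ratios"],
                "p_value": cox["p_values"],
            }
        ).to_csv(p, sep="\t", index=False)
        written.append(p)

    sweep = summary.get("bootstrap", {})
    rows = []
    for kind in ("cSNV", "dbSNV"):
        if kind in sweep and "trace" in sweep[kind]:
            t = pd.DataFrame(sweep[kind]["trace"])
            t.insert(0, "snv_kind", kind)
            rows.append(t)
    if rows:
        p = out / "bootstrap_trace.tsv"
        pd.concat(rows).to_csv(p, sep="\t", index=False)
        written.append(p)
    if not written:
        raise ValueError(f"summary {summary_path} contains no reportable sections")
    return written
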