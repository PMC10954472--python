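#!/usr/bin/env python
"""Patient-level G4 statistics and Cox proportional-hazards survival.

From the cohort study's window table: per-patient G4-average, normalized
G4-average and cSNV-average; intra-cancer-type variance of G4-averages;
survival-cohort selection (cancer deaths + alive patients); and the Cox
model with the G4-average and cSNV-average as covariates. Writes
``results/patient_metrics.tsv``, ``results/intra_cancer_variance.tsv``
and ``results/cox_model.json``.
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from g4snv.pipeline import load_dataset
from g4snv.preprocess import filter_cancer_types, filter_germline
from g4snv.survival import (
    fit_cox,
    intra_cancer_variance,
    patient_g4_metrics,
    select_survival_cohort,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ds = load_dataset(ROOT / "scratch" / "data" / "cohort")
    csnvs, _ = filter_germline(ds.csnvs, ds.dbsnvs)
    csnvs, _ = filter_cancer_types(csnvs, ds.patients)
    table = pd.read_csv(ROOT / "results" / "window_table.tsv", sep="\t")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        metrics = patient_g4_metrics(table, csnvs)
    print(f"{len(metrics)} patients with cSNV-bearing windows; "
          f"mean G4-average {metrics['g4_average'].mean():.2f}")

    variance = pd.DataFrame([g.as_dict() for g in intra_cancer_variance(metrics)])
    print(f"median intra-cancer normalized std of the G4-average: "
          f"{variance['normalized_std'].median():.2f}")

    cohort, report = select_survival_cohort(ds.patients)
    cohort = cohort.drop(columns=["g4_average"], errors="ignore").merge(
        metrics[["patient_id", "g4_average", "csnv_average"]], on="patient_id"
    )
    print(f"survival cohort: {report['n_retained']} patients "
          f"({report['n_events']} cancer deaths, {report['n_censored']} censored; "
          f"{report['n_noncancer_death']} non-cancer deaths excluded)")

    cox = fit_cox(cohort, ["g4_average", "csnv_average"])
    hr_pct = 100 * (cox.hazard_ratios[0] - 1)
    print(f"Cox: G4-average coefficient {cox.coefficients[0]:+.3f} "
          f"(p={cox.p_values[0]:.2g}) -> hazard {hr_pct:+.1f}% per unit; "
          f"cSNV-average p={cox.p_values[1]:.2g}; concordance {cox.concordance:.3f}")

    out = ROOT / "results"
    metrics.to_csv(out / "patient_metrics.tsv", sep="\t", index=False)
    variance.to_csv(out / "intra_cancer_variance.tsv", sep="\t", index=False)
    payload = cox.as_dict()
    payload["cohort_selection"] = report
    with open(out / "cox_model.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
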