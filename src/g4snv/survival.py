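"""Patient-level G4 statistics and Cox proportional-hazards modelling.

Patient metrics: for every patient, the windows holding at least one of
that patient's somatic SNVs are selected; the *G4-average* is the mean G4
count over those windows, the *normalized G4-average* divides it by the
summed G4 count over the same windows, and the *cSNV-average* is the mean
of the patient's per-window SNV counts. The G4-average then enters a Cox
proportional-hazards model of survival.

The Cox fit maximises the partial likelihood by Newton iterations, with
Breslow's approximation for tied event times by default and Efron's as an
option. Wald standard errors come from the inverse observed information;
model discrimination is Harrell's concordance over comparable pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupVariance",
    "CoxResult",
    "patient_g4_metrics",
    "intra_cancer_variance",
    "fit_cox",
    "select_survival_cohort",
    "concordance_index",
]


def _windows_of_snvs(
    window_table: pd.DataFrame, snvs: pd.DataFrame
) -> np.ndarray:
    """Map each SNV to the (non-overlapping) window containing it, -1 if none."""
    idx = np.full(len(snvs), -1, dtype=np.int64)
    for chrom, grp in window_table.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        rows = grp.index.to_numpy()[order]
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("patient metrics require non-overlapping windows")
        sel = snvs["chrom"].to_numpy() == chrom
        pos = snvs.loc[sel, "pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        out = np.where(ok, rows[np.clip(j, 0, None)], -1)
        idx[np.flatnonzero(sel)] = out
    return idx


def patient_g4_metrics(
    window_table: pd.DataFrame,
    csnvs: pd.DataFrame,
    windows=None,
) -> pd.DataFrame:
    """Per-patient G4-average, normalized G4-average and cSNV-average.

    For each patient the windows where that patient carries at least one
    cSNV are selected from the window table. Patients none of whose cSNVs
    fall into a retained window are excluded with a warning. The
    ``windows`` argument is accepted for signature compatibility and
    unused: the window table itself carries the coordinates.
    """
    window_table = window_table.reset_index(drop=True)
    win_idx = _windows_of_snvs(window_table, csnvs)
    df = pd.DataFrame(
        {
            "patient_id": csnvs["patient_id"].to_numpy(),
            "cancer_type": csnvs["cancer_type"].to_numpy(),
            "tissue": csnvs["tissue"].to_numpy(),
            "window": win_idx,
        }
    )
    dropped = df.loc[df["window"] < 0, "patient_id"].unique()
    df = df[df["window"] >= 0]
    per_pw = (
        df.groupby(["patient_id", "cancer_type", "tissue", "window"])
        .size()
        .rename("patient_csnv_count")
        .reset_index()
    )
    per_pw["g4_count"] = window_table["g4_count"].to_numpy()[per_pw["window"].to_numpy()]

    rows = []
    for (pid, ctype, tissue), grp in per_pw.groupby(
        ["patient_id", "cancer_type", "tissue"], sort=False
    ):
        g4 = grp["g4_count"].to_numpy(dtype=float)
        g4_sum = float(g4.sum())
        g4_avg = float(g4.mean())
        rows.append(
            {
                "patient_id": pid,
                "cancer_type": ctype,
                "tissue": tissue,
                "n_windows": len(grp),
                "g4_average": g4_avg,
                "normalized_g4_average": g4_avg / g4_sum if g4_sum > 0 else np.nan,
                "csnv_average": float(grp["patient_csnv_count"].mean()),
            }
        )
    excluded = set(dropped) - set(r["patient_id"] for r in rows)
    if excluded:
        warnings.warn(
            f"{len(excluded)} patient(s) had no cSNV-bearing window and were excluded"
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "cancer_type",
            "tissue",
            "n_windows",
            "g4_average",
            "normalized_g4_average",
            "csnv_average",
        ],
    )


@dataclass
class GroupVariance:
    cancer_type: str
    n_patients: int
    mean: float
    std: float
    normalized_std: float  # std / mean; NaN when mean == 0 or n < 2

    def as_dict(self) -> dict:
        return {
            "cancer_type": self.cancer_type,
            "n_patients": self.n_patients,
            "mean": self.mean,
            "std": self.std,
            "normalized_std": self.normalized_std,
        }


def intra_cancer_variance(
    summaries: pd.DataFrame, value: str = "g4_average", ddof: int = 1
) -> list[GroupVariance]:
    """Mean-normalized standard deviation of G4-averages per cancer type."""
    out: list[GroupVariance] = []
    for ctype, grp in summaries.groupby("cancer_type"):
        v = grp[value].dropna().to_numpy(dtype=float)
        mean = float(v.mean()) if len(v) else np.nan
        std = float(v.std(ddof=ddof)) if len(v) > ddof else np.nan
        norm = std / mean if len(v) > ddof and mean != 0 else np.nan
        if len(v) < 2:
            warnings.warn(f"cancer type {ctype!r} has fewer than 2 patients")
        out.append(GroupVariance(str(ctype), int(len(v)), mean, std, norm))
    return out


@dataclass
class CoxResult:
    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    concordance: float
    n_patients: int
    n_events: int
    log_likelihood: float
    ties: str

    def as_dict(self) -> dict:
        return {
            "covariates": list(self.covariates),
            "coefficients": self.coefficients.tolist(),
            "hazard_ratios": self.hazard_ratios.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "p_values": self.p_values.tolist(),
            "ci95_low": self.ci95_low.tolist(),
            "ci95_high": self.ci95_high.tolist(),
            "concordance": self.concordance,
            "n_patients": self.n_patients,
            "n_events": self.n_events,
            "log_likelihood": self.log_likelihood,
            "ties": self.ties,
        }


def cox_partial_loglik(
    beta: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    x: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Log partial likelihood (Breslow or Efron ties); reference implementation
    shape also used by the Newton solver below."""
    ll, _, _ = _cox_derivatives(np.asarray(beta, dtype=float), time, event, x, ties)
    return ll


def _cox_derivatives(beta, time, event, x, ties):
    """Log partial likelihood with gradient and Hessian.

    Observations are processed in decreasing time order so risk-set sums
    are cumulative; tied event times form a single block handled by the
    chosen approximation.
    """
    n, p = x.shape
    order = np.argsort(-time, kind="stable")
    t, d, xv = time[order], event[order], x[order]
    eta = xv @ beta
    w = np.exp(eta)
    wx = w[:, None] * xv
    wxx = w[:, None, None] * (xv[:, :, None] * xv[:, None, :])

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        block = slice(i, j)
        s0 += float(w[block].sum())
        s1 += wx[block].sum(axis=0)
        s2 += wxx[block].sum(axis=0)
        ev = np.flatnonzero(d[block] == 1) + i
        m = len(ev)
        if m:
            ll += float(eta[ev].sum())
            grad += xv[ev].sum(axis=0)
            if ties == "breslow" or m == 1:
                ll -= m * np.log(s0)
                grad -= m * s1 / s0
                hess -= m * (s2 / s0 - np.outer(s1, s1) / s0**2)
            elif ties == "efron":
                d0 = float(w[ev].sum())
                d1 = wx[ev].sum(axis=0)
                d2 = wxx[ev].sum(axis=0)
                for k in range(m):
                    f = k / m
                    a0 = s0 - f * d0
                    a1 = s1 - f * d1
                    a2 = s2 - f * d2
                    ll -= np.log(a0)
                    grad -= a1 / a0
                    hess -= a2 / a0 - np.outer(a1, a1) / a0**2
            else:
                raise ValueError(f"unknown ties method {ties!r}")
        i = j
    return ll, grad, hess


def fit_cox(
    summaries: pd.DataFrame,
    covariates: list[str] = ("g4_average",),
    duration_col: str = "survival_time",
    event_col: str = "event",
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Newton maximisation of the Cox partial likelihood.

    Requires at least two events and non-constant covariates; raises with
    diagnostics on non-convergence. Covariates are used unstandardized, so
    a coefficient is the log-hazard change per one-unit covariate increase.
    """
    covariates = list(covariates)
    df = summaries.dropna(subset=[duration_col, event_col, *covariates])
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=float).astype(int)
    x = df[covariates].to_numpy(dtype=float)
    n, p = x.shape
    if event.sum() < 2:
        raise ValueError(f"need >= 2 events, got {int(event.sum())}")
    for k, name in enumerate(covariates):
        if np.std(x[:, k]) == 0:
            raise ValueError(f"covariate {name!r} is constant")

    beta = np.zeros(p)
    ll_old = -np.inf
    for it in range(max_iter):
        ll, grad, hess = _cox_derivatives(beta, time, event, x, ties)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular information matrix at iteration {it}") from exc
        beta_new = beta - step
        # halve the step until the likelihood does not decrease
        for _ in range(30):
            ll_new, _, _ = _cox_derivatives(beta_new, time, event, x, ties)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            beta_new = (beta + beta_new) / 2
        if np.max(np.abs(beta_new - beta)) < tol or abs(ll_new - ll_old) < tol:
            beta = beta_new
            break
        beta, ll_old = beta_new, ll_new
    else:
        raise ValueError(
            f"Newton did not converge in {max_iter} iterations "
            f"(last |step| = {np.max(np.abs(step)):.3g}, ll = {ll:.6g})"
        )

    ll, grad, hess = _cox_derivatives(beta, time, event, x, ties)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    from scipy import stats as sps

    z = beta / se
    pvals = 2 * sps.norm.sf(np.abs(z))
    risk = x @ beta
    return CoxResult(
        covariates=covariates,
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        standard_errors=se,
        p_values=pvals,
        ci95_low=beta - 1.96 * se,
        ci95_high=beta + 1.96 * se,
        concordance=concordance_index(time, -risk, event),
        n_patients=n,
        n_events=int(event.sum()),
        log_likelihood=float(ll),
        ties=ties,
    )


def concordance_index(time: np.ndarray, predicted: np.ndarray, event: np.ndarray) -> float:
    """Harrell's C: fraction of comparable pairs ordered correctly.

    ``predicted`` is interpreted like a survival-time prediction (higher =
    longer survival), matching the convention of the established survival
    packages; pass the negated risk score for a Cox model. Ties in the
    prediction count one half.
    """
    from lifelines.utils import concordance_index as _ci

    return float(_ci(time, predicted, event))


def select_survival_cohort(patients: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep cancer deaths (event) and alive patients (censored); drop the rest.

    Expects columns ``vital_status`` ('dead'/'alive'), ``cause_of_death``
    ('cancer'/'other'/empty) and ``survival_time``. Records with missing
    times, missing status, or non-cancer deaths are dropped and counted.
    """
    df = patients.copy()
    status = df.get("vital_status")
    if status is None or "survival_time" not in df:
        raise ValueError("patient table needs vital_status and survival_time columns")
    cause = df.get("cause_of_death", pd.Series("", index=df.index))
    has_time = df["survival_time"].notna()
    is_dead = status == "dead"
    is_alive = status == "alive"
    cancer_death = is_dead & (cause == "cancer")
    noncancer_death = is_dead & (cause != "cancer")
    keep = has_time & (cancer_death | is_alive)
    out = df[keep].copy()
    out["event"] = cancer_death[keep].astype(int)
    report = {
        "n_input": int(len(df)),
        "n_retained": int(keep.sum()),
        "n_noncancer_death": int((noncancer_death & has_time).sum()),
        "n_missing": int((~has_time | ~(is_dead | is_alive)).sum()),
        "n_events": int(out["event"].sum()),
        "n_censored": int((out["event"] == 0).sum()),
    }
    return out.reset_index(drop=True), report
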