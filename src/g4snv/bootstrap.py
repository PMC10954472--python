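"""Incomplete categorical bootstrapping and linear regression on window tables.

Window counts are heavily unbalanced across G4-count categories: windows
with zero G4s outnumber those with fifteen by orders of magnitude, and the
within-category variance dwarfs the between-category trend. The
bootstrapping scheme equalizes category influence and shrinks within-group
noise before regression:

for every retained category c (G4 count 0..15), draw ``n_permutations``
subsets of ``I`` windows with replacement and reduce each subset to its
mean SNV count -- yielding exactly ``n_permutations`` points per category
regardless of the category's size. An ordinary least-squares line is then
fitted to the pooled (c, mean) points. Sweeping I upward shrinks the
within-category variance like s^2/I, so the fit's R^2 climbs toward the
R^2 of the exact category means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "RegressionResult",
    "BootstrapSweepResult",
    "PRESETS",
    "categorical_bootstrap",
    "fit_linear",
    "bootstrap_sweep",
    "whole_table_regression",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling profile: N permutations of I points, swept in i_step increments."""

    n_permutations: int = 250
    i_max: int = 100
    i_step: int = 10
    cycles: int = 10
    seed: int = 0
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if min(self.n_permutations, self.i_max, self.i_step, self.cycles) < 1:
            raise ValueError("all bootstrap counts must be >= 1")
        if self.i_step > self.i_max:
            raise ValueError("i_step must not exceed i_max")


#: Named profiles; the sweep cost grows as n_permutations * cycles / i_step.
PRESETS: dict[str, BootstrapConfig] = {
    "small": BootstrapConfig(n_permutations=250, i_max=100, i_step=10, cycles=10),
    "medium": BootstrapConfig(n_permutations=500, i_max=100, i_step=5, cycles=20),
    "large": BootstrapConfig(n_permutations=1000, i_max=100, i_step=1, cycles=50),
}


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


@dataclass
class BootstrapSweepResult:
    """Per (cycle, I) fit results plus per-category mean traces."""

    records: pd.DataFrame  # columns: cycle, i, slope, intercept, r_squared
    category_means: pd.DataFrame  # columns: g4_count, mean (raw category means)
    skipped_categories: list[int] = field(default_factory=list)
    config: BootstrapConfig | None = None

    def median_trace(self) -> pd.DataFrame:
        return (
            self.records.groupby("i")[["slope", "intercept", "r_squared"]]
            .median()
            .reset_index()
        )


def categorical_bootstrap(
    table: pd.DataFrame,
    snv_kind: str = "cSNV",
    n_permutations: int = 250,
    i_points: int = 10,
    rng: np.random.Generator | int | None = 0,
    with_replacement: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Equal-influence resampling: N averaged subsets of size I per category.

    Returns (x, y, skipped): x holds the raw G4 count of each point's
    category, y the subset means; every non-empty category contributes
    exactly ``n_permutations`` points irrespective of its window count.
    Empty categories are skipped with a warning and reported.
    """
    if i_points < 1:
        raise ValueError("I must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    col = "csnv_count" if snv_kind == "cSNV" else "dbsnv_count"
    max_cat = int(table["g4_count"].max())
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    skipped: list[int] = []
    for c in range(max_cat + 1):
        values = table.loc[table["g4_count"] == c, col].to_numpy(dtype=float)
        if len(values) == 0:
            skipped.append(c)
            warnings.warn(f"G4 category {c} has no windows; skipped")
            continue
        if with_replacement or len(values) < i_points:
            draws = rng.integers(0, len(values), size=(n_permutations, i_points))
            means = values[draws].mean(axis=1)
        else:
            means = np.array(
                [
                    values[rng.choice(len(values), size=i_points, replace=False)].mean()
                    for _ in range(n_permutations)
                ]
            )
        xs.append(np.full(n_permutations, c, dtype=float))
        ys.append(means)
    if not xs:
        raise ValueError("all categories empty")
    return np.concatenate(xs), np.concatenate(ys), skipped


def fit_linear(x, y) -> RegressionResult:
    """Ordinary least squares through the (x, y) point cloud."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired points")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct x values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
    return RegressionResult(float(slope), float(intercept), r2, len(x))


def bootstrap_sweep(
    table: pd.DataFrame,
    snv_kind: str = "cSNV",
    config: BootstrapConfig = PRESETS["small"],
) -> BootstrapSweepResult:
    """Sweep the subset size I and refit; collects slope/R^2 traces.

    Each (cycle, I) combination gets an independent reproducible stream
    derived from the config seed.
    """
    col = "csnv_count" if snv_kind == "cSNV" else "dbsnv_count"
    records: list[dict] = []
    skipped: list[int] = []
    i_values = list(range(config.i_step, config.i_max + 1, config.i_step))
    root = np.random.SeedSequence(config.seed % (2**31))
    streams = root.spawn(config.cycles * len(i_values))
    k = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty categories reported once below
        for cycle in range(config.cycles):
            for i_points in i_values:
                rng = np.random.default_rng(streams[k])
                k += 1
                x, y, skip = categorical_bootstrap(
                    table,
                    snv_kind,
                    n_permutations=config.n_permutations,
                    i_points=i_points,
                    rng=rng,
                    with_replacement=config.with_replacement,
                )
                skipped = skip
                fit = fit_linear(x, y)
                records.append(
                    {
                        "cycle": cycle,
                        "i": i_points,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "r_squared": fit.r_squared,
                    }
                )
    cat_means = (
        table.groupby("g4_count")[col].mean().rename("mean").reset_index()
    )
    return BootstrapSweepResult(
        records=pd.DataFrame(records),
        category_means=cat_means,
        skipped_categories=skipped,
        config=config,
    )


def whole_table_regression(
    table: pd.DataFrame,
    snv_kind: str = "cSNV",
    train_fraction: float = 0.7,
    seed: int = 0,
) -> RegressionResult:
    """OLS on a random train split, R^2 scored on the held-out windows."""
    from sklearn.linear_model import LinearRegression
    from sklearn.metrics import r2_score

    if len(table) < 10:
        raise ValueError("need at least 10 windows")
    col = "csnv_count" if snv_kind == "cSNV" else "dbsnv_count"
    rng = np.random.default_rng(seed)
    n = len(table)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 2:
        raise ValueError("degenerate train/test split")
    train, test = perm[:n_train], perm[n_train:]
    x = table["g4_count"].to_numpy(dtype=float).reshape(-1, 1)
    y = table[col].to_numpy(dtype=float)
    model = LinearRegression().fit(x[train], y[train])
    r2 = float(r2_score(y[test], model.predict(x[test])))
    return RegressionResult(
        float(model.coef_[0]), float(model.intercept_), r2, n_points=len(test)
    )
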