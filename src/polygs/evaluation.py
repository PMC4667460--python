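"""Prediction-accuracy estimation and the selection-gain comparison.

Accuracy is the Pearson correlation between predicted and observed
phenotypes in repeated random-split cross-validation: per repetition 90 % of
genotypes train the model and 10 % validate it, repeated 500 times by
default, averaging the correlations.  Cross-population accuracy trains on
all genotypes of one population and predicts the other on the shared
(COMMON) marker panel, with phenotypes z-normalized within population.
``run_benchmark_grid`` enumerates the full calling-strategy x imputer x
missing-threshold x model factorial.  ``gain_ratio`` compares genomic and
conventional selection as predicted gain per unit time, r_A / cycle_gs
versus h_N / cycle_conv.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import fit_model
from .simdata import derive_seed

__all__ = [
    "AccuracyReport",
    "GainComparison",
    "cross_validate",
    "cross_population_predict",
    "run_benchmark_grid",
    "gain_ratio",
    "plot_threshold_curve",
]


@dataclass
class AccuracyReport:
    """Per-repetition CV accuracies for one pipeline configuration."""

    config: dict
    per_rep_r: np.ndarray
    n_reps: int = field(init=False)

    def __post_init__(self) -> None:
        self.per_rep_r = np.asarray(self.per_rep_r, dtype=float)
        self.n_reps = len(self.per_rep_r)

    @property
    def mean_r(self) -> float:
        return float(self.per_rep_r.mean())

    @property
    def sd_r(self) -> float:
        return float(self.per_rep_r.std(ddof=1)) if self.n_reps > 1 else 0.0

    def to_row(self) -> dict:
        return {**self.config, "mean_r": self.mean_r, "sd_r": self.sd_r,
                "n_reps": self.n_reps}


@dataclass(frozen=True)
class GainComparison:
    """Genomic vs conventional per-unit-time selection-gain comparison."""

    r_A: float
    h_N: float
    cycle_gs: float
    cycle_conv: float

    @property
    def gain_gs(self) -> float:
        return self.r_A / self.cycle_gs

    @property
    def gain_conv(self) -> float:
        return self.h_N / self.cycle_conv

    @property
    def ratio(self) -> float:
        return self.gain_gs / self.gain_conv


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant vector in a validation fold: r recorded as 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate(
    G,
    y,
    model_spec: str | tuple[str, dict] = "rrBLUP",
    train_frac: float = 0.9,
    n_reps: int = 500,
    seed: int = 0,
    config: dict | None = None,
) -> AccuracyReport:
    """Repeated random-split cross-validation accuracy.

    Per repetition an independent random split assigns ``train_frac`` of the
    genotypes to training (default 90 %) and the rest to validation; the
    model is refitted on the training rows and scored by the Pearson
    correlation between its predictions and the observed validation
    phenotypes.  Repetition seeds derive from ``seed`` by a counter scheme,
    so identical seeds reproduce the whole split sequence.
    """
    tag, params = _parse_spec(model_spec)
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    n_val = int(round((1 - train_frac) * n))
    if n_val < 3:
        raise ValueError("validation folds need at least 3 individuals")
    rs = []
    for rep in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, f"cv{rep}"))
        perm = rng.permutation(n)
        val, train = perm[:n_val], perm[n_val:]
        res = fit_model(tag, G[train], y[train],
                        seed=derive_seed(seed, f"fit{rep}"), **params)
        pred = res.predict(G[val])
        rs.append(_safe_pearson(pred, y[val]))
    cfg = dict(config or {})
    cfg.setdefault("model", tag)
    return AccuracyReport(config=cfg, per_rep_r=np.asarray(rs))


def _parse_spec(model_spec) -> tuple[str, dict]:
    if isinstance(model_spec, str):
        return model_spec, {}
    tag, params = model_spec
    return tag, dict(params or {})


def _znorm(v: np.ndarray) -> np.ndarray:
    sd = np.std(v)
    if sd == 0:
        raise ValueError("cannot z-normalize a constant phenotype vector")
    return (v - np.mean(v)) / sd


def cross_population_predict(
    G_train,
    y_train,
    G_test,
    y_test,
    model_spec: str | tuple[str, dict] = "rrBLUP",
    seed: int = 0,
    marker_names_train=None,
    marker_names_test=None,
) -> float:
    """Train on all genotypes of one population, predict the other.

    Phenotypes are z-normalized within each population before training and
    scoring (accuracy itself is scale-free, the normalization matches the
    study protocol).  If marker-name lists are supplied they must match
    exactly (same COMMON panel, same order).
    """
    if marker_names_train is not None or marker_names_test is not None:
        if list(marker_names_train) != list(marker_names_test):
            raise ValueError("train/test marker panels differ; build COMMON first")
    G_train = np.asarray(G_train, dtype=float)
    G_test = np.asarray(G_test, dtype=float)
    if G_train.shape[1] != G_test.shape[1]:
        raise ValueError("train/test marker counts differ; build COMMON first")
    tag, params = _parse_spec(model_spec)
    yt = _znorm(np.asarray(y_train, dtype=float).ravel())
    yv = _znorm(np.asarray(y_test, dtype=float).ravel())
    res = fit_model(tag, G_train, yt, seed=seed, **params)
    return _safe_pearson(res.predict(G_test), yv)


def run_benchmark_grid(
    datasets: dict,
    phenotypes: dict,
    strategies=("separate", "joint"),
    imputers=("MNI", "SVDI", "RFI"),
    thresholds=(0.10, 0.20, 0.30, 0.40, 0.50, 0.70),
    models=("rrBLUP",),
    n_reps: int = 500,
    train_frac: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validate every calling x imputer x threshold x model cell.

    ``datasets`` maps (population, strategy, imputer, threshold) to a
    QC-complete marker matrix (array or GenotypeMatrix); ``phenotypes`` maps
    population to its phenotype vector.  Returns one tidy row per
    configuration per population per model, with mean and SD of the
    per-repetition Pearson accuracies.  A missing pre-computed combination
    raises an error naming it.
    """
    pops = sorted(phenotypes)
    rows = []
    for pop, strat, imp, thr, mtag in itertools.product(
        pops, strategies, imputers, thresholds, models
    ):
        key = (pop, strat, imp, thr)
        if key not in datasets:
            raise KeyError(f"no pre-computed marker matrix for combination {key}")
        G = datasets[key]
        codes = G.codes if hasattr(G, "codes") else G
        rep = cross_validate(
            codes,
            phenotypes[pop],
            model_spec=mtag,
            train_frac=train_frac,
            n_reps=n_reps,
            seed=derive_seed(seed, f"{pop}|{strat}|{imp}|{thr}|{mtag}"),
            config={
                "population": pop,
                "strategy": strat,
                "imputer": imp,
                "threshold": thr,
                "model": mtag,
            },
        )
        rows.append(rep.to_row())
    return pd.DataFrame(rows)


def gain_ratio(
    r_A: float,
    h_N2: float,
    cycle_gs: float = 1.0,
    cycle_conv: float = 5.0,
    round_h: int | None = 2,
) -> GainComparison:
    """Compare genomic vs conventional selection gains per unit time.

    Genomic selection gains r_A per ``cycle_gs`` years; conventional
    phenotypic (progeny-test) selection gains h_N = sqrt(h_N2) per
    ``cycle_conv`` years.  ``round_h`` rounds h_N to that many decimals
    (2 by default, matching how the comparison is usually quoted);
    pass None for the unrounded value.
    """
    if not 0.0 < r_A <= 1.0:
        raise ValueError("r_A must lie in (0, 1]")
    if not 0.0 < h_N2 <= 1.0:
        raise ValueError("h_N2 must lie in (0, 1]")
    if cycle_gs <= 0 or cycle_conv <= 0:
        raise ValueError("cycle lengths must be positive")
    h_N = float(np.sqrt(h_N2))
    if round_h is not None:
        h_N = round(h_N, round_h)
    return GainComparison(r_A=r_A, h_N=h_N, cycle_gs=cycle_gs, cycle_conv=cycle_conv)


def plot_threshold_curve(grid_table: pd.DataFrame, ax=None):
    """Accuracy vs missing-data threshold, one line per (population, imputer).

    Expects the tidy frame produced by :func:`run_benchmark_grid`; returns
    the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for (pop, imp), grp in grid_table.groupby(["population", "imputer"]):
        curve = grp.groupby("threshold")["mean_r"].mean()
        ax.plot(curve.index, curve.to_numpy(), marker="o",
                label=f"{pop} / {imp}")
    ax.set_xlabel("missing-data threshold")
    ax.set_ylabel("mean Pearson accuracy")
    ax.legend(fontsize=8)
    return ax
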