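"""Progeny-trial variance components and BLUP-adjusted parent phenotypes.

Half-sib progeny plot yields from a randomized complete block trial are
decomposed by two-way ANOVA (progeny + block) into a half-sib progeny
variance component S2_hs and a plot error component S2_e.  Broad-sense
heritability on a progeny-mean basis is

    h_B^2 = S2_hs / (S2_hs + S2_e / r)

with r the number of replications, and the parent phenotype used for
genomic prediction is the progeny mean shrunk toward the grand mean by
h_B^2 (a BLUP of the progeny main effect under the ANOVA model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "estimate_variance_components",
    "heritability_progeny_mean",
    "blup_adjust",
    "adjust_trial",
]


class TrialDesignError(ValueError):
    pass


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA variance components of a replicated half-sib trial."""

    s2_hs: float  # half-sib progeny variance (>= 0, truncated)
    s2_e: float  # plot error variance
    r: int  # replications


def _check_trial(trial: pd.DataFrame) -> pd.DataFrame:
    required = {"progeny_id", "replication_id", "plot_value"}
    if not required.issubset(trial.columns):
        raise TrialDesignError(f"trial table needs columns {sorted(required)}")
    dup = trial.duplicated(subset=["progeny_id", "replication_id"])
    if dup.any():
        raise TrialDesignError("a progeny appears more than once in a replication")
    return trial


def estimate_variance_components(trial: pd.DataFrame) -> VarianceComponents:
    """Two-way (progeny + block) expected-mean-squares ANOVA estimators.

    S2_e is the residual mean square; S2_hs = (MS_progeny - MS_error)/r,
    truncated at zero.  Requires a complete block design with >= 2
    replications and >= 2 progenies.
    """
    trial = _check_trial(trial)
    r = trial["replication_id"].nunique()
    g = trial["progeny_id"].nunique()
    if r < 2:
        raise TrialDesignError("variance components need >= 2 replications")
    if g < 2:
        raise TrialDesignError("variance components need >= 2 progenies")
    wide = trial.pivot(index="progeny_id", columns="replication_id", values="plot_value")
    if wide.isna().any().any():
        raise TrialDesignError("incomplete blocks: every progeny needs every replication")
    y = wide.to_numpy(dtype=float)
    grand = y.mean()
    prog_means = y.mean(axis=1)
    block_means = y.mean(axis=0)
    ss_prog = r * np.sum((prog_means - grand) ** 2)
    ss_block = g * np.sum((block_means - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_prog - ss_block
    df_err = (g - 1) * (r - 1)
    ms_prog = ss_prog / (g - 1)
    ms_err = max(ss_err / df_err, 0.0)
    s2_hs = (ms_prog - ms_err) / r
    if s2_hs < 0:
        warnings.warn("negative progeny variance estimate truncated to 0")
        s2_hs = 0.0
    return VarianceComponents(s2_hs=float(s2_hs), s2_e=float(ms_err), r=int(r))


def heritability_progeny_mean(vc: VarianceComponents) -> float:
    """h_B^2 = S2_hs / (S2_hs + S2_e / r); 0 in the degenerate all-zero case."""
    if vc.s2_hs < 0 or vc.s2_e < 0 or vc.r < 1:
        raise TrialDesignError("invalid variance components")
    denom = vc.s2_hs + vc.s2_e / vc.r
    if denom == 0.0:
        warnings.warn("all variance components are zero; h_B^2 defined as 0")
        return 0.0
    return vc.s2_hs / denom


def blup_adjust(progeny_means: np.ndarray | pd.Series, h_B2: float) -> np.ndarray | pd.Series:
    """Shrink progeny means toward their grand mean by h_B^2.

    adjusted_i = grand_mean + h_B2 * (mean_i - grand_mean).  Preserves the
    grand mean exactly and the ranking of progenies for any h_B2 > 0.
    """
    if not 0.0 <= h_B2 <= 1.0:
        raise TrialDesignError("h_B^2 must lie in [0, 1]")
    grand = np.mean(progeny_means)
    return grand + h_B2 * (progeny_means - grand)


def adjust_trial(trial: pd.DataFrame) -> tuple[pd.Series, VarianceComponents, float]:
    """Full adjustment: ANOVA components, h_B^2, shrunken progeny means."""
    vc = estimate_variance_components(trial)
    h2 = heritability_progeny_mean(vc)
    means = trial.groupby("progeny_id")["plot_value"].mean()
    return blup_adjust(means, h2), vc, h2
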