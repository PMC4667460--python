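"""Kinship estimation and kinship-corrected single-marker association.

The kinship matrix is the centered cross-product (VanRaden-type) relatedness
K = Z Z' / (2 sum_j p_j (1 - p_j)) on the pseudo-diploid {0,1,2} codes, used
both as a population-structure diagnostic and as the random-effect
covariance of the mixed model.  Association follows the EMMAX scheme: the
two variance components (sigma2_g for K, sigma2_e) are estimated once by
REML under the no-marker null, then every marker is tested as a fixed effect
by a generalized-least-squares Wald test with those components held fixed.
Markers without a genome alignment are displayed on a fictitious chromosome
"N" with sequential pseudo-positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "kinship_matrix",
    "mixed_model_gwas",
    "manhattan_export",
    "plot_manhattan",
]


@dataclass
class KinshipMatrix:
    """Individuals x individuals marker-derived relatedness."""

    values: np.ndarray
    sample_ids: list[str] | None = None
    method: str = "vanraden"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship matrix must be square")


def _codes(G) -> np.ndarray:
    codes = G.codes if isinstance(G, GenotypeMatrix) else np.asarray(G)
    if np.any(codes == MISSING):
        raise ValueError("kinship/GWAS need a complete matrix; impute first")
    return codes.astype(float)


def kinship_matrix(G) -> KinshipMatrix:
    """Centered cross-product relatedness K = ZZ' / (2 sum p_j (1-p_j))."""
    codes = _codes(G)
    p = codes.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (codes.std(axis=0) > 0)
    if poly.sum() < 2:
        raise ValueError("kinship needs at least 2 polymorphic markers")
    Z = codes[:, poly] - 2.0 * p[None, poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = Z @ Z.T / denom
    ids = G.sample_ids if isinstance(G, GenotypeMatrix) else None
    return KinshipMatrix(values=(K + K.T) / 2.0, sample_ids=ids)


def _null_variance_components(y: np.ndarray, K: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """REML (sigma2_g, sigma2_e) under y = 1 mu + g + e, g ~ N(0, sigma2_g K)."""
    n = len(y)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_rll(log_delta: float) -> float:
        delta = np.exp(log_delta)  # sigma2_e / sigma2_g
        w = 1.0 / (d + delta)
        xwx = np.sum(w * xt * xt)
        mu = np.sum(w * xt * yt) / xwx
        r = yt - mu * xt
        sigma_g2 = np.sum(w * r * r) / (n - 1)
        return 0.5 * ((n - 1) * np.log(2 * np.pi * sigma_g2)
                      + np.sum(np.log(d + delta)) + np.log(xwx) + (n - 1))

    res = optimize.minimize_scalar(neg_rll, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-6})
    delta = float(np.exp(res.x))
    w = 1.0 / (d + delta)
    xwx = np.sum(w * xt * xt)
    mu = np.sum(w * xt * yt) / xwx
    r = yt - mu * xt
    sigma_g2 = float(np.sum(w * r * r) / (n - 1))
    return sigma_g2, sigma_g2 * delta, d + delta, U


def mixed_model_gwas(G, y, K: KinshipMatrix | np.ndarray | None = None) -> pd.DataFrame:
    """EMMAX-style mixed-model association scan.

    Variance components are estimated once under the null; each marker is
    then tested as a fixed effect by GLS with covariance
    sigma2_g K + sigma2_e I held fixed (Wald t-test, two-sided).  Returns a
    tidy frame with effect estimates, test statistics and p-values, one row
    per input marker.
    """
    codes = _codes(G)
    y = np.asarray(y, dtype=float).ravel()
    n, m = codes.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match genotype rows")
    if np.std(y) == 0:
        raise ValueError("constant phenotype: association undefined")
    if K is None:
        K = kinship_matrix(G)
    Kv = K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    sigma_g2, sigma_e2, dw, U = _null_variance_components(y, Kv)

    # rotate once; V^-1 = U diag(1/dw) U' / sigma_g2 (constant factor cancels
    # in the t statistic, keep it for interpretable SEs)
    w = 1.0 / dw
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    Gt = U.T @ codes
    # GLS with X = [1, x] per marker, closed-form 2x2 solve, vectorized
    a11 = np.sum(w * ones_t * ones_t)
    a12 = Gt.T @ (w * ones_t)                      # per marker
    a22 = np.einsum("ij,ij->j", Gt, w[:, None] * Gt)
    b1 = np.sum(w * ones_t * yt)
    b2 = Gt.T @ (w * yt)
    det = a11 * a22 - a12**2
    ok = det > 1e-12 * a11 * np.maximum(a22, 1e-300)
    beta = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), 0.0)
    alpha = np.where(ok, (a22 * b1 - a12 * b2) / np.where(ok, det, 1.0), b1 / a11)
    # residual variance on the whitened scale, per marker
    yty = np.sum(w * yt * yt)
    rss = yty - 2 * (alpha * b1 + beta * b2) \
        + (alpha**2 * a11 + 2 * alpha * beta * a12 + beta**2 * a22)
    dof = n - 2
    s2 = np.maximum(rss, 0.0) / dof
    var_beta = np.where(ok, s2 * a11 / np.where(ok, det, 1.0), np.inf)
    tstat = beta / np.sqrt(np.maximum(var_beta, 1e-300))
    pvals = np.where(ok, 2.0 * stats.t.sf(np.abs(tstat), dof), 1.0)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    names = G.marker_names if isinstance(G, GenotypeMatrix) else [f"M{j:05d}" for j in range(m)]
    out = pd.DataFrame(
        {
            "marker": names,
            "effect": beta,
            "stat": tstat,
            "p_value": pvals,
        }
    )
    out.attrs["sigma2_g"] = sigma_g2
    out.attrs["sigma2_e"] = sigma_e2
    return out


def manhattan_export(
    results: pd.DataFrame, chromosome_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Attach chromosome/position and -log10(p) for Manhattan plotting.

    ``chromosome_map`` has columns (marker, chromosome, position); markers
    absent from it (no genome alignment) are labelled chromosome "N" and
    given sequential pseudo-positions after the last mapped chromosome.
    Output is sorted by (chromosome, position), one row per input marker,
    with a Bonferroni-adjusted p-value column as a convenience extension.
    """
    if results.empty:
        raise ValueError("no association results to export")
    out = results.copy()
    if chromosome_map is not None:
        cmap = chromosome_map.set_index("marker")
        out["chromosome"] = [
            str(cmap.loc[mk, "chromosome"]) if mk in cmap.index else "N"
            for mk in out["marker"]
        ]
        out["position"] = [
            int(cmap.loc[mk, "position"]) if mk in cmap.index else -1
            for mk in out["marker"]
        ]
    else:
        out["chromosome"] = "N"
        out["position"] = -1
    unplaced = out["position"] < 0
    out.loc[unplaced, "position"] = np.arange(1, int(unplaced.sum()) + 1)
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out["p_bonferroni"] = np.minimum(out["p_value"] * len(out), 1.0)
    chrom_order = sorted(c for c in out["chromosome"].unique() if c != "N")
    order = {c: i for i, c in enumerate(chrom_order)}
    order["N"] = len(order)
    out["_ord"] = out["chromosome"].map(order)
    out = out.sort_values(["_ord", "position"], kind="stable").drop(columns="_ord")
    return out.reset_index(drop=True)


def plot_manhattan(table: pd.DataFrame, ax=None):
    """Manhattan plot of a `manhattan_export` table; returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(table.groupby("chromosome", sort=False)):
        x = grp["position"].to_numpy() + offset
        ax.scatter(x, grp["neg_log10_p"], s=6,
                   color=["#3b6ea5", "#9aa5b1"][i % 2])
        ticks.append(x.mean())
        labels.append(chrom)
        offset = x.max() + 1
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax
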