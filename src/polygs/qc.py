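"""Missing-data filtering, genotype imputation and marker QC.

Pipeline order follows the study design for unordered GBS markers:
``filter_missing`` (drop markers whose missing rate exceeds a fixed
threshold from the grid 10-70 %), then ``impute`` (MNI mean imputation,
SVDI singular-value-decomposition regression, or RFI iterative random-forest
imputation), then ``filter_maf`` (drop markers with minor allele frequency
below 2.5 %).  ``build_common`` intersects two jointly-called matrices by
SNP name to form the COMMON panel used for cross-population prediction.

All imputers leave observed entries untouched and discretize imputed values
to the closest code in {0, 1, 2}; ties round toward the heterozygote, which
absorbs three of the five underlying tetraploid dosage classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix

__all__ = [
    "MISSING_THRESHOLDS",
    "IMPUTERS",
    "filter_missing",
    "impute",
    "filter_maf",
    "build_common",
    "allele_freq",
    "qc_pipeline",
]

MISSING_THRESHOLDS = (0.10, 0.20, 0.30, 0.40, 0.50, 0.70)
IMPUTERS = ("MNI", "SVDI", "RFI")
# REF is a synthetic stand-in for a haplotype-order-based reference imputer:
# marker columns are randomly re-ordered before mean imputation and restored
# afterwards.  Column-wise imputation is order-invariant, so REF equals MNI by
# construction — it exists to keep the 4-imputer benchmark grid shape and to
# demonstrate that marker order carries no information for unordered panels.
GRID_IMPUTERS = IMPUTERS + ("REF",)


class QcError(ValueError):
    pass


def filter_missing(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep markers whose missing rate is <= ``threshold`` (strictly greater
    excluded); individuals are untouched."""
    if not 0.0 < threshold < 1.0:
        raise QcError(f"missing threshold must lie in (0, 1), got {threshold}")
    rates = G.missing_rate()
    keep = np.nonzero(rates <= threshold + 1e-12)[0]
    return G.select_markers(keep)


def allele_freq(G: GenotypeMatrix) -> np.ndarray:
    """Per-marker alternate-allele frequency p = mean(code)/2 over observed."""
    codes = np.ma.masked_equal(G.codes, MISSING)
    return np.asarray(codes.mean(axis=0) / 2.0)


def filter_maf(G: GenotypeMatrix, maf_min: float = 0.025) -> GenotypeMatrix:
    """Keep markers with minor allele frequency >= ``maf_min`` (default 2.5 %)."""
    if not 0.0 <= maf_min <= 0.5:
        raise QcError("maf_min must lie in [0, 0.5]")
    p = allele_freq(G)
    maf = np.minimum(p, 1.0 - p)
    keep = np.nonzero(maf >= maf_min - 1e-12)[0]
    return G.select_markers(keep)


def _discretize(values: np.ndarray) -> np.ndarray:
    """Round to the closest of {0, 1, 2}; exact ties go to the heterozygote."""
    v = np.clip(values, 0.0, 2.0)
    out = np.where(v < 0.5, 0, np.where(v <= 1.5, 1, 2))  # ties at .5/1.5 -> 1
    return out.astype(np.int8)


def _col_means(codes: np.ndarray) -> np.ndarray:
    masked = np.ma.masked_equal(codes, MISSING)
    means = masked.mean(axis=0)
    if np.ma.is_masked(means) and means.mask.any():
        raise QcError("marker with no observed values; filter before imputing")
    return np.asarray(means, dtype=float)


def _impute_mni(codes: np.ndarray) -> np.ndarray:
    means = _col_means(codes)
    out = codes.astype(np.int8).copy()
    miss = codes == MISSING
    fill = _discretize(np.broadcast_to(means, codes.shape)[miss])
    out[miss] = fill
    return out


def _impute_svdi(codes: np.ndarray, k: int = 10) -> np.ndarray:
    """SVD-regression imputation.

    Mean-fill the matrix, take the k leading marker eigenvectors (rows of
    V^T), and re-estimate each marker's missing cells by ordinary least
    squares of that marker on the k eigenvector coordinates of the
    individuals, using only its observed rows.
    """
    n, m = codes.shape
    means = _col_means(codes)
    X = np.where(codes == MISSING, means[None, :], codes).astype(float)
    Xc = X - X.mean(axis=0)
    k_eff = min(k, np.linalg.matrix_rank(Xc)) or 1
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k_eff] * s[:k_eff]  # individual coordinates on top axes
    out = codes.astype(np.int8).copy()
    for j in range(m):
        miss = codes[:, j] == MISSING
        if not miss.any():
            continue
        obs = ~miss
        A = np.column_stack([np.ones(obs.sum()), scores[obs]])
        beta, *_ = np.linalg.lstsq(A, codes[obs, j].astype(float), rcond=None)
        pred = np.column_stack([np.ones(miss.sum()), scores[miss]]) @ beta
        out[miss, j] = _discretize(pred)
    return out


def _impute_rfi(
    codes: np.ndarray,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    tol_changed: float = 0.005,
) -> np.ndarray:
    """Iterative marker-wise random-forest imputation (missForest scheme).

    Markers are visited in order of increasing missingness; each marker with
    missing cells is regressed on all other markers (current imputed state)
    with a 100-tree random forest, and its missing cells are replaced by the
    forest predictions.  Iteration stops when fewer than ``tol_changed`` of
    the imputed cells change between sweeps, or at ``max_iter`` sweeps.
    """
    from sklearn.ensemble import RandomForestRegressor

    n, m = codes.shape
    miss = codes == MISSING
    n_missing = int(miss.sum())
    if n_missing == 0:
        return codes.astype(np.int8).copy()
    means = _col_means(codes)
    X = np.where(miss, means[None, :], codes).astype(float)
    order = np.argsort(miss.sum(axis=0))
    rng = np.random.default_rng(seed)
    prev_fill = None
    for it in range(max_iter):
        for j in order:
            mj = miss[:, j]
            if not mj.any():
                continue
            others = np.delete(np.arange(m), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=1.0 / 3.0,
                min_samples_leaf=5,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[~mj][:, others], X[~mj, j])
            X[mj, j] = rf.predict(X[mj][:, others])
        fill = _discretize(X[miss])
        if prev_fill is not None and (fill != prev_fill).mean() < tol_changed:
            prev_fill = fill
            break
        prev_fill = fill
    out = codes.astype(np.int8).copy()
    out[miss] = prev_fill
    return out


def impute(
    G: GenotypeMatrix,
    method: str = "MNI",
    params: dict | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Impute missing genotypes with MNI, SVDI or RFI (see module docstring).

    Returns a complete matrix; observed entries are bit-identical to the
    input.  ``params`` passes method-specific settings (SVDI: ``k``; RFI:
    ``n_trees``, ``max_iter``).
    """
    params = dict(params or {})
    method = method.upper()
    if not np.any(G.codes == MISSING):
        return G.copy()
    if method == "MNI":
        codes = _impute_mni(G.codes)
    elif method == "REF":
        perm = np.random.default_rng(seed).permutation(G.n_markers)
        inv = np.argsort(perm)
        codes = _impute_mni(G.codes[:, perm])[:, inv]
    elif method == "SVDI":
        codes = _impute_svdi(G.codes, k=int(params.pop("k", 10)))
    elif method == "RFI":
        codes = _impute_rfi(
            G.codes,
            n_trees=int(params.pop("n_trees", 100)),
            max_iter=int(params.pop("max_iter", 10)),
            seed=seed,
        )
    else:
        raise QcError(f"unknown imputer {method!r}; choose from {IMPUTERS}")
    out = G.copy()
    out.codes = codes
    return out


def build_common(
    G_a: GenotypeMatrix, G_b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict two matrices to their shared SNP names, in identical order.

    Requires jointly-called (name-compatible) inputs; raises if the
    intersection is empty.
    """
    shared = [name for name in G_a.marker_names if name in set(G_b.marker_names)]
    if not shared:
        raise QcError("COMMON marker set is empty: no shared SNP names")
    idx_a = [G_a.marker_names.index(n) for n in shared]
    pos_b = {n: i for i, n in enumerate(G_b.marker_names)}
    idx_b = [pos_b[n] for n in shared]
    return G_a.select_markers(idx_a), G_b.select_markers(idx_b)


def qc_pipeline(
    G: GenotypeMatrix,
    threshold: float,
    imputer: str,
    maf_min: float = 0.025,
    imputer_params: dict | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """filter_missing -> impute -> filter_maf, with a per-stage marker ledger."""
    stages = [("input", G.n_markers)]
    G1 = filter_missing(G, threshold)
    stages.append(("missing_filter", G1.n_markers))
    if G1.n_markers == 0:
        warnings.warn("no markers survive the missing-data filter")
        return G1, pd.DataFrame(stages, columns=["stage", "n_markers"])
    G2 = impute(G1, imputer, imputer_params, seed=seed)
    stages.append(("imputed", G2.n_markers))
    G3 = filter_maf(G2, maf_min)
    stages.append(("maf_filter", G3.n_markers))
    return G3, pd.DataFrame(stages, columns=["stage", "n_markers"])
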