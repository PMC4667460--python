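"""Whole-genome prediction models with a uniform Model/Results contract.

Seven predictors of a quantitative phenotype from a complete {0,1,2} marker
matrix, all built the same way::

    res = RidgeBLUP(y, G).fit()          # -> Results object
    y_hat = res.predict(G_new)
    print(res.summary())

Linear mixed / Bayesian whole-genome regressions (additive model
``y = mu + G u + e``):

* :class:`RidgeBLUP` — ridge-regression BLUP.  The ridge parameter
  ``lambda = sigma2_e / sigma2_u`` is estimated by restricted maximum
  likelihood via a spectral decomposition of GG', and marker effects come
  from the closed form ``u_hat = G'(GG' + lambda I)^-1 (y - mu)``.
* :class:`BayesA` — Gibbs sampler with marker-specific scaled-inverse-chi2
  effect variances (scaled-t shrinkage).
* :class:`BayesB` — as BayesA plus a point mass at zero with prior inclusion
  probability ``1 - pi0`` (variable selection).
* :class:`BayesianLasso` — double-exponential shrinkage via the
  exponential-mixture (Park & Casella) hierarchy.

Machine-learning predictors (fitted through scikit-learn):

* :class:`SVRLinear`, :class:`SVRGaussian` — epsilon-insensitive support
  vector regression, defaults C = 1, epsilon = 0.1; the Gaussian bandwidth
  follows the median pairwise-distance heuristic.
* :class:`RandomForestModel` — bagged regression trees, defaults 500 trees,
  mtry = ceil(p/3), minimum node size 5.

Marker columns are centered internally before the linear fits (the intercept
absorbs the means); predictions re-add the intercept, so coding conventions
cancel.  All stochastic fits are reproducible given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MODEL_TAGS",
    "RidgeBLUP",
    "BayesA",
    "BayesB",
    "BayesianLasso",
    "SVRLinear",
    "SVRGaussian",
    "RandomForestModel",
    "get_model",
    "fit_model",
]


def _as_xy(endog, exog) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(endog, dtype=float).ravel()
    G = np.asarray(exog, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.shape[0]:
        raise ValueError("exog must be n x p with n matching endog")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(G)):
        raise ValueError("endog/exog must be finite (impute before fitting)")
    return y, G


class MarkerModel:
    """Base class: phenotype vector (endog) + marker matrix (exog)."""

    tag = "base"

    def __init__(self, endog, exog, marker_names=None):
        self.endog, self.exog = _as_xy(endog, exog)
        self.nobs, self.n_markers = self.exog.shape
        self.marker_names = (
            list(marker_names)
            if marker_names is not None
            else [f"M{j:05d}" for j in range(self.n_markers)]
        )

    @classmethod
    def from_dataframe(cls, df, phenotype_col, marker_cols=None, **kwargs):
        """Build a model from a tidy DataFrame (one row per individual)."""
        if marker_cols is None:
            marker_cols = [c for c in df.columns if c != phenotype_col]
        return cls(df[phenotype_col].to_numpy(), df[marker_cols].to_numpy(),
                   marker_names=marker_cols, **kwargs)

    @classmethod
    def from_genotype_matrix(cls, gmat, y, **kwargs):
        """Build a model from a :class:`~polygs.simdata.GenotypeMatrix`."""
        return cls(y, gmat.codes.astype(float), marker_names=gmat.marker_names, **kwargs)

    def fit(self, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class MarkerModelResults:
    """Fitted predictor: intercept, effects (or machine state), predict()."""

    model: MarkerModel
    mu: float
    effects: np.ndarray | None  # per-marker additive effects (linear models)
    col_means: np.ndarray | None
    hyperparams: dict = field(default_factory=dict)
    machine: Any = None  # opaque predictor state (kernel / tree models)
    extras: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        """Intercept followed by marker effects (linear models)."""
        if self.effects is None:
            raise AttributeError(f"{self.model.tag} has no explicit marker effects")
        return np.concatenate([[self.mu], self.effects])

    def predict(self, exog=None) -> np.ndarray:
        G = self.model.exog if exog is None else np.asarray(exog, dtype=float)
        if self.machine is not None:
            return np.asarray(self.machine.predict(G), dtype=float)
        Gc = G - self.col_means[None, :]
        return self.mu + Gc @ self.effects

    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def summary(self) -> str:
        lines = [
            f"{self.model.tag} whole-genome prediction",
            "=" * 44,
            f"No. individuals: {self.model.nobs:>10d}",
            f"No. markers:     {self.model.n_markers:>10d}",
            f"Intercept (mu):  {self.mu:>10.4f}",
        ]
        for k, v in self.hyperparams.items():
            lines.append(f"{k + ':':<17}{v!r:>10}")
        if self.effects is not None:
            top = np.argsort(-np.abs(self.effects))[:5]
            lines.append("Largest |effects|:")
            for j in top:
                lines.append(f"  {self.model.marker_names[j]:<14}{self.effects[j]:>10.4f}")
        r = np.corrcoef(self.fittedvalues(), self.model.endog)[0, 1]
        lines.append(f"In-sample r:     {r:>10.4f}")
        return "\n".join(lines)

    # -- JSON container ----------------------------------------------------
    def to_json(self) -> str:
        if self.effects is None:
            raise NotImplementedError(
                f"{self.model.tag} stores an opaque machine; only linear fits "
                "serialize to the JSON container"
            )
        return json.dumps(
            {
                "model_tag": self.model.tag,
                "mu": self.mu,
                "effects": self.effects.tolist(),
                "col_means": self.col_means.tolist(),
                "marker_names": self.model.marker_names,
                "hyperparams": {k: _jsonable(v) for k, v in self.hyperparams.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MarkerModelResults":
        d = json.loads(text)
        model = MarkerModel(np.zeros(1), np.zeros((1, len(d["effects"]))),
                            marker_names=d["marker_names"])
        model.tag = d["model_tag"]
        return cls(
            model=model,
            mu=float(d["mu"]),
            effects=np.asarray(d["effects"], dtype=float),
            col_means=np.asarray(d["col_means"], dtype=float),
            hyperparams=d.get("hyperparams", {}),
        )


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# Ridge-regression BLUP


class RidgeBLUP(MarkerModel):
    """Ridge-regression BLUP of marker effects (see module docstring)."""

    tag = "rrBLUP"

    def fit(self, lam: float | None = None) -> MarkerModelResults:
        """Fit; ``lam`` fixes the ridge parameter, otherwise REML estimates it.

        REML maximizes the restricted log-likelihood of the variance ratio
        over the spectrum of GG' (one eigendecomposition, then 1-D bounded
        optimization of log lambda).
        """
        if self.nobs < 3:
            raise ValueError("rrBLUP needs at least 3 individuals")
        y, G = self.endog, self.exog
        col_means = G.mean(axis=0)
        Gc = G - col_means[None, :]
        mu = float(y.mean())
        if np.var(y) == 0.0:
            warnings.warn("zero-variance phenotype: all marker effects are 0")
            return MarkerModelResults(self, mu, np.zeros(self.n_markers), col_means,
                                      {"lambda": np.inf})
        K = Gc @ Gc.T
        extras: dict = {}
        if lam is None:
            lam, extras = _reml_lambda(y, K)
        u = Gc.T @ np.linalg.solve(K + lam * np.eye(self.nobs), y - mu)
        return MarkerModelResults(
            self, mu, u, col_means, {"lambda": float(lam)}, extras=extras
        )


def _reml_lambda(y: np.ndarray, K: np.ndarray) -> tuple[float, dict]:
    """REML estimate of lambda = sigma2_e/sigma2_u for y = 1 mu + g + e,
    g ~ N(0, sigma2_u K), via the spectral decomposition of K."""
    n = len(y)
    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = 1.0 / (d + lam)
        xwx = np.sum(w * xt * xt)
        mu = np.sum(w * xt * yt) / xwx
        resid = yt - mu * xt
        rss = np.sum(w * resid * resid)
        sigma_u2 = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2 * np.pi * sigma_u2)
            + np.sum(np.log(d + lam))
            + np.log(xwx)
            + (n - 1)
        )
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0),
                                   method="bounded", options={"xatol": 1e-6})
    lam = float(np.exp(res.x))
    w = 1.0 / (d + lam)
    xwx = np.sum(w * xt * xt)
    mu = float(np.sum(w * xt * yt) / xwx)
    resid = yt - mu * xt
    sigma_u2 = float(np.sum(w * resid * resid) / (n - 1))
    return lam, {
        "sigma2_u": sigma_u2,
        "sigma2_e": sigma_u2 * lam,
        "reml_loglik": -res.fun,
        "gls_mu": mu,
    }


# ---------------------------------------------------------------------------
# Bayesian whole-genome regressions (Gibbs samplers)


class _GibbsBase(MarkerModel):
    """Shared chain driver for the Bayesian alphabet.

    Defaults follow the study settings: 5000 iterations, 500 burn-in,
    thinning 5.  Hyper-prior scales are solved from the usual
    proportion-of-variance heuristic with R2 = 0.5.
    """

    r2_prior = 0.5
    nu_e = 4.0

    def fit(self, n_iter: int = 5000, burn_in: int = 500, thin: int = 5,
            seed: int = 0, **prior_kwargs) -> MarkerModelResults:
        if n_iter <= 0 or burn_in < 0 or thin <= 0 or burn_in >= n_iter:
            raise ValueError("require 0 <= burn_in < n_iter and thin >= 1")
        y, G = self.endog, self.exog
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype")
        rng = np.random.default_rng(seed)
        col_means = G.mean(axis=0)
        Gc = np.asfortranarray(G - col_means[None, :])
        n, p = Gc.shape
        cj = np.einsum("ij,ij->j", Gc, Gc)
        active = cj > 1e-12  # monomorphic columns get no update (effect 0)
        vy = float(np.var(y))
        if vy == 0.0:
            warnings.warn("zero-variance phenotype: posterior effects are 0")
            return MarkerModelResults(self, float(y[0]), np.zeros(p), col_means, {})
        state = self._init_state(rng, p, vy, cj, **prior_kwargs)
        mu = float(y.mean())
        beta = np.zeros(p)
        e = y - mu
        sigma_e2 = vy * (1 - self.r2_prior)
        s_e = vy * (1 - self.r2_prior) * (self.nu_e + 2)  # prior scale * nu
        sum_beta = np.zeros(p)
        sum_mu = 0.0
        n_kept = 0
        extras_acc = self._init_extras(p)
        for it in range(n_iter):
            # intercept
            e += mu
            mu = rng.normal(e.mean(), np.sqrt(sigma_e2 / n))
            e -= mu
            # marker effects
            self._update_effects(rng, Gc, cj, active, beta, e, sigma_e2, state)
            # residual variance (scaled-inverse-chi2)
            sse = float(e @ e)
            sigma_e2 = (sse + s_e) / rng.chisquare(n + self.nu_e)
            self._update_hyper(rng, beta, sigma_e2, state)
            if it >= burn_in and (it - burn_in) % thin == 0:
                sum_beta += beta
                sum_mu += mu
                n_kept += 1
                self._accumulate(extras_acc, state)
        effects = sum_beta / n_kept
        hyper = {"n_iter": n_iter, "burn_in": burn_in, "thin": thin, "seed": seed}
        hyper.update(self._report_hyper(state))
        extras = self._finalize_extras(extras_acc, n_kept)
        return MarkerModelResults(self, sum_mu / n_kept, effects, col_means,
                                  hyper, extras=extras)

    # hooks -----------------------------------------------------------------
    def _init_state(self, rng, p, vy, cj, **kwargs) -> dict:
        raise NotImplementedError

    def _update_effects(self, rng, Gc, cj, active, beta, e, sigma_e2, state):
        raise NotImplementedError

    def _update_hyper(self, rng, beta, sigma_e2, state):
        pass

    def _report_hyper(self, state) -> dict:
        return {}

    def _init_extras(self, p) -> dict:
        return {}

    def _accumulate(self, acc, state):
        pass

    def _finalize_extras(self, acc, n_kept) -> dict:
        return {}


class BayesA(_GibbsBase):
    """Marker-specific variances with a scaled-inverse-chi2 prior (scaled-t)."""

    tag = "BayesA"

    def _init_state(self, rng, p, vy, cj, nu_beta: float = 4.2, scale_beta: float | None = None):
        if scale_beta is None:
            # proportion-of-variance heuristic: the prior mean of the summed
            # marker variance matches R2 * var(y)
            msx = max(float(np.sum(cj)) / self.nobs, 1e-12)  # sum of column variances
            scale_beta = self.r2_prior * vy * (nu_beta - 2) / (nu_beta * msx)
            scale_beta = max(scale_beta, 1e-10)
        return {
            "nu_beta": nu_beta,
            "s_beta": scale_beta * nu_beta,
            "sigma_j2": np.full(p, max(scale_beta, 1e-8)),
        }

    def _update_effects(self, rng, Gc, cj, active, beta, e, sigma_e2, state):
        sigma_j2 = state["sigma_j2"]
        for j in np.nonzero(active)[0]:
            xj = Gc[:, j]
            rj = xj @ e + cj[j] * beta[j]
            prec = cj[j] + sigma_e2 / sigma_j2[j]
            mean = rj / prec
            new = rng.normal(mean, np.sqrt(sigma_e2 / prec))
            e += xj * (beta[j] - new)
            beta[j] = new

    def _update_hyper(self, rng, beta, sigma_e2, state):
        chi = rng.chisquare(state["nu_beta"] + 1, size=len(beta))
        state["sigma_j2"] = (beta**2 + state["s_beta"]) / chi


class BayesB(BayesA):
    """BayesA slab plus a point mass at zero (prior inclusion 1 - pi0)."""

    tag = "BayesB"

    def _init_state(self, rng, p, vy, cj, nu_beta: float = 4.2,
                    scale_beta: float | None = None, pi0: float = 0.95):
        state = super()._init_state(rng, p, vy, cj, nu_beta, scale_beta)
        if not 0.0 <= pi0 < 1.0:
            raise ValueError("pi0 must lie in [0, 1)")
        # rescale the slab for the reduced number of non-zero effects
        state["s_beta"] /= max(1.0 - pi0, 1e-3)
        state["pi0"] = pi0
        state["included"] = np.zeros(p, dtype=bool)
        return state

    def _update_effects(self, rng, Gc, cj, active, beta, e, sigma_e2, state):
        sigma_j2 = state["sigma_j2"]
        pi0 = state["pi0"]
        incl = state["included"]
        log_prior_odds = np.log((1 - pi0) / pi0) if pi0 > 0 else np.inf
        for j in np.nonzero(active)[0]:
            xj = Gc[:, j]
            rj = xj @ e + cj[j] * beta[j]
            v0 = cj[j] * sigma_e2
            v1 = v0 + cj[j] ** 2 * sigma_j2[j]
            log_bf = 0.5 * (np.log(v0 / v1) + rj * rj * (1.0 / v0 - 1.0 / v1))
            prob1 = 1.0 / (1.0 + np.exp(-(log_prior_odds + log_bf)))
            if rng.uniform() < prob1:
                prec = cj[j] + sigma_e2 / sigma_j2[j]
                new = rng.normal(rj / prec, np.sqrt(sigma_e2 / prec))
                incl[j] = True
            else:
                new = 0.0
                incl[j] = False
            e += xj * (beta[j] - new)
            beta[j] = new

    def _update_hyper(self, rng, beta, sigma_e2, state):
        nu, s = state["nu_beta"], state["s_beta"]
        incl = state["included"]
        chi_in = rng.chisquare(nu + 1, size=int(incl.sum()))
        state["sigma_j2"][incl] = (beta[incl] ** 2 + s) / chi_in
        n_out = int((~incl).sum())
        if n_out:
            state["sigma_j2"][~incl] = s / rng.chisquare(nu, size=n_out)

    def _init_extras(self, p):
        return {"incl": np.zeros(p)}

    def _accumulate(self, acc, state):
        acc["incl"] += state["included"]

    def _finalize_extras(self, acc, n_kept):
        return {"inclusion_prob": acc["incl"] / n_kept}


class BayesianLasso(_GibbsBase):
    """Double-exponential shrinkage via the exponential-mixture hierarchy."""

    tag = "BayesLasso"

    def _init_state(self, rng, p, vy, cj, lambda2: float | None = None,
                    rate_shape: float = 1.0, rate_rate: float = 1e-3):
        if lambda2 is None:
            msx = max(float(np.mean(cj)), 1e-12)
            lambda2 = 2 * (1 - self.r2_prior) / self.r2_prior * msx / 2
            lambda2 = max(lambda2, 1e-6)
        return {
            "tau2": np.full(p, 1.0),
            "lambda2": float(lambda2),
            "rate_shape": rate_shape,
            "rate_rate": rate_rate,
        }

    def _update_effects(self, rng, Gc, cj, active, beta, e, sigma_e2, state):
        tau2 = state["tau2"]
        for j in np.nonzero(active)[0]:
            xj = Gc[:, j]
            rj = xj @ e + cj[j] * beta[j]
            prec = cj[j] + 1.0 / tau2[j]
            new = rng.normal(rj / prec, np.sqrt(sigma_e2 / prec))
            e += xj * (beta[j] - new)
            beta[j] = new

    def _update_hyper(self, rng, beta, sigma_e2, state):
        lam2 = state["lambda2"]
        b2 = np.maximum(beta**2, 1e-12)
        # tau_j^-2 | . ~ Inverse-Gaussian(sqrt(lam2 sigma_e2 / beta_j^2), lam2)
        mu_ig = np.sqrt(lam2 * sigma_e2 / b2)
        inv_tau2 = stats.invgauss.rvs(mu_ig / lam2, scale=lam2,
                                      random_state=rng)
        state["tau2"] = 1.0 / np.maximum(inv_tau2, 1e-12)
        p = len(beta)
        shape = p + state["rate_shape"]
        rate = np.sum(state["tau2"]) / 2.0 + state["rate_rate"]
        state["lambda2"] = float(rng.gamma(shape, 1.0 / rate))

    def _report_hyper(self, state):
        return {"lambda2": state["lambda2"]}


# ---------------------------------------------------------------------------
# Kernel / tree machines (scikit-learn backed)


class SVRLinear(MarkerModel):
    """Epsilon-insensitive SVR, linear kernel (defaults C = 1, eps = 0.1)."""

    tag = "SVR-lin"
    kernel = "linear"

    def fit(self, C: float = 1.0, epsilon: float = 0.1, tol: float = 1e-3,
            **kwargs) -> MarkerModelResults:
        from sklearn.svm import SVR

        params = {"C": C, "epsilon": epsilon, "tol": tol}
        machine = SVR(kernel=self.kernel, C=C, epsilon=epsilon, tol=tol,
                      **self._kernel_kwargs(params), **kwargs)
        machine.fit(self.exog, self.endog)
        effects = col_means = None
        if self.kernel == "linear":
            # the primal weight vector is recoverable: expose it as effects
            effects = np.asarray(machine.coef_).ravel()
        return MarkerModelResults(self, float(machine.intercept_[0]),
                                  effects, col_means, params, machine=machine)

    def _kernel_kwargs(self, params: dict) -> dict:
        return {}


class SVRGaussian(SVRLinear):
    """Epsilon-insensitive SVR with a Gaussian kernel.

    The bandwidth follows the median heuristic: gamma = 1 / (2 sigma^2) with
    sigma the median pairwise Euclidean distance between training rows.
    """

    tag = "SVR-gau"
    kernel = "rbf"

    def _kernel_kwargs(self, params: dict) -> dict:
        from scipy.spatial.distance import pdist

        d = pdist(self.exog)
        sigma = np.median(d[d > 0]) if np.any(d > 0) else 1.0
        gamma = 1.0 / (2.0 * sigma**2)
        params["gamma"] = float(gamma)
        return {"gamma": float(gamma)}


class RandomForestModel(MarkerModel):
    """Bagged regression trees: 500 trees, mtry = ceil(p/3), node size 5."""

    tag = "RFR"

    def fit(self, n_trees: int = 500, mtry: int | None = None,
            min_node: int = 5, seed: int = 0) -> MarkerModelResults:
        from sklearn.ensemble import RandomForestRegressor

        if mtry is None:
            mtry = int(np.ceil(self.n_markers / 3))
        machine = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=min(mtry, self.n_markers),
            min_samples_leaf=min_node,
            random_state=seed,
            n_jobs=1,
        )
        machine.fit(self.exog, self.endog)
        params = {"n_trees": n_trees, "mtry": mtry, "min_node": min_node, "seed": seed}
        return MarkerModelResults(self, float(np.mean(self.endog)), None, None,
                                  params, machine=machine)


# ---------------------------------------------------------------------------
# Registry

MODEL_TAGS = {
    "rrBLUP": RidgeBLUP,
    "BayesA": BayesA,
    "BayesB": BayesB,
    "BayesLasso": BayesianLasso,
    "SVR-lin": SVRLinear,
    "SVR-gau": SVRGaussian,
    "RFR": RandomForestModel,
}

_SEEDED = {"BayesA", "BayesB", "BayesLasso", "RFR"}


def get_model(tag: str) -> type[MarkerModel]:
    try:
        return MODEL_TAGS[tag]
    except KeyError:
        raise ValueError(f"unknown model tag {tag!r}; choose from {sorted(MODEL_TAGS)}")


def fit_model(tag: str, G, y, seed: int = 0, **params) -> MarkerModelResults:
    """One-call fit: look up the model class by tag, seed it if stochastic."""
    cls = get_model(tag)
    model = cls(y, G)
    if tag in _SEEDED:
        params.setdefault("seed", seed)
    return model.fit(**params)
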