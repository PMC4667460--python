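"""Model/Results contracts for the seven whole-genome predictors."""

import inspect

import numpy as np
import pytest
from scipy import optimize

from polygs.models import (
    BayesA,
    BayesB,
    BayesianLasso,
    MarkerModelResults,
    RandomForestModel,
    RidgeBLUP,
    SVRGaussian,
    SVRLinear,
    fit_model,
)


class TestRidgeBLUP:
    def test_constant_phenotype_gives_zero_effects(self):
        G = np.random.default_rng(0).integers(0, 3, (10, 6)).astype(float)
        with pytest.warns(UserWarning):
            res = RidgeBLUP(np.full(10, 3.0), G).fit()
        np.testing.assert_array_equal(res.effects, 0.0)
        np.testing.assert_allclose(res.predict(G), 3.0)

    @pytest.mark.parametrize("n,p", [(5, 3), (10, 8), (20, 50)])
    @pytest.mark.parametrize("lam", [0.1, 1.0, 10.0])
    def test_fixed_lambda_matches_primal_ridge_solve(self, n, p, lam):
        rng = np.random.default_rng(n * p)
        G = rng.integers(0, 3, (n, p)).astype(float)
        y = rng.normal(size=n)
        res = RidgeBLUP(y, G).fit(lam=lam)
        Gc = G - G.mean(axis=0)
        beta = np.linalg.solve(Gc.T @ Gc + lam * np.eye(p), Gc.T @ (y - y.mean()))
        np.testing.assert_allclose(res.effects, beta, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, (15, 10)).astype(float)
        y = rng.normal(size=15)
        res = RidgeBLUP(y, G).fit(lam=1e12)
        assert np.linalg.norm(res.effects) < 1e-6

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            RidgeBLUP(np.zeros(2), np.zeros((2, 3))).fit()

    def test_marker_effect_and_kinship_forms_agree(self, toy_matrix):
        # rrBLUP/GBLUP duality: predictions via u_hat equal predictions via
        # the equivalent GG'-based mixed model with the same lambda
        G, y = toy_matrix
        lam = 2.5
        res = RidgeBLUP(y, G).fit(lam=lam)
        Gc = G - G.mean(axis=0)
        K = Gc @ Gc.T
        rng = np.random.default_rng(3)
        Gnew = rng.integers(0, 3, (7, G.shape[1])).astype(float)
        Knew = (Gnew - G.mean(axis=0)) @ Gc.T
        pred_kinship = y.mean() + Knew @ np.linalg.solve(K + lam * np.eye(len(y)), y - y.mean())
        np.testing.assert_allclose(res.predict(Gnew), pred_kinship, atol=1e-6)

    def test_reml_recovers_variance_ratio_scale(self, small_population):
        G, truth, y = small_population
        res = RidgeBLUP(y, G.codes.astype(float)).fit()
        assert res.hyperparams["lambda"] > 0
        assert res.extras["sigma2_u"] > 0
        r = np.corrcoef(res.fittedvalues(), y)[0, 1]
        assert r > 0.5


class TestBayesianAlphabet:
    @pytest.mark.parametrize("cls", [BayesA, BayesB, BayesianLasso])
    def test_zero_variance_phenotype_gives_null_effects(self, cls):
        G = np.random.default_rng(2).integers(0, 3, (12, 8)).astype(float)
        with pytest.warns(UserWarning):
            res = cls(np.ones(12), G).fit(n_iter=200, burn_in=50, seed=1)
        assert np.max(np.abs(res.effects)) < 0.01

    def test_default_chain_settings(self):
        sig = inspect.signature(BayesA.fit)
        assert sig.parameters["n_iter"].default == 5000
        assert sig.parameters["burn_in"].default == 500
        assert sig.parameters["thin"].default == 5

    def test_bayesb_ranks_large_qtl_top(self):
        rng = np.random.default_rng(7)
        n, m = 300, 200
        G = rng.binomial(2, 0.5, (n, m)).astype(float)
        qtl = np.array([10, 50, 90, 130, 170])
        beta = np.array([2.0, -2.0, 1.5, -1.5, 2.0])
        g = G[:, qtl] @ beta
        y = g + rng.normal(scale=np.sqrt(np.var(g) * 0.25), size=n)  # h2 = 0.8
        res = BayesB(y, G).fit(n_iter=1500, burn_in=300, thin=5, seed=1)
        top5 = set(np.argsort(-np.abs(res.effects))[:5])
        assert len(top5 & set(qtl)) >= 4

    @pytest.mark.parametrize("cls", [BayesA, BayesB, BayesianLasso])
    def test_chain_deterministic_given_seed(self, cls, toy_matrix):
        G, y = toy_matrix
        a = cls(y, G).fit(n_iter=300, burn_in=50, seed=4)
        b = cls(y, G).fit(n_iter=300, burn_in=50, seed=4)
        np.testing.assert_array_equal(a.effects, b.effects)

    def test_effects_shrink_as_noise_grows(self):
        rng = np.random.default_rng(9)
        n, m = 150, 60
        G = rng.binomial(2, 0.5, (n, m)).astype(float)
        beta = np.zeros(m)
        beta[:5] = 1.0
        g = G @ beta
        norms = []
        for noise_sd in (0.5, 2.0, 8.0):
            y = g + rng.normal(scale=noise_sd, size=n)
            # fixed prior scale so the comparison isolates the residual
            # variance (the default scale adapts to var(y))
            res = BayesA(y, G).fit(n_iter=600, burn_in=100, seed=2, scale_beta=0.05)
            norms.append(float(np.mean(np.abs(res.effects[:5]))))
        assert norms[0] > norms[1] > norms[2]

    def test_invalid_chain_settings_rejected(self, toy_matrix):
        G, y = toy_matrix
        with pytest.raises(ValueError):
            BayesA(y, G).fit(n_iter=100, burn_in=100)


class TestSVR:
    def test_defaults_are_c1_eps01(self):
        sig = inspect.signature(SVRLinear.fit)
        assert sig.parameters["C"].default == 1.0
        assert sig.parameters["epsilon"].default == 0.1

    def test_noiseless_fit_within_epsilon_tube(self):
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, (30, 3)).astype(float)
        y = G @ np.array([0.5, -0.3, 0.2])
        res = SVRLinear(y, G).fit(C=100.0, epsilon=0.1)
        assert np.max(np.abs(res.predict(G) - y)) <= 0.1 + 1e-6

    def test_linear_kernel_matches_qp_dual_solve(self):
        # independent oracle: solve the eps-SVR dual QP directly
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        C, eps = 1.0, 0.1
        n = len(y)
        K = X @ X.T

        def obj(z):
            a, astar = z[:n], z[n:]
            d = a - astar
            return 0.5 * d @ K @ d + eps * np.sum(a + astar) - y @ d

        cons = {"type": "eq", "fun": lambda z: np.sum(z[:n] - z[n:])}
        sol = optimize.minimize(obj, np.zeros(2 * n), bounds=[(0, C)] * 2 * n,
                                constraints=cons, method="SLSQP",
                                options={"maxiter": 2000, "ftol": 1e-12})
        d = sol.x[:n] - sol.x[n:]
        # intercept from a free support vector
        free = (np.abs(d) > 1e-6) & (np.abs(np.abs(d) - C) > 1e-6)
        i = int(np.argmax(free))
        b = y[i] - (K @ d)[i] - eps * np.sign(d[i])
        pred_qp = K @ d + b
        res = SVRLinear(y, X).fit(C=C, epsilon=eps, tol=1e-8)
        np.testing.assert_allclose(res.predict(X), pred_qp, atol=1e-4)

    def test_gaussian_bandwidth_median_heuristic_recorded(self, toy_matrix):
        G, y = toy_matrix
        res = SVRGaussian(y, G).fit()
        assert res.hyperparams["gamma"] > 0


class TestRandomForest:
    def test_constant_phenotype_predicts_constant(self):
        G = np.random.default_rng(6).integers(0, 3, (20, 5)).astype(float)
        res = RandomForestModel(np.full(20, 7.0), G).fit(n_trees=20, seed=1)
        np.testing.assert_allclose(res.predict(G), 7.0)

    def test_defaults(self):
        sig = inspect.signature(RandomForestModel.fit)
        assert sig.parameters["n_trees"].default == 500
        assert sig.parameters["min_node"].default == 5
        res = RandomForestModel(np.zeros(4), np.zeros((4, 10))).fit(n_trees=2)
        assert res.hyperparams["mtry"] == 4  # ceil(10/3)

    def test_deterministic_given_seed(self, toy_matrix):
        G, y = toy_matrix
        a = RandomForestModel(y, G).fit(n_trees=30, seed=3).predict(G)
        b = RandomForestModel(y, G).fit(n_trees=30, seed=3).predict(G)
        np.testing.assert_array_equal(a, b)


class TestResultsContract:
    def test_summary_mentions_model_and_sizes(self, toy_matrix):
        G, y = toy_matrix
        s = RidgeBLUP(y, G).fit().summary()
        assert "rrBLUP" in s and "20" in s and "50" in s

    def test_json_roundtrip_preserves_predictions(self, toy_matrix):
        G, y = toy_matrix
        res = RidgeBLUP(y, G).fit()
        clone = MarkerModelResults.from_json(res.to_json())
        np.testing.assert_allclose(clone.predict(G), res.predict(G), atol=1e-12)

    def test_opaque_machines_refuse_json(self, toy_matrix):
        G, y = toy_matrix
        res = RandomForestModel(y, G).fit(n_trees=5)
        with pytest.raises(NotImplementedError):
            res.to_json()

    def test_fit_model_registry_dispatch(self, toy_matrix):
        G, y = toy_matrix
        res = fit_model("rrBLUP", G, y)
        assert res.model.tag == "rrBLUP"
        with pytest.raises(ValueError):
            fit_model("GBLUP++", G, y)
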