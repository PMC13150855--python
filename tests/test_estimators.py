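"""Estimator ensemble: registry completeness, analytic ridge oracles,
marker/kinship equivalence, Gibbs-sampler behaviour and seeded determinism."""

import numpy as np
import pytest

from megs.estimators import (
    CATEGORIES,
    EstimatorSpec,
    get_estimator,
    mixed_solve,
    registry,
)


def ridge_oracle(X, y, lam):
    """Direct linear solve of (X'X + lam I) u = X'y."""
    q = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(q), X.T @ y)


@pytest.fixture
def toy_xy():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    y = np.array([1.0, 1.0, 2.0])
    return X, y


class TestRegistry:
    def test_fifteen_members(self):
        specs = registry()
        assert len(specs) == 15
        assert len({s.name for s in specs}) == 15

    def test_category_partition(self):
        from collections import Counter

        counts = Counter(CATEGORIES.values())
        assert counts["parametric"] == 10
        assert counts["semi-parametric"] == 2
        assert counts["non-parametric"] == 3

    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            get_estimator("DeepNet")

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ValueError, match="unknown hyper"):
            get_estimator(EstimatorSpec("RR", {"bogus": 1}))


class TestRidgeOracles:
    def test_rr_fixed_lambda_toy(self, toy_xy):
        X, y = toy_xy
        est = get_estimator(EstimatorSpec("RR", {"lam": 1.0, "intercept": False}))
        fit = est.fit(y, X=X)
        np.testing.assert_allclose(fit.marker_effects, [0.75, 0.75], atol=1e-12)
        np.testing.assert_allclose(fit.marker_effects, ridge_oracle(X, y, 1.0), atol=1e-12)

    def test_rrblup_fixed_lambda_matches_primal_ridge(self):
        """The dual (kinship-spectral) solve must agree with the primal
        (X'X + lam I) solve at the same fixed penalty."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        for lam in (0.1, 1.0, 10.0):
            est = get_estimator(EstimatorSpec("rrBLUP", {"lam": lam, "intercept": False}))
            fit = est.fit(y, X=X)
            np.testing.assert_allclose(fit.marker_effects, ridge_oracle(X, y, lam),
                                       atol=1e-8)

    def test_null_responses_give_null_effects(self, toy_xy):
        X, _ = toy_xy
        y = np.zeros(3)
        for name in ("RR", "rrBLUP", "LASSO", "EN"):
            spec = EstimatorSpec(name, {"lam": 1.0} if name in ("RR", "rrBLUP") else {"alpha": 0.1})
            est = get_estimator(spec, seed=0)
            fit = est.fit(y, X=X)
            np.testing.assert_allclose(fit.marker_effects, 0.0, atol=1e-10)
            assert fit.mu == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_recovery_with_vanishing_penalty(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 10))
        u_true = rng.normal(size=10)
        y = X @ u_true
        est = get_estimator(EstimatorSpec("rrBLUP", {"lam": 1e-10, "intercept": False}))
        fit = est.fit(y, X=X)
        assert np.max(np.abs(fit.marker_effects - u_true)) < 1e-6


class TestMarkerKinshipEquivalence:
    @pytest.mark.parametrize("trial", range(5))
    def test_rrblup_equals_gblup_on_crossproduct_kinship(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, p, n_new = 30, 50, 8
        X = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        X_new = rng.binomial(2, 0.4, size=(n_new, p)).astype(float)
        y = rng.normal(size=n)
        lam = float(rng.uniform(0.5, 5.0))
        rr = get_estimator(EstimatorSpec("rrBLUP", {"lam": lam}))
        gb = get_estimator(EstimatorSpec("GBLUP", {"lam": lam}))
        fit_rr = rr.fit(y, X=X)
        fit_gb = gb.fit(y, K=X @ X.T)
        pred_rr = rr.predict(fit_rr, X_new=X_new)
        pred_gb = gb.predict(fit_gb, K_cross=X_new @ X.T)
        assert np.max(np.abs(pred_rr - pred_gb)) < 1e-8

    def test_reml_lambda_agrees_between_forms(self):
        rng = np.random.default_rng(42)
        X = rng.binomial(2, 0.3, size=(35, 20)).astype(float)
        u = rng.normal(scale=0.4, size=20)
        y = 2.0 + X @ u + rng.normal(scale=0.5, size=35)
        fit_rr = get_estimator("rrBLUP").fit(y, X=X)
        fit_gb = get_estimator("GBLUP").fit(y, K=X @ X.T)
        assert fit_rr.variance_components["lam"] == pytest.approx(
            fit_gb.variance_components["lam"], rel=1e-6
        )


class TestPredictContract:
    def test_fitted_values_consistency(self, toy_xy):
        X, y = toy_xy
        est = get_estimator(EstimatorSpec("RR", {"lam": 1.0, "intercept": False}))
        fit = est.fit(y, X=X)
        np.testing.assert_allclose(est.predict(fit, X_new=X), X @ fit.marker_effects)

    def test_duplicate_rows_identical_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15)
        for name in ("rrBLUP", "SVM", "RF", "RKHS"):
            est = get_estimator(name, seed=4)
            fit = est.fit(y, X=X)
            X_new = np.vstack([X[:1], X[:1]])
            pred = est.predict(fit, X_new=X_new)
            assert pred[0] == pytest.approx(pred[1], abs=1e-12)

    def test_dimension_mismatch_names_expected(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        est = get_estimator(EstimatorSpec("RR", {"lam": 1.0}))
        fit = est.fit(y, X=X)
        with pytest.raises(ValueError, match="expected 5"):
            est.predict(fit, X_new=rng.normal(size=(3, 7)))

    def test_non_psd_kinship_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        est = get_estimator("GBLUP")
        with pytest.raises(ValueError, match="PSD"):
            est.fit(np.array([1.0, 2.0]), K=K)


class TestGibbsSamplers:
    def test_brr_fixed_variances_matches_analytic_ridge(self):
        """With both variances frozen the BRR posterior mean is the ridge
        solution at lam = sigma_e^2/sigma_u^2; Monte-Carlo agreement at 2%."""
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 1.0, 2.0])
        est = get_estimator(
            EstimatorSpec(
                "BRR",
                {"iters": 22000, "burnin": 2000, "thin": 1,
                 "fix_sigma_u2": 1.0, "fix_sigma_e2": 1.0, "intercept": False},
                seed=5,
            )
        )
        fit = est.fit(y, X=X)
        np.testing.assert_allclose(fit.marker_effects, [0.75, 0.75], rtol=0.02)

    @pytest.mark.parametrize("name", ["BayesA", "BayesB", "BayesC", "BL"])
    def test_alphabet_shrinks_toward_signal(self, name):
        """Each sampler must put most effect mass on the one causal marker
        in a tiny high-signal problem."""
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.5, size=(60, 8)).astype(float)
        y = 3.0 * X[:, 2] + rng.normal(scale=0.3, size=60)
        est = get_estimator(
            EstimatorSpec(name, {"iters": 1500, "burnin": 500, "thin": 2}, seed=11)
        )
        fit = est.fit(y, X=X)
        u = np.abs(fit.marker_effects)
        assert np.argmax(u) == 2
        assert u[2] > 2.0

    def test_half_chain_stability(self):
        """Geweke-style check: the two halves of the kept chain agree on
        the marker-effect means within Monte-Carlo error."""
        rng = np.random.default_rng(14)
        X = rng.binomial(2, 0.4, size=(50, 6)).astype(float)
        y = X @ np.array([1.0, 0.0, -0.5, 0.0, 0.2, 0.0]) + rng.normal(scale=0.4, size=50)
        est = get_estimator(EstimatorSpec("BRR", {"iters": 4000, "burnin": 1000, "thin": 2}, seed=3))
        fit = est.fit(y, X=X)
        h1, h2 = fit.diagnostics["u_half_means"]
        ve = fit.variance_components["sigma_e2"]
        mc_se = np.sqrt(ve) / np.sqrt(fit.diagnostics["n_kept"] / 2)
        assert np.max(np.abs(h1 - h2)) < 3 * max(mc_se, 0.05)


class TestDeterminism:
    @pytest.mark.parametrize("name", sorted(CATEGORIES))
    def test_same_seed_same_output(self, name):
        rng = np.random.default_rng(77)
        X = rng.binomial(2, 0.4, size=(30, 10)).astype(float)
        y = X @ rng.normal(scale=0.5, size=10) + rng.normal(scale=0.5, size=30)
        X_new = rng.binomial(2, 0.4, size=(6, 10)).astype(float)
        fast = {
            "BayesA": {"iters": 300, "burnin": 100},
            "BayesB": {"iters": 300, "burnin": 100},
            "BayesC": {"iters": 300, "burnin": 100},
            "BRR": {"iters": 300, "burnin": 100},
            "BL": {"iters": 300, "burnin": 100},
            "RF": {"n_trees": 50},
            "GBM": {"n_rounds": 50},
        }
        spec = EstimatorSpec(name, fast.get(name, {}), seed=123)

        def run():
            est = get_estimator(spec)
            fit = est.fit(y, X=X)
            if name == "GBLUP":
                return est.predict(fit, K_cross=X_new @ X.T)
            return est.predict(fit, X_new=X_new)

        np.testing.assert_array_equal(run(), run())


class TestMixedSolve:
    def test_reml_recovers_variance_ratio(self):
        """On data simulated from the mixed model the REML ratio estimate
        should land near the generative sigma_e^2/sigma_u^2."""
        rng = np.random.default_rng(6)
        n, p = 150, 80
        X = rng.binomial(2, 0.5, size=(n, p)).astype(float)
        sigma_u, sigma_e = 0.3, 0.8
        y = 1.0 + X @ rng.normal(scale=sigma_u, size=p) + rng.normal(scale=sigma_e, size=n)
        res = mixed_solve(y, X @ X.T, W=np.ones((n, 1)))
        lam_true = sigma_e**2 / sigma_u**2
        assert 0.3 * lam_true < res.lam < 3 * lam_true
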