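"""Ridge-family and penalized linear estimators: RR, rrBLUP, GBLUP,
LASSO, elastic net.

RR solves marker-effect ridge regression at a fixed (or CV-chosen)
penalty; rrBLUP estimates the penalty as the REML variance ratio
sigma_e^2/sigma_u^2 through the kinship spectral trick; GBLUP is the same
mixed model parameterized by an explicit genomic relationship matrix, so
rrBLUP on X and GBLUP on K = XX' give identical predictions. LASSO and
elastic net delegate the coordinate-descent solve to scikit-learn behind
the shared contract.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV

from megs.estimators.base import (
    Estimator,
    EstimatorFit,
    build_fixed_design,
    check_kinship,
    check_xy,
    split_fixed,
)
from megs.estimators.mixed import marker_blup, mixed_solve


class RidgeRegression(Estimator):
    """Marker-effect ridge with a fixed penalty, or the penalty chosen by
    k-fold CV over a log grid when ``lam`` is None."""

    name = "RR"
    category = "parametric"
    defaults = {"lam": None, "lam_grid": tuple(np.logspace(-3, 4, 15)), "cv": 5,
                "intercept": True}

    def _solve(self, X, y, W, lam):
        q = X.shape[1]
        c = 0 if W is None else W.shape[1]
        A = np.zeros((c + q, c + q))
        b = np.zeros(c + q)
        if c:
            A[:c, :c] = W.T @ W
            A[:c, c:] = W.T @ X
            A[c:, :c] = X.T @ W
            b[:c] = W.T @ y
        A[c:, c:] = X.T @ X + lam * np.eye(q)
        b[c:] = X.T @ y
        coef = np.linalg.solve(A, b)
        return coef[:c], coef[c:]

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if X is None:
            raise ValueError("RR needs a design matrix X")
        W = build_fixed_design(y.size, covariates, self.params["intercept"])
        lam = self.params["lam"]
        chosen_by_cv = False
        if lam is None:
            lam = self._cv_lambda(X, y, W)
            chosen_by_cv = True
        beta, u = self._solve(X, y, W, lam)
        mu, cov_eff = split_fixed(beta, self.params["intercept"])
        resid = y - (W @ beta if W is not None else 0.0) - X @ u
        return EstimatorFit(
            spec=self.spec,
            mu=mu,
            covariate_effects=cov_eff,
            marker_effects=u,
            variance_components={"lam": float(lam),
                                 "sigma_e2": float(resid @ resid / max(y.size - 1, 1))},
            diagnostics={"converged": True, "lam_by_cv": chosen_by_cv},
        )

    def _cv_lambda(self, X, y, W):
        rng = self.rng()
        n = y.size
        folds = np.array_split(rng.permutation(n), self.params["cv"])
        best, best_err = None, np.inf
        for lam in self.params["lam_grid"]:
            err = 0.0
            for hold in folds:
                tr = np.setdiff1d(np.arange(n), hold)
                Wtr = W[tr] if W is not None else None
                beta, u = self._solve(X[tr], y[tr], Wtr, lam)
                pred = X[hold] @ u
                if W is not None:
                    pred = pred + W[hold] @ beta
                err += float(np.sum((y[hold] - pred) ** 2))
            if err < best_err:
                best, best_err = lam, err
        return float(best)

    def predict(self, fit, X_new=None, K_cross=None, covariates_new=None):
        if X_new is None:
            raise ValueError(f"{self.name} predicts from a design matrix")
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != fit.marker_effects.size:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, expected {fit.marker_effects.size}"
            )
        return fit.fixed_part(covariates_new, X_new.shape[0]) + X_new @ fit.marker_effects


class RRBlup(Estimator):
    """Marker-effect BLUP with the ridge penalty set to the REML estimate
    of sigma_e^2/sigma_u^2 (one spectral decomposition of XX')."""

    name = "rrBLUP"
    category = "parametric"
    defaults = {"lam": None, "intercept": True}

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if X is None:
            raise ValueError("rrBLUP needs a design matrix X")
        W = build_fixed_design(y.size, covariates, self.params["intercept"])
        res = mixed_solve(y, X @ X.T, W=W, lam=self.params["lam"])
        u = marker_blup(X, res)
        if W is None:
            mu, cov_eff = 0.0, None
        else:
            mu, cov_eff = split_fixed(res.beta, self.params["intercept"])
        return EstimatorFit(
            spec=self.spec,
            mu=mu,
            covariate_effects=cov_eff,
            marker_effects=u,
            variance_components={
                "sigma_u2": res.sigma_u2,
                "sigma_e2": res.sigma_e2,
                "lam": res.lam,
            },
            diagnostics={"converged": True, "log_reml": res.log_reml},
        )

    predict = RidgeRegression.predict


class GBlup(Estimator):
    """Kinship-parameterized BLUP (the animal model): REML variance
    components on K, individual effects g = K(K + lam I)^{-1}(y - Wb),
    new individuals predicted through the cross-kinship block."""

    name = "GBLUP"
    category = "parametric"
    defaults = {"lam": None, "intercept": True}

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if K is None:
            if X is None:
                raise ValueError("GBLUP needs a kinship K (or X to build XX')")
            K = X @ X.T
        K = check_kinship(K)
        W = build_fixed_design(y.size, covariates, self.params["intercept"])
        res = mixed_solve(y, K, W=W, lam=self.params["lam"])
        if W is None:
            mu, cov_eff = 0.0, None
        else:
            mu, cov_eff = split_fixed(res.beta, self.params["intercept"])
        return EstimatorFit(
            spec=self.spec,
            mu=mu,
            covariate_effects=cov_eff,
            individual_effects=res.g,
            variance_components={
                "sigma_u2": res.sigma_u2,
                "sigma_e2": res.sigma_e2,
                "lam": res.lam,
            },
            diagnostics={"converged": True, "log_reml": res.log_reml},
            model_state={"weights": res.weights},
        )

    def predict(self, fit, X_new=None, K_cross=None, covariates_new=None):
        if K_cross is None:
            raise ValueError("GBLUP predicts from a cross-kinship block K_new_train")
        K_cross = np.asarray(K_cross, dtype=float)
        w = fit.model_state["weights"]
        if K_cross.shape[1] != w.size:
            raise ValueError(
                f"K_cross has {K_cross.shape[1]} columns, expected {w.size} "
                "(training individuals)"
            )
        return fit.fixed_part(covariates_new, K_cross.shape[0]) + K_cross @ w


class _SkPenalized(Estimator):
    """Common wrapper for scikit-learn coordinate-descent penalized fits."""

    category = "parametric"

    def _make(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if X is None:
            raise ValueError(f"{self.name} needs a design matrix X")
        W = build_fixed_design(y.size, covariates, False)
        Xfit = np.hstack([W, X]) if W is not None else X
        model = self._make()
        model.fit(Xfit, y)
        ncov = 0 if W is None else W.shape[1]
        coef = np.asarray(model.coef_, dtype=float)
        return EstimatorFit(
            spec=self.spec,
            mu=float(model.intercept_),
            covariate_effects=coef[:ncov] if ncov else None,
            marker_effects=coef[ncov:],
            variance_components={
                "alpha": float(getattr(model, "alpha_", getattr(model, "alpha", np.nan)))
            },
            diagnostics={"converged": int(getattr(model, "n_iter_", 0)) >= 0},
        )

    predict = RidgeRegression.predict


class LassoEstimator(_SkPenalized):
    """L1-penalized marker regression; penalty by 5-fold CV unless fixed."""

    name = "LASSO"
    defaults = {"alpha": None, "cv": 5, "max_iter": 50000}

    def _make(self):
        a = self.params["alpha"]
        if a is None:
            return LassoCV(cv=self.params["cv"], max_iter=self.params["max_iter"],
                           random_state=self._seed())
        return Lasso(alpha=a, max_iter=self.params["max_iter"])

    def _seed(self):
        return None if self.spec.seed is None else int(self.spec.seed) % (2**31)


class ElasticNetEstimator(_SkPenalized):
    """Mixed L1/L2 marker regression (elastic net), penalty by CV."""

    name = "EN"
    defaults = {"alpha": None, "l1_ratio": 0.5, "cv": 5, "max_iter": 50000}

    def _make(self):
        a = self.params["alpha"]
        if a is None:
            return ElasticNetCV(
                l1_ratio=self.params["l1_ratio"], cv=self.params["cv"],
                max_iter=self.params["max_iter"], random_state=self._seed(),
            )
        return ElasticNet(alpha=a, l1_ratio=self.params["l1_ratio"],
                          max_iter=self.params["max_iter"])

    _seed = LassoEstimator._seed
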