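"""Non-parametric learners behind the shared contract: SVM, RF, GBM.

These delegate to scikit-learn (epsilon-SVR with an RBF kernel, random
forest, gradient boosting) and exist so tree/kernel learners can be swapped
for the linear mixed models without touching the calling code. Fixed
covariates are appended to the feature block; every stochastic learner is
seeded from the spec.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.svm import SVR

from megs.estimators.base import Estimator, EstimatorFit, check_xy


class _SkLearner(Estimator):
    category = "non-parametric"

    def _make(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _seed(self):
        return None if self.spec.seed is None else int(self.spec.seed) % (2**31)

    @staticmethod
    def _features(X, covariates):
        X = np.asarray(X, dtype=float)
        if covariates is None:
            return X
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        return np.hstack([X, C])

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if X is None:
            raise ValueError(f"{self.name} needs a feature matrix X")
        F = self._features(X, covariates)
        model = self._make()
        model.fit(F, y)
        return EstimatorFit(
            spec=self.spec,
            mu=float(np.mean(y)),
            diagnostics={"converged": True},
            model_state={"model": model, "n_features": F.shape[1]},
        )

    def predict(self, fit, X_new=None, K_cross=None, covariates_new=None):
        if X_new is None:
            raise ValueError(f"{self.name} predicts from features")
        F = self._features(X_new, covariates_new)
        if F.shape[1] != fit.model_state["n_features"]:
            raise ValueError(
                f"feature count {F.shape[1]} != training {fit.model_state['n_features']}"
            )
        return np.asarray(fit.model_state["model"].predict(F), dtype=float)


class SVMRegressor(_SkLearner):
    """Epsilon-SVR with RBF kernel (deterministic given data)."""

    name = "SVM"
    defaults = {"C": 1.0, "epsilon": 0.1, "gamma": "scale"}

    def _make(self):
        return SVR(kernel="rbf", C=self.params["C"],
                   epsilon=self.params["epsilon"], gamma=self.params["gamma"])


class RandomForest(_SkLearner):
    name = "RF"
    defaults = {"n_trees": 500, "max_features": 1.0 / 3.0, "min_samples_leaf": 5}

    def _make(self):
        return RandomForestRegressor(
            n_estimators=self.params["n_trees"],
            max_features=self.params["max_features"],
            min_samples_leaf=self.params["min_samples_leaf"],
            random_state=self._seed(),
            n_jobs=1,
        )


class GradientBoosting(_SkLearner):
    name = "GBM"
    defaults = {"n_rounds": 500, "max_depth": 3, "learning_rate": 0.05,
                "subsample": 1.0}

    def _make(self):
        return GradientBoostingRegressor(
            n_estimators=self.params["n_rounds"],
            max_depth=self.params["max_depth"],
            learning_rate=self.params["learning_rate"],
            subsample=self.params["subsample"],
            random_state=self._seed(),
        )
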