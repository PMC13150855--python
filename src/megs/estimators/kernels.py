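"""Semi-parametric kernel estimators: RKHS and multi-kernel RKHS.

RKHS regression fits the same single-random-effect mixed model as GBLUP
but with a Gaussian kernel K_h = exp(-h * d^2 / median(d^2)) over marker
(or feature) distances in place of a linear relationship matrix, capturing
non-additive signal. MKRKHS performs kernel averaging: each bandwidth on a
grid is fitted by REML, bandwidths are weighted by their restricted
likelihood, and the weighted-average kernel is refitted — the usual
kernel-averaging recipe when no single bandwidth is known a priori.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from megs.estimators.base import (
    Estimator,
    EstimatorFit,
    build_fixed_design,
    check_xy,
    split_fixed,
)
from megs.estimators.mixed import mixed_solve


def gaussian_kernel(
    X: np.ndarray, Z: np.ndarray | None = None, h: float = 1.0,
    scale: float | None = None,
):
    """K = exp(-h d^2 / scale); scale defaults to the median squared
    training distance (computed on X against itself)."""
    X = np.asarray(X, dtype=float)
    Z = X if Z is None else np.asarray(Z, dtype=float)
    d2 = cdist(Z, X, metric="sqeuclidean")
    if scale is None:
        dtrain = cdist(X, X, metric="sqeuclidean")
        off = dtrain[np.triu_indices_from(dtrain, k=1)]
        scale = float(np.median(off)) if off.size and np.median(off) > 0 else 1.0
    return np.exp(-h * d2 / scale), scale


class RKHS(Estimator):
    """Gaussian-kernel mixed model at a single bandwidth, REML variances."""

    name = "RKHS"
    category = "semi-parametric"
    defaults = {"h": 1.0, "intercept": True}

    def _fit_kernel(self, y, K, covariates, extra_state):
        W = build_fixed_design(y.size, covariates, self.params["intercept"])
        res = mixed_solve(y, K, W=W)
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
            model_state={"weights": res.weights, **extra_state},
        )

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if K is not None:
            return self._fit_kernel(y, np.asarray(K, float), covariates,
                                    {"X_train": None, "scale": None, "h": None})
        if X is None:
            raise ValueError("RKHS needs features X or a precomputed kernel K")
        Kh, scale = gaussian_kernel(X, h=self.params["h"])
        return self._fit_kernel(
            y, Kh, covariates,
            {"X_train": X.copy(), "scale": scale, "h": self.params["h"]},
        )

    def predict(self, fit, X_new=None, K_cross=None, covariates_new=None):
        w = fit.model_state["weights"]
        if K_cross is None:
            Xtr = fit.model_state.get("X_train")
            if X_new is None or Xtr is None:
                raise ValueError("RKHS predict needs X_new (or K_cross)")
            K_cross, _ = gaussian_kernel(
                Xtr, np.asarray(X_new, float),
                h=fit.model_state["h"], scale=fit.model_state["scale"],
            )
        K_cross = np.asarray(K_cross, dtype=float)
        if K_cross.shape[1] != w.size:
            raise ValueError(
                f"K_cross has {K_cross.shape[1]} columns, expected {w.size}"
            )
        return fit.fixed_part(covariates_new, K_cross.shape[0]) + K_cross @ w


class MKRKHS(RKHS):
    """Kernel averaging over a bandwidth grid, weights from REML evidence."""

    name = "MKRKHS"
    category = "semi-parametric"
    defaults = {"h_grid": (0.1, 0.5, 1.0, 2.5, 5.0), "intercept": True}

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if X is None:
            raise ValueError("MKRKHS needs features X")
        W = build_fixed_design(y.size, covariates, self.params["intercept"])
        grid = list(self.params["h_grid"])
        kernels, logliks = [], []
        scale = None
        for h in grid:
            Kh, scale = gaussian_kernel(X, h=h, scale=scale)
            res = mixed_solve(y, Kh, W=W)
            kernels.append(Kh)
            logliks.append(res.log_reml)
        ll = np.asarray(logliks)
        wts = np.exp(ll - ll.max())
        wts /= wts.sum()
        K_avg = sum(w * Kh for w, Kh in zip(wts, kernels))
        fit = self._fit_kernel(
            y, K_avg, covariates,
            {"X_train": X.copy(), "scale": scale, "h": None,
             "h_grid": grid, "h_weights": wts},
        )
        fit.diagnostics["kernel_weights"] = dict(zip(grid, wts.tolist()))
        return fit

    def predict(self, fit, X_new=None, K_cross=None, covariates_new=None):
        if K_cross is None:
            Xtr = fit.model_state["X_train"]
            if X_new is None:
                raise ValueError("MKRKHS predict needs X_new (or K_cross)")
            X_new = np.asarray(X_new, float)
            parts = []
            for h, w in zip(fit.model_state["h_grid"], fit.model_state["h_weights"]):
                Kc, _ = gaussian_kernel(Xtr, X_new, h=h, scale=fit.model_state["scale"])
                parts.append(w * Kc)
            K_cross = sum(parts)
        return super().predict(fit, K_cross=K_cross, covariates_new=covariates_new)
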