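"""REML machinery for the single-random-effect mixed model

    y = W b + g + e,   g ~ N(0, K sigma_u^2),   e ~ N(0, I sigma_e^2)

solved through one spectral decomposition of the (fixed-effect projected)
kinship, with the variance ratio lambda = sigma_e^2 / sigma_u^2 profiled by
1-D restricted-likelihood optimization. The marker parameterization
y = W b + X u (u ~ N(0, I sigma_u^2)) is the same model with K = X X', and
marker BLUPs are recovered as u = X' (K + lambda I)^{-1} (y - W b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class MixedSolveResult:
    beta: np.ndarray          # fixed-effect estimates (W columns)
    sigma_u2: float
    sigma_e2: float
    lam: float                # sigma_e2 / sigma_u2
    weights: np.ndarray       # w = (K + lam I)^{-1} (y - W beta)
    g: np.ndarray             # BLUP individual effects K w
    log_reml: float


def _reml_profile(eta2: np.ndarray, theta: np.ndarray):
    """Restricted log-likelihood of the ratio delta on the rotated data."""
    df = eta2.size

    def neg_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = theta + delta
        s = max(np.sum(eta2 / denom), 1e-300)  # guard the all-zero response
        return float(df * np.log(s) + np.sum(np.log(denom)))

    return neg_ll


def mixed_solve(
    y: np.ndarray,
    K: np.ndarray,
    W: np.ndarray | None = None,
    lam: float | None = None,
    bounds: tuple[float, float] = (1e-9, 1e9),
) -> MixedSolveResult:
    """REML fit of the kinship mixed model; ``lam`` fixes the variance
    ratio instead of estimating it (used for matched-component checks and
    vanishing-shrinkage limits).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if W is not None:
        W = np.asarray(W, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        if W.size == 0 or not W.any():
            W = None
    if K.shape != (n, n):
        raise ValueError(f"kinship shape {K.shape} does not match n={n}")
    K = 0.5 * (K + K.T)  # symmetrize against round-off

    if W is None:
        Kr, ytilde = K, y
    else:
        c = np.linalg.matrix_rank(W)
        # rotate out the fixed effects: columns of Q2 span the orthogonal
        # complement of col(W)
        Q, _ = np.linalg.qr(W, mode="complete")
        Q2 = Q[:, c:]
        Kr = Q2.T @ K @ Q2
        ytilde = Q2.T @ y
    theta, U = np.linalg.eigh(Kr)
    theta = np.clip(theta, 0.0, None)
    eta = U.T @ ytilde
    eta2 = eta**2

    if lam is None:
        neg_ll = _reml_profile(eta2, theta)
        lo, hi = np.log(bounds[0]), np.log(bounds[1])
        # coarse grid then local polish: the profile can be multimodal-flat
        grid = np.linspace(lo, hi, 61)
        vals = [neg_ll(g) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            neg_ll,
            bounds=(max(lo, g0 - 1.0), min(hi, g0 + 1.0)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        log_reml = -float(res.fun)
    else:
        log_reml = -_reml_profile(eta2, theta)(np.log(lam))

    df = eta2.size
    sigma_u2 = float(np.sum(eta2 / (theta + lam)) / df)
    sigma_e2 = float(lam * sigma_u2)

    H = K + lam * np.eye(n)
    if W is None:
        beta = np.zeros(0)
        resid = y
    else:
        Hinv_W = np.linalg.solve(H, W)
        Hinv_y = np.linalg.solve(H, y)
        WtHinvW = W.T @ Hinv_W
        beta = np.linalg.solve(WtHinvW, W.T @ Hinv_y)
        resid = y - W @ beta
    weights = np.linalg.solve(H, resid)
    g = K @ weights
    return MixedSolveResult(
        beta=beta,
        sigma_u2=sigma_u2,
        sigma_e2=sigma_e2,
        lam=float(lam),
        weights=weights,
        g=g,
        log_reml=log_reml,
    )


def marker_blup(X: np.ndarray, result: MixedSolveResult) -> np.ndarray:
    """Back-transform kinship weights to marker effects for K = X X'."""
    return X.T @ result.weights
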