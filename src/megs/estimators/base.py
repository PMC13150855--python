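"""Shared fit/predict contract for the estimator ensemble.

Every estimator — parametric (ridge-type, Bayesian alphabet), semi-
parametric (kernel mixed models) or non-parametric (delegated machine
learners) — is driven through the same surface: ``fit`` consumes a design
matrix X (N x q) and/or a kinship K (N x N) plus optional fixed
covariates, and returns an :class:`EstimatorFit`; ``predict`` consumes new
rows (marker/feature form) or a cross-kinship block (kinship form).
Randomized estimators are seeded through their spec, so identical spec +
data + seed is bit-reproducible.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass(frozen=True)
class EstimatorSpec:
    """A named estimator plus hyperparameters.

    ``name`` must be one of the 15 registry members; unspecified
    hyperparameters take the registry defaults.
    """

    name: str
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def with_params(self, **kwargs) -> "EstimatorSpec":
        hp = dict(self.hyperparams)
        seed = kwargs.pop("seed", self.seed)
        hp.update(kwargs)
        return EstimatorSpec(self.name, hp, seed)


@dataclass
class EstimatorFit:
    """Fitted state of an estimator.

    For linear estimators exactly one of ``marker_effects`` (marker form,
    trait units per allele copy) or ``individual_effects`` (kinship form)
    is populated; delegated learners keep their fitted model in
    ``model_state`` instead.
    """

    spec: EstimatorSpec
    mu: float
    covariate_effects: np.ndarray | None = None
    marker_effects: np.ndarray | None = None
    individual_effects: np.ndarray | None = None
    variance_components: dict[str, float] = field(default_factory=dict)
    diagnostics: dict[str, Any] = field(default_factory=dict)
    model_state: dict[str, Any] = field(default_factory=dict)

    def fixed_part(self, covariates: np.ndarray | None, n: int) -> np.ndarray:
        out = np.full(n, self.mu)
        if self.covariate_effects is not None and covariates is not None:
            C = np.atleast_2d(np.asarray(covariates, dtype=float))
            if C.shape[0] != n:
                C = C.T
            out = out + C @ self.covariate_effects
        return out


class Estimator(abc.ABC):
    """Abstract estimator; concrete classes register under a canonical name."""

    name: str = ""
    category: str = ""  # parametric | semi-parametric | non-parametric
    defaults: dict[str, Any] = {}

    def __init__(self, spec: EstimatorSpec):
        if spec.name != self.name:
            raise ValueError(f"spec {spec.name!r} handed to estimator {self.name!r}")
        unknown = set(spec.hyperparams) - set(self.defaults)
        if unknown:
            raise ValueError(f"{self.name}: unknown hyperparameters {sorted(unknown)}")
        self.spec = spec
        self.params = {**self.defaults, **spec.hyperparams}

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.spec.seed)

    @abc.abstractmethod
    def fit(
        self,
        y: np.ndarray,
        X: np.ndarray | None = None,
        K: np.ndarray | None = None,
        covariates: np.ndarray | None = None,
    ) -> EstimatorFit:
        """Fit to responses y (length N, no missing values)."""

    @abc.abstractmethod
    def predict(
        self,
        fit: EstimatorFit,
        X_new: np.ndarray | None = None,
        K_cross: np.ndarray | None = None,
        covariates_new: np.ndarray | None = None,
    ) -> np.ndarray:
        """Predict responses for new rows / cross-kinship block."""


def check_xy(y, X):
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValueError("y contains missing values; mask them upstream")
    if y.size < 2:
        raise ValueError("need at least two responses")
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError(f"X has {X.shape[0]} rows but y has {y.size}")
    return y, X


def check_kinship(K: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1]:
        raise ValueError(f"kinship not square: {K.shape}")
    if not np.allclose(K, K.T, atol=tol * max(1.0, np.abs(K).max())):
        raise ValueError("kinship not symmetric within tolerance")
    w = np.linalg.eigvalsh(0.5 * (K + K.T))
    floor = -1e-8 * max(np.trace(K) / K.shape[0], 1.0)
    if w.min() < floor:
        raise ValueError(f"kinship not PSD: min eigenvalue {w.min():.3e}")
    return 0.5 * (K + K.T)


def build_fixed_design(n: int, covariates: np.ndarray | None, intercept: bool):
    """Assemble the fixed-effect matrix W (may be None when nothing fixed)."""
    cols = []
    if intercept:
        cols.append(np.ones((n, 1)))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError(f"covariates have {C.shape[0]} rows, expected {n}")
        cols.append(C)
    if not cols:
        return None
    return np.hstack(cols)


def split_fixed(beta: np.ndarray, intercept: bool):
    """Split a stacked fixed-effect vector into (mu, covariate_effects)."""
    beta = np.asarray(beta, dtype=float).ravel()
    if intercept:
        mu = float(beta[0])
        rest = beta[1:] if beta.size > 1 else None
    else:
        mu = 0.0
        rest = beta if beta.size else None
    return mu, (rest.copy() if rest is not None and rest.size else None)
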