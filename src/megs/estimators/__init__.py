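"""The 15-estimator ensemble.

Ten parametric members (GBLUP, BayesA, BayesB, BayesC, BRR, BL, LASSO,
RR, rrBLUP, EN), two semi-parametric (RKHS, MKRKHS) and three
non-parametric (SVM, RF, GBM), all behind one fit/predict contract so any
of them can drive either prediction framework.

RR and rrBLUP are both ridge-type marker regressions; they differ in how
the penalty is chosen: RR takes a fixed or cross-validated penalty, rrBLUP
sets it to the REML variance ratio.
"""

from __future__ import annotations

from megs.estimators.base import Estimator, EstimatorFit, EstimatorSpec
from megs.estimators.bayes import BRR, BayesA, BayesB, BayesC, BayesianLasso
from megs.estimators.kernels import MKRKHS, RKHS, gaussian_kernel
from megs.estimators.linear import (
    ElasticNetEstimator,
    GBlup,
    LassoEstimator,
    RRBlup,
    RidgeRegression,
)
from megs.estimators.mixed import MixedSolveResult, marker_blup, mixed_solve
from megs.estimators.ml import GradientBoosting, RandomForest, SVMRegressor

_CLASSES: dict[str, type[Estimator]] = {
    cls.name: cls
    for cls in (
        GBlup, BayesA, BayesB, BayesC, BRR, BayesianLasso,
        LassoEstimator, RidgeRegression, RRBlup, ElasticNetEstimator,
        RKHS, MKRKHS,
        SVMRegressor, RandomForest, GradientBoosting,
    )
}

CATEGORIES = {name: cls.category for name, cls in _CLASSES.items()}


def registry() -> list[EstimatorSpec]:
    """Default specs for all 15 estimators (stable alphabetical order)."""
    return [EstimatorSpec(name, dict(_CLASSES[name].defaults)) for name in sorted(_CLASSES)]


def get_estimator(spec: EstimatorSpec | str, seed: int | None = None) -> Estimator:
    """Instantiate an estimator from a spec or a bare registry name."""
    if isinstance(spec, str):
        spec = EstimatorSpec(spec, seed=seed)
    elif seed is not None and spec.seed is None:
        spec = EstimatorSpec(spec.name, dict(spec.hyperparams), seed)
    if spec.name not in _CLASSES:
        raise KeyError(
            f"unknown estimator {spec.name!r}; registry: {sorted(_CLASSES)}"
        )
    return _CLASSES[spec.name](spec)


__all__ = [
    "Estimator",
    "EstimatorFit",
    "EstimatorSpec",
    "registry",
    "get_estimator",
    "CATEGORIES",
    "mixed_solve",
    "marker_blup",
    "MixedSolveResult",
    "gaussian_kernel",
]
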