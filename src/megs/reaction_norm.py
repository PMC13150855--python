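"""Reaction-norm (RN) framework.

Each genotype's phenotype is modelled as a straight line in the centred
environmental index x_j:

    y_ij = k_i x_j + b_i + e_ij

Per-genotype ordinary least squares over its observed environments gives a
slope k_i and intercept b_i — two derived "traits" describing
environmental response. Genomic prediction of k and b from markers (any
registry estimator, fitted independently per trait) then extends the
reaction norms to untested genotypes, and plugging the predicted (k, b)
back into the line with an environment's index value reconstructs its
phenotype — including in novel environments, whose index is centred
against the training centre.

A line needs at least three points for a residual degree of freedom, so
genotypes observed in fewer than three environments are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from megs.data import EnvIndex, GenotypeMatrix, PhenoTable
from megs.estimators import EstimatorFit, EstimatorSpec, get_estimator

logger = logging.getLogger(__name__)

MIN_ENVIRONMENTS = 3


def fit_rn(pheno: PhenoTable, index: EnvIndex, min_envs: int = MIN_ENVIRONMENTS) -> pd.DataFrame:
    """Per-genotype OLS of phenotype on the centred index.

    Returns a frame indexed by genotype with columns ``slope``,
    ``intercept``, ``resid_var`` and ``n_envs``; genotypes observed in
    fewer than ``min_envs`` environments are dropped (logged).
    """
    envs_with_index = set(index.centred_index)
    rec = pheno.observed()
    rec = rec[rec["environment"].isin(envs_with_index)]
    n_index_envs = rec["environment"].nunique()
    if n_index_envs < min_envs:
        raise ValueError(
            f"reaction-norm fit needs at least {min_envs} environments for "
            f"linear regression, got {n_index_envs}"
        )
    x_all = np.array([index.centred_index[e] for e in rec["environment"].unique()])
    if np.ptp(x_all) == 0:
        raise ValueError("environmental index is identical across environments")

    rows, excluded = [], []
    for gid, sub in rec.groupby("genotype", sort=True):
        if sub.shape[0] < min_envs:
            excluded.append(gid)
            continue
        x = np.array([index.centred_index[e] for e in sub["environment"]])
        y = sub["value"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            excluded.append(gid)
            continue
        k, b = np.polyfit(x, y, 1)
        resid = y - (k * x + b)
        dof = max(len(y) - 2, 1)
        rows.append((gid, float(k), float(b), float(resid @ resid / dof), len(y)))
    if excluded:
        logger.info(
            "excluded %d genotypes with < %d usable environments: %s",
            len(excluded), min_envs, excluded[:10],
        )
    if not rows:
        raise ValueError("no genotype has enough environments for a reaction norm")
    out = pd.DataFrame(rows, columns=["genotype", "slope", "intercept", "resid_var", "n_envs"])
    return out.set_index("genotype")


def predict_rn_traits(
    params: pd.DataFrame,
    geno: GenotypeMatrix,
    train_ids: list[str],
    test_ids: list[str],
    spec: EstimatorSpec | str,
    seed: int | None = None,
) -> pd.DataFrame:
    """Genomic prediction of slope and intercept for untested genotypes.

    Two independent estimator fits (one per derived trait) on the training
    genotypes' marker data.
    """
    missing = [g for g in train_ids if g not in params.index]
    if missing:
        raise KeyError(f"training genotypes without fitted reaction norms: {missing[:5]}")
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    Xtr = geno.subset(list(train_ids)).dosages
    Xte = geno.subset(list(test_ids)).dosages
    out = {}
    for trait in ("slope", "intercept"):
        y = params.loc[list(train_ids), trait].to_numpy(dtype=float)
        est = get_estimator(spec, seed=seed)
        try:
            fit = est.fit(y, X=Xtr)
            out[trait] = est.predict(fit, X_new=Xte, K_cross=_cross(est, Xte, Xtr, fit))
        except Exception as exc:
            raise RuntimeError(f"estimator failed on derived trait {trait!r}: {exc}") from exc
    return pd.DataFrame(out, index=list(test_ids))


def _cross(est, Xte, Xtr, fit):
    """Cross-kinship block for kinship-form estimators, else None."""
    if fit.individual_effects is not None and est.name == "GBLUP":
        return Xte @ Xtr.T
    return None


def reconstruct(
    traits: pd.DataFrame,
    index: EnvIndex,
    environments: list[str],
) -> PhenoTable:
    """Phenotype reconstruction: yhat_ij = k_i x_j + b_i.

    ``environments`` must each have an index value (novel environments are
    allowed once their window mean has been appended with the training
    centre, see :meth:`EnvIndex.extend`).
    """
    missing = [e for e in environments if e not in index.centred_index]
    if missing:
        raise KeyError(f"environments without an index value: {missing}")
    rows = []
    for env in environments:
        x = index.centred_index[env]
        yhat = traits["slope"].to_numpy() * x + traits["intercept"].to_numpy()
        for gid, v in zip(traits.index, yhat):
            rows.append((gid, env, "predicted", float(v)))
    return PhenoTable(pd.DataFrame(rows, columns=["genotype", "environment", "trait", "value"]))


@dataclass
class ReactionNormResults:
    """Fitted reaction norms plus the machinery to extend them to untested
    genotypes and reconstruct phenotypes."""

    model: "ReactionNormModel"
    params: pd.DataFrame  # genotype-indexed: slope, intercept, resid_var, n_envs

    @property
    def slopes(self) -> pd.Series:
        return self.params["slope"]

    @property
    def intercepts(self) -> pd.Series:
        return self.params["intercept"]

    def predict_traits(
        self, test_ids: list[str], train_ids: list[str] | None = None,
        spec: EstimatorSpec | str = "rrBLUP", seed: int | None = None,
    ) -> pd.DataFrame:
        if self.model.geno is None:
            raise ValueError("model was built without genotypes")
        if train_ids is None:
            train_ids = [g for g in self.params.index if g not in set(test_ids)]
        return predict_rn_traits(self.params, self.model.geno, train_ids, test_ids, spec, seed)

    def predict(
        self, test_ids: list[str], environments: list[str] | None = None,
        spec: EstimatorSpec | str = "rrBLUP", seed: int | None = None,
        index: EnvIndex | None = None,
    ) -> PhenoTable:
        """End-to-end: predict (k, b) for test genotypes, then reconstruct
        their phenotypes in the requested environments."""
        idx = index if index is not None else self.model.index
        if environments is None:
            environments = list(idx.centred_index)
        traits = self.predict_traits(test_ids, spec=spec, seed=seed)
        return reconstruct(traits, idx, environments)

    def reconstruct_fitted(self, environments: list[str] | None = None) -> PhenoTable:
        """Reconstruction from the *fitted* (not genomically predicted)
        reaction norms — the in-sample check."""
        envs = environments or list(self.model.index.centred_index)
        return reconstruct(self.params, self.model.index, envs)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Reaction-norm fit",
            "=================",
            f"genotypes fitted     : {len(p)}",
            f"environments (index) : {len(self.model.index.centred_index)}",
            f"index factor/window  : {self.model.index.factor_name} "
            f"{self.model.index.window}",
            f"slope  mean (sd)     : {p['slope'].mean():.4f} ({p['slope'].std():.4f})",
            f"intercept mean (sd)  : {p['intercept'].mean():.4f} ({p['intercept'].std():.4f})",
            f"median resid var     : {p['resid_var'].median():.4f}",
        ]
        return "\n".join(lines)


class ReactionNormModel:
    """Reaction-norm model over a phenotype table and environmental index.

    Parameters
    ----------
    pheno : PhenoTable
        Long-format records for one trait.
    index : EnvIndex
        Scalar environmental index (centred per its own centre).
    geno : GenotypeMatrix, optional
        Needed only for genomic prediction of the derived traits.
    """

    def __init__(
        self,
        pheno: PhenoTable,
        index: EnvIndex,
        geno: GenotypeMatrix | None = None,
        min_envs: int = MIN_ENVIRONMENTS,
    ):
        self.pheno = pheno
        self.index = index
        self.geno = geno
        self.min_envs = min_envs

    def fit(self) -> ReactionNormResults:
        params = fit_rn(self.pheno, self.index, self.min_envs)
        if self.geno is not None:
            known = set(self.geno.sample_ids)
            orphans = [g for g in params.index if g not in known]
            if orphans:
                raise KeyError(
                    f"phenotyped genotypes absent from genotype matrix: {orphans[:5]}"
                )
        return ReactionNormResults(self, params)
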