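"""Polygenic-environment-interaction (PEI) framework.

Every marker k carries a main effect a_k plus an effect b_k that scales
with the centred environmental index x_j, so the record of genotype i in
environment j is modelled as

    y_ij = mu + beta x_j + sum_k m_ik (a_k + b_k x_j) + e_ij .

Stacking environments gives a design whose block for environment j is the
genotype matrix next to its index-scaled copy, [M | x_j M] — doubling the
markers with one interaction pseudo-marker each — plus a fixed covariate
column x_j. Because the marker effects are shared across environments, the
equivalent kinship has blocks

    K_(j,j') = (1 + x_j x_j') * G ,

with G the genomic relationship matrix, and the whole model collapses to a
single GBLUP on that kinship. Either parameterization predicts any
(genotype, environment) cell — including environments wholly absent from
training, once their index value is known.

The literal environment-specific reading (block-diagonal effects, no
information shared between environments) is kept behind
``shared_effects=False`` for comparison; it cannot predict novel
environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from megs.data import EnvIndex, GenotypeMatrix, PhenoTable
from megs.estimators import EstimatorFit, EstimatorSpec, get_estimator

#: estimators fitted on the kinship rather than the 2p-column design
_KINSHIP_FORM = {"GBLUP"}
#: estimators fitted on per-record feature vectors [dosages, x_j]
_FEATURE_FORM = {"SVM", "RF", "GBM", "RKHS", "MKRKHS"}


def build_interaction_block(M: np.ndarray, x_j: float) -> np.ndarray:
    """Index-scaled copy of the genotype matrix: every entry times x_j."""
    return np.asarray(M, dtype=float) * float(x_j)


def genomic_relationship(M: np.ndarray, method: str = "vanraden") -> np.ndarray:
    """Genomic relationship matrix of a dosage matrix.

    ``vanraden``: columns centred by twice the allele frequency and scaled
    by sum 2 p_k (1 - p_k); ``crossprod``: raw M M' (the form under which
    the kinship blocks equal the design cross-product exactly).
    """
    M = np.asarray(M, dtype=float)
    if method == "crossprod":
        return M @ M.T
    if method == "vanraden":
        pbar = M.mean(axis=0) / 2.0
        W = M - 2.0 * pbar
        denom = float(np.sum(2.0 * pbar * (1.0 - pbar)))
        if denom <= 0:
            raise ValueError("all markers monomorphic; VanRaden denominator is zero")
        return W @ W.T / denom
    raise ValueError(f"unknown GRM method {method!r}")


@dataclass
class PEIDesign:
    """Stacked interaction design and its row identity map.

    ``X_all`` is (n_cells x 2p): the main-effect block next to the
    index-scaled interaction block, shared columns across environments;
    ``covariate`` is the per-row centred index x_j (the fixed environment
    regressor); ``rows`` maps each row to its (genotype, environment).
    """

    environments: list[str]
    x: dict[str, float]
    marker_ids: list[str]
    rows: list[tuple[str, str]]
    X_all: np.ndarray
    covariate: np.ndarray

    @property
    def m(self) -> int:
        return len(self.environments)


def build_design(
    geno: GenotypeMatrix,
    index: EnvIndex,
    environments: list[str] | None = None,
    cells: list[tuple[str, str]] | None = None,
    interaction: bool = True,
) -> PEIDesign:
    """Assemble the stacked [M | x_j M] design.

    By default every genotype appears in every requested environment,
    blocks ordered by environment then genotype; ``cells`` restricts the
    rows to an explicit (genotype, environment) list (training rows during
    cross-validation).
    """
    if environments is None:
        environments = list(index.centred_index)
    unknown = [e for e in environments if e not in index.centred_index]
    if unknown:
        raise KeyError(f"environments without an index value: {unknown}")
    if cells is None:
        cells = [(g, e) for e in environments for g in geno.sample_ids]
    else:
        bad_env = sorted({e for _, e in cells if e not in index.centred_index})
        if bad_env:
            raise KeyError(f"cells in environments without an index value: {bad_env}")

    sample_pos = {s: i for i, s in enumerate(geno.sample_ids)}
    bad = [g for g, _ in cells if g not in sample_pos]
    if bad:
        raise KeyError(f"cell genotypes absent from genotype matrix: {sorted(set(bad))[:5]}")
    gidx = np.array([sample_pos[g] for g, _ in cells])
    xvec = np.array([index.centred_index[e] for _, e in cells])
    M_rows = geno.dosages[gidx]
    if interaction:
        X_all = np.hstack([M_rows, M_rows * xvec[:, None]])
        marker_ids = list(geno.marker_ids) + [f"{m}:x" for m in geno.marker_ids]
    else:
        X_all = M_rows
        marker_ids = list(geno.marker_ids)
    if not np.all(np.isfinite(xvec)):
        raise ValueError("non-finite environmental index value")
    return PEIDesign(
        environments=list(environments),
        x={e: index.centred_index[e] for e in environments},
        marker_ids=marker_ids,
        rows=list(cells),
        X_all=X_all,
        covariate=xvec,
    )


def build_kinship(
    geno: GenotypeMatrix,
    index: EnvIndex,
    environments: list[str] | None = None,
    grm: str = "vanraden",
    cells: list[tuple[str, str]] | None = None,
    cells2: list[tuple[str, str]] | None = None,
    interaction: bool = True,
) -> np.ndarray:
    """Multi-environment kinship with blocks (1 + x_j x_j') * G.

    With ``cells2`` given, returns the rectangular cross-kinship between
    the two cell lists (rows = cells, columns = cells2) — the block needed
    to project BLUPs onto unobserved cells.
    """
    if environments is None:
        environments = list(index.centred_index)
    if cells is None:
        cells = [(g, e) for e in environments for g in geno.sample_ids]
    G = genomic_relationship(geno.dosages, grm)
    sample_pos = {s: i for i, s in enumerate(geno.sample_ids)}

    def parts(cell_list):
        gi = np.array([sample_pos[g] for g, _ in cell_list])
        xv = np.array([index.centred_index[e] for _, e in cell_list])
        if not np.all(np.isfinite(xv)):
            raise ValueError("non-finite environmental index value")
        return gi, xv

    gi1, x1 = parts(cells)
    gi2, x2 = parts(cells2) if cells2 is not None else (gi1, x1)
    scale = 1.0 + np.outer(x1, x2) if interaction else 1.0
    return scale * G[np.ix_(gi1, gi2)]


@dataclass
class PEIResults:
    """Fitted PEI model: estimator state, the cells it was trained on,
    and predictions for the requested test cells."""

    model: "PEIModel"
    fit: EstimatorFit | dict[str, EstimatorFit]
    form: str
    train_cells: list[tuple[str, str]]
    predictions: pd.DataFrame  # genotype, environment, yhat
    shared_effects: bool = True

    def predict_cells(self, cells: list[tuple[str, str]], index: EnvIndex | None = None) -> pd.DataFrame:
        """Predict additional (genotype, environment) cells, optionally
        with an index extended to novel environments."""
        return self.model._predict(self, cells, index or self.model.index)

    def summary(self) -> str:
        vc = self.fit.variance_components if isinstance(self.fit, EstimatorFit) else {}
        lines = [
            "Polygenic-environment-interaction fit",
            "=====================================",
            f"estimator            : {self.model.spec_name} ({self.form} form)",
            f"training cells       : {len(self.train_cells)}",
            f"environments         : {len(self.model.index.centred_index)}",
            f"index factor/window  : {self.model.index.factor_name} "
            f"{self.model.index.window}",
        ]
        for k, v in vc.items():
            lines.append(f"{k:<21}: {v:.6g}")
        lines.append(f"test cells predicted : {len(self.predictions)}")
        return "\n".join(lines)


class PEIModel:
    """PEI model over phenotypes, genotypes and an environmental index.

    Parameters
    ----------
    pheno : PhenoTable
        Long-format records for one trait; NA cells are masked.
    geno : GenotypeMatrix
    index : EnvIndex
    grm : str
        Relationship-matrix flavour for the kinship form
        (``vanraden`` default, ``crossprod`` for exact design equivalence).
    augment_features : bool
        Feature-form learners see [dosages, x_j] by default; True switches
        to [dosages, x_j * dosages, x_j], mirroring the parametric design.
    shared_effects : bool
        False selects the environment-specific (block-diagonal) reading:
        one independent fit per environment, no sharing across blocks.
    interaction : bool
        False removes the marker-by-index interaction columns (and the
        index scaling of the kinship), leaving a main-effects-plus-
        environment-covariate model — the baseline the interaction model
        is contrasted against. Feature-form learners are unaffected.
    """

    def __init__(
        self,
        pheno: PhenoTable,
        geno: GenotypeMatrix,
        index: EnvIndex,
        grm: str = "vanraden",
        augment_features: bool = False,
        shared_effects: bool = True,
        interaction: bool = True,
    ):
        traits = pheno.traits
        if len(traits) != 1:
            raise ValueError(f"PEI fits one trait at a time, got {traits}")
        self.pheno = pheno
        self.geno = geno
        self.index = index
        self.grm = grm
        self.augment_features = augment_features
        self.shared_effects = shared_effects
        self.interaction = interaction
        self.spec_name = None

    # -- internals ---------------------------------------------------------

    def _form(self, name: str) -> str:
        if name in _KINSHIP_FORM:
            return "kinship"
        if name in _FEATURE_FORM:
            return "feature"
        return "marker"

    def _feature_rows(self, cells):
        pos = {s: i for i, s in enumerate(self.geno.sample_ids)}
        gidx = np.array([pos[g] for g, _ in cells])
        xv = np.array([self.index.centred_index[e] for _, e in cells])
        M_rows = self.geno.dosages[gidx]
        if self.augment_features:
            F = np.hstack([M_rows, M_rows * xv[:, None]])
        else:
            F = M_rows
        return F, xv

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        spec: EstimatorSpec | str = "rrBLUP",
        test_cells: list[tuple[str, str]] | None = None,
        seed: int | None = None,
    ) -> PEIResults:
        """Fit on all observed cells except ``test_cells``; predict those.

        Test cells may sit in environments wholly absent from training
        (novel-environment mode) provided the index covers them.
        """
        est = get_estimator(spec, seed=seed)
        self.spec_name = est.name
        test_cells = list(test_cells or [])
        obs = self.pheno.observed()
        obs_cells = list(zip(obs["genotype"], obs["environment"]))
        test_set = set(test_cells)
        train_mask = [c not in test_set for c in obs_cells]
        train = obs.loc[train_mask]
        train_cells = [c for c in obs_cells if c not in test_set]
        if not train_cells:
            raise ValueError("no training cells left after removing test cells")
        known = set(self.geno.sample_ids)
        bad = sorted({g for g, _ in test_cells if g not in known})
        if bad:
            raise KeyError(f"test genotypes absent from genotype matrix: {bad[:5]}")
        bad_env = sorted({e for _, e in test_cells if e not in self.index.centred_index})
        if bad_env:
            raise KeyError(
                f"test environments without an index value (novel environment "
                f"needs its window mean appended first): {bad_env}"
            )
        y = train["value"].to_numpy(dtype=float)

        if not self.shared_effects:
            return self._fit_blockdiag(est, train_cells, y, test_cells)

        form = self._form(est.name)
        if form == "kinship":
            K = build_kinship(self.geno, self.index, grm=self.grm,
                              cells=train_cells, interaction=self.interaction)
            xv = np.array([self.index.centred_index[e] for _, e in train_cells])
            fit = est.fit(y, K=K, covariates=xv)
        elif form == "feature":
            F, xv = self._feature_rows(train_cells)
            fit = est.fit(y, X=F, covariates=xv)
        else:
            design = build_design(self.geno, self.index, cells=train_cells,
                                  interaction=self.interaction)
            fit = est.fit(y, X=design.X_all, covariates=design.covariate)

        res = PEIResults(
            model=self, fit=fit, form=form, train_cells=train_cells,
            predictions=pd.DataFrame(columns=["genotype", "environment", "yhat"]),
            shared_effects=True,
        )
        res._estimator = est
        if test_cells:
            res.predictions = self._predict(res, test_cells, self.index)
        return res

    def _fit_blockdiag(self, est, train_cells, y, test_cells):
        """Environment-specific effects: an independent fit per environment."""
        fits: dict[str, EstimatorFit] = {}
        ests: dict[str, object] = {}
        by_env: dict[str, list[int]] = {}
        for i, (_, e) in enumerate(train_cells):
            by_env.setdefault(e, []).append(i)
        for env, rows in by_env.items():
            cells_e = [train_cells[i] for i in rows]
            design = build_design(self.geno, self.index, cells=cells_e)
            est_e = get_estimator(est.spec)
            fits[env] = est_e.fit(y[rows], X=design.X_all, covariates=design.covariate)
            ests[env] = est_e
        res = PEIResults(
            model=self, fit=fits, form="marker", train_cells=train_cells,
            predictions=pd.DataFrame(columns=["genotype", "environment", "yhat"]),
            shared_effects=False,
        )
        res._estimators = ests
        if test_cells:
            missing = sorted({e for _, e in test_cells if e not in fits})
            if missing:
                raise ValueError(
                    "environment-specific (block-diagonal) effects cannot "
                    f"predict environments absent from training: {missing}"
                )
            preds = []
            for env in sorted({e for _, e in test_cells}):
                cells_e = [c for c in test_cells if c[1] == env]
                design = build_design(self.geno, self.index, cells=cells_e)
                yhat = ests[env].predict(
                    fits[env], X_new=design.X_all, covariates_new=design.covariate
                )
                preds += [(g, e, float(v)) for (g, e), v in zip(cells_e, yhat)]
            res.predictions = pd.DataFrame(preds, columns=["genotype", "environment", "yhat"])
        return res

    def _predict(self, res: PEIResults, cells, index: EnvIndex) -> pd.DataFrame:
        if not res.shared_effects:
            raise ValueError("use fit(test_cells=...) for the block-diagonal mode")
        est = res._estimator
        missing = [e for _, e in cells if e not in index.centred_index]
        if missing:
            raise KeyError(f"environments without an index value: {sorted(set(missing))}")
        # temporarily view the model through the (possibly extended) index
        saved = self.index
        self.index = index
        try:
            if res.form == "kinship":
                Kc = build_kinship(
                    self.geno, index, grm=self.grm,
                    cells=cells, cells2=res.train_cells,
                    interaction=self.interaction,
                )
                xv = np.array([index.centred_index[e] for _, e in cells])
                yhat = est.predict(res.fit, K_cross=Kc, covariates_new=xv)
            elif res.form == "feature":
                F, xv = self._feature_rows(cells)
                yhat = est.predict(res.fit, X_new=F, covariates_new=xv)
            else:
                design = build_design(self.geno, index, cells=list(cells),
                                      interaction=self.interaction)
                yhat = est.predict(res.fit, X_new=design.X_all,
                                   covariates_new=design.covariate)
        finally:
            self.index = saved
        return pd.DataFrame(
            [(g, e, float(v)) for (g, e), v in zip(cells, yhat)],
            columns=["genotype", "environment", "yhat"],
        )


def fit_predict_pei(
    pheno: PhenoTable,
    geno: GenotypeMatrix,
    index: EnvIndex,
    spec: EstimatorSpec | str,
    test_cells: list[tuple[str, str]],
    seed: int | None = None,
    grm: str = "vanraden",
    augment_features: bool = False,
    shared_effects: bool = True,
    interaction: bool = True,
) -> pd.DataFrame:
    """One-shot convenience: fit PEI minus the test cells, return their
    predictions as a (genotype, environment, yhat) frame."""
    model = PEIModel(
        pheno, geno, index, grm=grm,
        augment_features=augment_features, shared_effects=shared_effects,
        interaction=interaction,
    )
    return model.fit(spec=spec, test_cells=test_cells, seed=seed).predictions
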