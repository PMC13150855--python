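"""Cross-validation schemes, the accuracy metric, heritability and the
resource-guidance dimension rule.

Two scenarios mirror how a breeder would deploy the frameworks:

* **untested genotypes** — genotypes are split into folds; for each fold
  the environmental index is re-searched on the training genotypes only
  (no index leakage), the framework is fitted on training genotypes, and
  the held-out genotypes are predicted in every environment;
* **novel environment** — each environment in turn is masked entirely,
  the index is searched on the remaining environments, and the masked
  environment's genotypes are predicted through its own (training-centred)
  index value.

Accuracy is the within-environment Pearson correlation between observed
and predicted values, averaged over fold-level correlations per
environment and then (unweighted) over environments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from megs.ceris import env_means, search_index, window_mean
from megs.data import EnvSeries, GenotypeMatrix, PhenoTable, VarianceComponents
from megs.estimators import EstimatorSpec
from megs.pei import PEIModel
from megs.reaction_norm import ReactionNormModel, reconstruct

logger = logging.getLogger(__name__)

#: above this order of magnitude of n_lines * n_markers, heavy estimators
#: become impractical and lighter ones are advised
DIMENSION_ADVICE_THRESHOLD = 8


def accuracy(pred: np.ndarray, obs: np.ndarray) -> float:
    """Sample Pearson correlation between predictions and observations.

    Returns NaN (with a warning) when fewer than three non-missing pairs
    remain or either side has zero variance.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.size != obs.size:
        raise ValueError(f"length mismatch: {pred.size} vs {obs.size}")
    ok = ~(np.isnan(pred) | np.isnan(obs))
    pred, obs = pred[ok], obs[ok]
    if pred.size < 3:
        warnings.warn(f"accuracy undefined with {pred.size} pairs", stacklevel=2)
        return float("nan")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        warnings.warn("accuracy undefined: zero variance", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(pred, obs)[0, 1])


@dataclass
class CVResult:
    """Fold-level accuracies plus their per-environment and overall means."""

    table: pd.DataFrame        # environment, replicate, fold, accuracy, n_pairs
    scheme: str
    k: int
    reps: int
    seed: int
    pooled: pd.Series = field(default=None)  # per-env pooled-prediction correlation

    @property
    def per_environment(self) -> pd.Series:
        return self.table.groupby("environment")["accuracy"].mean()

    @property
    def overall(self) -> float:
        return float(self.per_environment.mean())

    def summary(self) -> str:
        pe = self.per_environment
        lines = [
            f"Cross-validation ({self.scheme}; k={self.k}, reps={self.reps}, seed={self.seed})",
            "-" * 56,
        ]
        for env, acc in pe.items():
            lines.append(f"  {env:<12} accuracy {acc:.4f}")
        lines.append(f"  overall      accuracy {self.overall:.4f}")
        return "\n".join(lines)


def _partition(genotypes: list[str], k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random exact partition of genotypes into k folds."""
    perm = rng.permutation(len(genotypes))
    ids = np.asarray(genotypes, dtype=object)
    return [ids[chunk] for chunk in np.array_split(perm, k)]


def _fold_predictions_rn(pheno, geno, series, fold, train_ids, spec, seed, min_width, step):
    means = env_means(pheno, genotype_subset=list(train_ids))
    idx = search_index(series, means, min_width=min_width, step=step).best
    train_pheno = PhenoTable(
        pheno.records[pheno.records["genotype"].isin(set(train_ids))].reset_index(drop=True)
    )
    res = ReactionNormModel(train_pheno, idx, geno).fit()
    usable_train = [g for g in train_ids if g in res.params.index]
    traits = res.predict_traits(list(fold), train_ids=usable_train, spec=spec, seed=seed)
    return reconstruct(traits, idx, list(idx.centred_index))


def _fold_predictions_pei(pheno, geno, series, fold, train_ids, spec, seed,
                          min_width, step, grm):
    means = env_means(pheno, genotype_subset=list(train_ids))
    idx = search_index(series, means, min_width=min_width, step=step).best
    obs = pheno.observed()
    fold_set = set(fold)
    test_cells = [
        (g, e) for g, e in zip(obs["genotype"], obs["environment"]) if g in fold_set
    ]
    model = PEIModel(pheno, geno, idx, grm=grm)
    return model.fit(spec=spec, test_cells=test_cells, seed=seed).predictions


def cv_untested_genotypes(
    framework: str,
    spec: EstimatorSpec | str,
    geno: GenotypeMatrix,
    pheno: PhenoTable,
    series: EnvSeries,
    k: int = 10,
    reps: int = 5,
    seed: int = 0,
    min_width: int = 7,
    step: int = 1,
    grm: str = "vanraden",
) -> CVResult:
    """Scenario (i): forecast untested genotypes in tested environments.

    ``k=2`` reproduces the leave-one-half-of-genotypes-out variant. The
    index search is re-run inside every fold on training genotypes only.
    """
    framework = framework.upper()
    if framework not in ("RN", "PEI"):
        raise ValueError(f"framework must be RN or PEI, got {framework!r}")
    genotypes = sorted(set(pheno.observed()["genotype"]))
    seeds = np.random.SeedSequence(seed).spawn(reps)
    obs = pheno.observed()

    rows = []
    pooled_acc: dict[str, list[tuple[float, float]]] = {}
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        fold_seed = int(rng.integers(2**31))
        for fold_i, fold in enumerate(_partition(genotypes, k, rng)):
            train_ids = [g for g in genotypes if g not in set(fold)]
            if framework == "RN":
                pred = _fold_predictions_rn(
                    pheno, geno, series, fold, train_ids, spec, fold_seed,
                    min_width, step,
                ).records.rename(columns={"value": "yhat"})
            else:
                pred = _fold_predictions_pei(
                    pheno, geno, series, fold, train_ids, spec, fold_seed,
                    min_width, step, grm,
                )
            merged = obs.merge(
                pred[["genotype", "environment", "yhat"]],
                on=["genotype", "environment"],
            )
            merged = merged[merged["genotype"].isin(set(fold))]
            for env, sub in merged.groupby("environment"):
                if sub.shape[0] < 2:
                    logger.info(
                        "rep %d fold %d env %s: %d test genotypes; accuracy skipped",
                        rep, fold_i, env, sub.shape[0],
                    )
                    acc = float("nan")
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        acc = accuracy(sub["yhat"], sub["value"])
                rows.append((env, rep, fold_i, acc, sub.shape[0]))
                pooled_acc.setdefault(env, []).extend(
                    zip(sub["yhat"].tolist(), sub["value"].tolist())
                )

    table = pd.DataFrame(rows, columns=["environment", "replicate", "fold", "accuracy", "n_pairs"])
    pooled = pd.Series(
        {
            env: accuracy(*map(np.asarray, zip(*pairs)))
            for env, pairs in pooled_acc.items()
        },
        name="pooled_accuracy",
    )
    return CVResult(table=table, scheme="untested-genotypes", k=k, reps=reps,
                    seed=seed, pooled=pooled)


def cv_novel_environment(
    framework: str,
    spec: EstimatorSpec | str,
    geno: GenotypeMatrix,
    pheno: PhenoTable,
    series: EnvSeries,
    seed: int = 0,
    min_width: int = 7,
    step: int = 1,
    grm: str = "vanraden",
) -> CVResult:
    """Scenario (ii): leave-one-environment-out.

    Each environment in turn is masked; the index is searched on the
    remaining environments; the masked environment's phenotypes are
    predicted through its own index value centred at the training centre.
    For the RN framework the genotypes are *tested*, so the fitted
    per-genotype lines are extrapolated directly.
    """
    framework = framework.upper()
    if framework not in ("RN", "PEI"):
        raise ValueError(f"framework must be RN or PEI, got {framework!r}")
    envs = [e for e in pheno.environment_ids if pheno.observed()["environment"].eq(e).any()]
    m = len(envs)
    if framework == "RN" and m < 4:
        raise ValueError(
            "leave-one-environment-out with the RN framework needs >= 4 "
            "environments (a minimum of three environments must remain for "
            f"linear regression), got {m}"
        )
    if m < 3:
        raise ValueError(f"leave-one-environment-out needs >= 3 environments, got {m}")

    obs_all = pheno.observed()
    rng = np.random.default_rng(seed)
    rows = []
    for h_i, held in enumerate(envs):
        train_envs = [e for e in envs if e != held]
        masked = PhenoTable(
            pheno.records[pheno.records["environment"].isin(train_envs)].reset_index(drop=True)
        )
        means = env_means(masked)
        train_series = series.subset_environments(train_envs)
        idx = search_index(train_series, means, min_width=min_width, step=step).best
        # held-out environment's index from its own series, training centre
        e_new = window_mean(series, idx.factor_name, idx.window)[held]
        idx_ext = idx.extend({held: e_new})

        held_obs = obs_all[obs_all["environment"] == held]
        fold_seed = int(rng.integers(2**31))
        if framework == "RN":
            res = ReactionNormModel(masked, idx, geno).fit()
            pred = reconstruct(res.params, idx_ext, [held]).records.rename(
                columns={"value": "yhat"}
            )
        else:
            model = PEIModel(masked, geno, idx, grm=grm)
            fit = model.fit(spec=spec, seed=fold_seed)
            cells = list(zip(held_obs["genotype"], held_obs["environment"]))
            pred = fit.predict_cells(cells, index=idx_ext)
        merged = held_obs.merge(
            pred[["genotype", "environment", "yhat"]], on=["genotype", "environment"]
        )
        acc = accuracy(merged["yhat"], merged["value"])
        rows.append((held, 0, h_i, acc, merged.shape[0]))

    table = pd.DataFrame(rows, columns=["environment", "replicate", "fold", "accuracy", "n_pairs"])
    return CVResult(table=table, scheme="novel-environment", k=m, reps=1, seed=seed)


def estimate_components(records: pd.DataFrame) -> VarianceComponents:
    """Two-way random-effects decomposition of a balanced replicated MET.

    ``records`` needs columns genotype, environment, rep, value with every
    genotype observed in every environment at the same replicate count.
    Components come from equating observed to expected mean squares;
    negative estimates are truncated at zero with a warning.
    """
    req = {"genotype", "environment", "rep", "value"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rec = records.dropna(subset=["value"])
    counts = rec.groupby(["genotype", "environment"])["value"].count()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every (genotype, environment) cell must have "
            "the same replicate count; balance the data or supply externally "
            "estimated components"
        )
    R = int(counts.iloc[0])
    G = rec["genotype"].nunique()
    L = rec["environment"].nunique()
    if G < 2 or L < 2:
        raise ValueError(f"need >= 2 genotypes and >= 2 environments, got {G} x {L}")
    if len(rec) != G * L * R:
        raise ValueError("unbalanced design: not every genotype appears in every environment")

    grand = rec["value"].mean()
    g_means = rec.groupby("genotype")["value"].mean()
    e_means = rec.groupby("environment")["value"].mean()
    cell_means = rec.groupby(["genotype", "environment"])["value"].mean()

    ss_g = L * R * float(((g_means - grand) ** 2).sum())
    ss_e = G * R * float(((e_means - grand) ** 2).sum())
    inter = (
        cell_means
        - g_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - e_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_ge = R * float((inter**2).sum())
    resid = rec["value"].to_numpy() - cell_means.reindex(
        pd.MultiIndex.from_frame(rec[["genotype", "environment"]])
    ).to_numpy()
    ss_err = float((resid**2).sum())

    ms_g = ss_g / (G - 1)
    ms_ge = ss_ge / ((G - 1) * (L - 1))
    if R > 1:
        ms_err = ss_err / (G * L * (R - 1))
        Vge = (ms_ge - ms_err) / R
        Ve = ms_err
    else:
        # single replicate: interaction and residual are confounded; report
        # the whole interaction mean square as residual
        warnings.warn(
            "R=1: genotype-by-environment and residual variance are "
            "confounded; Vge set to 0 and Ve to the interaction mean square",
            stacklevel=2,
        )
        ms_err = ms_ge
        Vge = 0.0
        Ve = ms_err
    Vg = (ms_g - ms_ge) / (L * R)
    for name, v in (("Vg", Vg), ("Vge", Vge), ("Ve", Ve)):
        if v < 0:
            warnings.warn(f"negative {name} estimate {v:.4g} truncated to 0", stacklevel=2)
    return VarianceComponents(
        Vg=max(Vg, 0.0), Vge=max(Vge, 0.0), Ve=max(Ve, 0.0), L=L, R=R
    )


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on an entry-mean basis:
    H = Vg / (Vg + Vge/L + Ve/(R L))."""
    denom = vc.Vg + vc.Vge / vc.L + vc.Ve / (vc.R * vc.L)
    if denom <= 0:
        raise ValueError("all variance components zero; heritability undefined")
    return float(vc.Vg / denom)


def dimension(n_lines: int, n_markers: int) -> int:
    """Order of magnitude (base 10) of population size x marker count.

    Used for resource guidance: at dimension >= 8 the heavier estimators
    (kernel and Bayesian members) become costly and lighter alternatives
    are advised.
    """
    if n_lines < 1 or n_markers < 1:
        raise ValueError("n_lines and n_markers must be >= 1")
    d = int(np.floor(np.log10(float(n_lines) * float(n_markers)) + 1e-12))
    if d >= DIMENSION_ADVICE_THRESHOLD:
        warnings.warn(
            f"dimension {d} >= {DIMENSION_ADVICE_THRESHOLD}: consider "
            "lighter estimators (e.g. GBM, SVM) at this scale",
            stacklevel=2,
        )
    return d
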