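# megs — multi-environment genomic selection

Genomic prediction for multi-environment trials (METs) with explicit
genotype-by-environment (G×E) interaction. Breeders phenotype the same
genotypes at several locations or years; a genotype that excels at one
site may underperform at another, and selecting on a single-environment
or averaged prediction wastes that information. `megs` provides the two
complementary modelling routes for this problem, a searchable
environmental index that ties them to weather data, a 15-member estimator
ensemble, both cross-validation scenarios a breeder cares about, and a
fully seeded MET simulator with known ground truth.

## The models

**Environmental index (CERIS search).** A scalar per environment
summarizing its growing conditions: the mean of one daily environmental
factor (e.g. daily highest temperature) over one day window. The search
enumerates every (factor, window) pair, regresses environment-mean
phenotype on the per-environment window mean, and keeps the candidate
with the highest R². The winning index, centred across environments,
is `x_j`.

**Reaction norm (RN).** Each genotype responds linearly to the index:

    y_ij = k_i x_j + b_i + e_ij

Per-genotype least squares gives slope `k_i` and intercept `b_i`; these
two derived "traits" are predicted from markers for untested genotypes
(any estimator in the ensemble), and phenotypes are reconstructed by
plugging the predicted line back in at any environment's `x_j`.

**Polygenic environment interaction (PEI).** Every marker `k` carries a
main effect `a_k` and an index-scaled interaction effect `b_k`:

    y_ij = mu + beta x_j + sum_k m_ik (a_k + b_k x_j) + e_ij

Stacking environments gives the design block `[M | x_j M]` per
environment — the marker set doubled by interaction pseudo-markers —
plus a fixed covariate `x_j`. With shared effects across environments
the equivalent kinship has blocks `(1 + x_j x_j') G`, so the whole model
also solves as one GBLUP; both parameterizations are implemented and
agree to machine precision.

**Estimators.** One fit/predict contract covers ten parametric members
(GBLUP, rrBLUP, RR, LASSO, EN, BayesA, BayesB, BayesC, BRR, BL), two
semi-parametric (RKHS, MKRKHS — Gaussian-kernel mixed models, single
bandwidth or likelihood-weighted kernel averaging) and three
non-parametric (SVM, RF, GBM). `megs.registry()` lists all fifteen with
their defaults.

**Evaluation.** Scenario (i): untested genotypes in tested environments
(k-fold over genotypes, index re-searched on training genotypes inside
every fold). Scenario (ii): tested genotypes in a novel environment
(leave-one-environment-out; the held-out environment's index value is
computed from its own weather series and centred at the training
centre). Accuracy is the within-environment Pearson correlation of
predicted vs observed, averaged over environments. Broad-sense
heritability uses the entry-mean formula
`H = Vg / (Vg + Vge/L + Ve/(R L))` with components from a balanced
two-way ANOVA.

## Worked example

```python
import numpy as np
from megs import (SimConfig, sim_genotypes, sim_environments, sim_phenotypes,
                  env_means, search_index, PEIModel, accuracy)

cfg = SimConfig(n=200, p=100, m=6, h2=0.6, seed=11)
geno = sim_genotypes(cfg)
series = sim_environments(cfg)
sim = sim_phenotypes(geno, series, cfg)

best = search_index(series, env_means(sim.pheno), min_width=7, step=1).best
print(f"best index: {best.factor_name} days {best.window[0]}-{best.window[1]}  R2 = {best.r2:.3f}")

held = geno.sample_ids[150:]                       # 50 untested genotypes
cells = [(g, e) for g in held for e in cfg.env_ids()]
res = PEIModel(sim.pheno, geno, best).fit(spec="rrBLUP", test_cells=cells, seed=11)
print(res.summary())

obs = sim.pheno.records.rename(columns={"value": "y"})
m = res.predictions.merge(obs, on=["genotype", "environment"])
acc = np.mean([accuracy(s["yhat"], s["y"]) for _, s in m.groupby("environment")])
print(f"held-out genotype accuracy (mean over environments): {acc:.3f}")
```

Output:

```
best index: F3 days 5-12  R2 = 0.528
Polygenic-environment-interaction fit
=====================================
estimator            : rrBLUP (marker form)
training cells       : 900
environments         : 6
index factor/window  : F3 (5, 12)
sigma_u2             : 0.0773991
sigma_e2             : 32.5256
lam                  : 420.232
test cells predicted : 300
held-out genotype accuracy (mean over environments): 0.330
```

The search picked factor F3 over days 5–12 (with noisy weather and a
heritability of 0.6, a correlated proxy window can out-score the causal
one in-sample); the mixed model attributes most variance to the residual
(`lam` = sigma_e²/sigma_u² ≈ 420 across 200 doubled markers), and the 50
genotypes never seen in training are predicted with mean
within-environment accuracy 0.33 — close to the ceiling implied by an
entry-mean heritability of 0.6 spread over six environments.

The same steps run from the shell:

```sh
megs simulate --config sim.json --out-prefix run_
megs ceris --env run_env.tsv --pheno run_pheno.tsv --trait sim --out grid.tsv
megs cv --framework pei --scheme genotype --geno run_geno.tsv \
        --pheno run_pheno.tsv --env run_env.tsv --trait sim \
        --estimator rrBLUP --k 10 --reps 5 --seed 11 --out cv.tsv
```

Every command writes a JSON manifest (seed, input digests, version,
wall time) next to its output.

## Data formats

* genotypes: TSV matrix (header = marker ids, first column = sample id)
  or PLINK RAW (`--recode A`); dosages 0/1/2, missing either rejected or
  mean-imputed per marker (`impute=True`).
* phenotypes: long TSV `genotype  environment  trait  value`, `NA`
  = masked cell.
* environment: daily TSV `environment  day  factor  value`, harmonized
  to the day range and factor set shared by all environments.
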