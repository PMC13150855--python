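# Methods

This note documents the models, the numerical choices behind them, what
the synthetic-data generator does and does not emulate, and the known
limitations — in enough detail that someone could reimplement the
package from it.

## Environmental index search

The index search summarizes each environment by the arithmetic mean of
one daily factor over one inclusive day window, then scores every
candidate `(factor, start, end)` by the R² of a simple (unweighted)
linear regression of environment-mean phenotype on the per-environment
window mean. Environment means are taken over whichever genotype subset
the caller supplies — during cross-validation this is the training fold,
so held-out phenotypes never influence the index.

Grid and numerics:

* every `(start, end)` pair on a `step`-day grid with width
  ≥ `min_width` is enumerated (defaults: step 1, min-width 7 days). The
  7-day floor exists to exclude one- or two-day windows that fit noise;
  the full pair enumeration (rather than fixed-width bins) is the more
  general reading of an "equal-sized bins" sliding scan, and the
  brute-force oracle in the test suite checks every cell of the grid.
* window means use per-factor prefix sums, so the whole grid costs
  O(factors · D² · m) additions for D days and m environments.
* a candidate whose window mean is constant across environments (or a
  constant phenotype) has R² defined as 0.
* ties on R² break deterministically: earlier start, then shorter
  window, then factor name — exhaustive grids on synthetic data produce
  exact ties, and a deterministic rule keeps runs reproducible.
* two environments are refused: any non-degenerate factor fits two
  points perfectly, so a "best" index would be meaningless. Three is the
  minimum.

The winning per-environment value `e_j` is centred by its
across-environment mean; the centred `x_j` is what both frameworks use.
Novel environments are centred with the *training* centre — recentring
would silently shift every trained coefficient's meaning.

## Reaction-norm framework

Per genotype, ordinary least squares of phenotype on `x_j` over the
environments where it was observed, requiring at least three
environments (a line through two points has no residual degree of
freedom); genotypes below the floor are excluded and logged, never
fitted. Slope and intercept are then treated as two derived traits and
predicted from markers independently (no bivariate model — their genetic
correlation is ignored, which loses a little efficiency but keeps every
estimator in the ensemble usable unchanged). Reconstruction is the plain
plug-in `ŷ_ij = k̂_i x_j + b̂_i`.

## Polygenic-environment-interaction framework

Record-level model:

    y_ij = mu + beta * x_j + sum_k m_ik (a_k + b_k x_j) + e_ij

* **Design (marker form).** Rows are (genotype, environment) cells; the
  row block for environment j is `[M | x_j M]` — each marker contributes
  one main column and one interaction pseudo-marker — plus `x_j` as a
  fixed covariate. Marker effects are *shared* across environments. The
  environment-specific (block-diagonal) reading, in which each
  environment gets its own effect vector, is implemented behind
  `shared_effects=False` for comparison only: within a block the
  interaction columns are exactly collinear with the main columns, and a
  block-diagonal model passes no information to a left-out environment,
  so it cannot predict novel environments at all.
* **Kinship form.** With shared effects and a common effect variance,
  the covariance between cells (i, j) and (i′, j′) is
  `(1 + x_j x_j′) · G_ii′`; with `G = MM'` this equals the design
  cross-product exactly (identity verified to 1e-9 in tests), and the
  model solves as a single GBLUP. The default G is VanRaden-standardized
  (columns centred by twice the allele frequency, scaled by
  Σ 2p̄(1−p̄)); `crossprod` is kept for the exact-equivalence oracle.
* **Fixed environmental part.** The environment enters as a regression
  on the centred index (`mu + beta x_j`), not as per-environment free
  intercepts — free intercepts cannot extrapolate to a novel
  environment. `x_j` is the centred index throughout.
* **Feature-form learners.** Kernel and tree estimators see per-record
  features `[dosages, x_j]` by default — trees and RBF kernels model
  interactions implicitly, and doubling the feature count with explicit
  products mainly hurts them; `augment_features=True` switches to the
  explicit `[dosages, x_j·dosages, x_j]` layout.
* Residuals are homoscedastic across environments.

## Estimator ensemble

All fifteen estimators sit behind one contract: `fit(y, X=..., K=...,
covariates=...) -> EstimatorFit`, `predict(fit, X_new / K_cross)`.
Identical spec + seed + data reproduces output bit-for-bit, including
the delegated scikit-learn learners.

* **Mixed-model core (rrBLUP, GBLUP, RKHS, MKRKHS).** One spectral
  decomposition of the fixed-effect-projected kinship turns the REML
  profile in the variance ratio λ = σe²/σu² into a cheap 1-D problem;
  a 61-point log-grid scan (1e-9…1e9) followed by bounded Brent polish
  guards against flat or multimodal profiles. Marker BLUPs are recovered
  as `u = X'(XX' + λI)⁻¹(y − Wβ)`. rrBLUP = REML λ; RR = fixed λ or a
  seeded k-fold CV over a log grid (this disambiguation of two
  otherwise-identical ridge estimators is ours). GBLUP validates K
  (symmetry, PSD to −1e-8·trace/N) and predicts through the
  cross-kinship block. The λ→0 limit reproduces noiseless interpolation
  (tested to 1e-6).
* **Bayesian alphabet (BRR, BayesA, BayesB, BayesC, BL).** Single-site
  Gibbs with residual updating. Priors: BRR common effect variance;
  BayesA per-marker scaled-inv-χ² (df 5); BayesB adds a point mass at
  zero with prior exclusion probability π = 0.95 and per-marker
  variances; BayesC point mass with a common variance; BL
  double-exponential via per-marker exponential mixing (inverse-Gaussian
  conditional, Gamma update for λ²). Hyperprior scales follow the usual
  variance-partition heuristic: prior R² = 0.5 of var(y) to markers
  (spread over the summed column variance), the rest to the residual.
  Defaults 6000 iterations / 1000 burn-in / thin 5; posterior summaries
  are chain means; both variances can be frozen, which turns BRR into a
  Monte-Carlo ridge whose posterior mean must match the analytic ridge
  solution (checked to 2% at 20k samples). Chains expose half-chain
  effect means for a Geweke-style stability check, and a non-finite
  state aborts with the iteration index.
* **Kernels.** RKHS uses `K_h = exp(−h d²/median(d²))` with h = 1;
  MKRKHS fits each bandwidth in {0.1, 0.5, 1, 2.5, 5} by REML, weights
  them by their restricted likelihood, and refits on the weighted-average
  kernel — kernel averaging as commonly practised when no bandwidth is
  known a priori.
* **Delegated learners.** SVR (RBF, ε = 0.1), random forest (500 trees,
  1/3 features per split, leaf ≥ 5) and gradient boosting (500 rounds,
  depth 3, shrinkage 0.05), all seeded.

## Evaluation

* **Accuracy** is the within-environment Pearson correlation, undefined
  (returned missing, with a warning) below three pairs or at zero
  variance. Per-environment accuracies average fold-level correlations;
  a pooled-prediction correlation per environment is reported alongside
  as an alternative aggregation. The overall figure is the unweighted
  mean over environments.
* **Scenario (i)** partitions genotypes into k folds (default 10 folds ×
  5 replicates; k = 2 gives the leave-one-half-out variant) and re-runs
  the index search inside every fold on training genotypes only.
* **Scenario (ii)** leaves each environment out in turn; the held-out
  environment's index value comes from its own daily series via the
  training window, centred at the training centre. For the RN framework
  the genotypes are tested, so the fitted per-genotype lines are
  extrapolated directly; RN needs at least three *training* environments,
  hence at least four overall.
* **Variance components** come from the balanced two-way
  expected-mean-squares decomposition (genotype, environment, G×E,
  residual); negative estimates truncate to zero with a warning;
  unbalanced tables are rejected rather than approximated. With one
  replicate, G×E and residual are confounded; the confounded mean square
  is reported as residual.
* **Heritability** is the entry-mean ratio
  `H = Vg / (Vg + Vge/L + Ve/(R L))`.
* **Dimension** is `floor(log10(n_lines × n_markers))`; at ≥ 8 the
  package warns that the heavier (kernel/Bayesian) estimators become
  impractical and lighter ones are advisable.

## Synthetic-data generator

The generator emulates the three inputs end to end with known truth.

* **Genotypes**: independent dosages ~ Binomial(2, p_k), p_k uniform in
  (0.1, 0.5). No linkage disequilibrium by default — estimator oracles
  are cleanest on independent markers; an AR(1) option on allele
  frequencies exists for mild realism.
* **Daily series**: per factor, a sinusoid (base 20, amplitude 8,
  factor-specific phase — think °C over a 60-day season) plus an
  environment offset and day-level noise (sd 0.5). Offsets form a
  symmetric ladder with sd exactly `env_offset_sd` (default 1.0),
  permuted across environments per factor. A ladder rather than a normal
  draw is deliberate: with few environments a random draw makes the
  between-environment index spread — and with it the realized
  interaction variance — strongly seed-dependent, which would make any
  fixed heritability target unattainable at unlucky seeds.
* **Phenotypes**: the PEI generative model with sparse effects (20 main
  QTL sd 1.0, 10 interaction QTL sd 0.5 by default), `mu = 10`,
  `beta = 0.5`. Residual variance is calibrated on the *realized*
  genetic values (not analytically) so the entry-mean heritability of
  the simulated truth hits the target: sparse-effect variance depends on
  the realized dosage frequencies, so an analytic calibration would be
  biased. A target that is infeasible given the realized interaction
  variance (the `Vge/L` term caps attainable H) raises an error rather
  than silently clipping. `noise_sd` overrides calibration when a fixed
  residual scale is wanted — the strong-interaction contrast in the
  acceptance run uses `noise_sd = 5.0`, the scale the h² = 0.5
  calibration itself produces, because at interaction-effect sd 1.2 the
  realized `Vge` occasionally crosses the feasibility bound.
* The truth record (effects, index, noise draws, components) regenerates
  every phenotype exactly; a test asserts this.

What passing tests on this generator do **not** show about real data:
no linkage disequilibrium or population structure, homoscedastic
residuals, a single truly linear index, balanced designs, and weather
series far smoother than station records. Accuracies on real METs will
be lower and estimator rankings can differ.

## Design choices where the design was genuinely open

* **Shared vs environment-specific marker effects**: shared is the
  default (see PEI section); the literal block-diagonal variant survives
  behind a flag.
* **Missing phenotype cells** within a tested environment are dropped
  from the stacked vector (and logged); missing genotype dosages are a
  hard error unless per-marker mean imputation is requested — silent
  imputation masks upstream data problems.
* **Interaction-vs-main-effects contrast** (in the acceptance run): the
  comparison uses LASSO on a half split of genotypes. Measured, not
  assumed: under a *shared* ridge penalty, a zero-signal interaction
  block systematically dilutes shrinkage of the main effects — the
  interaction model is then consistently (if slightly) worse whenever
  interaction is absent, and a paired sign test flags that tiny
  systematic loss as significant. A sparsity-capable estimator can drive
  a null interaction block to zero, so with LASSO the b = 0 comparison
  is direction-balanced while the strong-interaction comparison is won
  in ≳ 90% of replicates. This is worth knowing when applying the
  framework: with ridge-type estimators, the interaction columns are not
  free — they cost a little accuracy when G×E is truly absent.
* **Heritability ladder** (0.2 / 0.5 / 0.8) runs at interaction-effect
  sd 0.25: the `Vge/L` term bounds attainable entry-mean H, and a
  modest interaction keeps h² = 0.8 feasible at four environments.

## Problem sizes

The test suite and acceptance script run trials of 20–500 genotypes,
25–100 markers and 3–6 environments, with 10-seed replication where a
claim is statistical; these sizes were chosen so the full recovery
experiments re-run comfortably on a laptop-class single core while
keeping every Monte-Carlo tolerance honest.

## Known limitations

* Single environmental index; no multi-index models.
* No REML variance components for unbalanced METs (method-of-moments,
  balanced only).
* The Gibbs samplers are single-site and loop over markers in Python —
  fine at desk scale, not at 10⁵ markers.
* Kinship-form fitting materializes the (n·m)² matrix; for dimension ≥ 8
  use the marker form or the lighter learners (the package warns).
* The RN framework cannot use genotypes seen in fewer than three
  environments; PEI has no such floor but shares the linear-index
  assumption.
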