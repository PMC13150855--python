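"""Bayesian whole-genome regression by single-site Gibbs sampling.

Five members of the "Bayesian alphabet" share one sampler skeleton and
differ only in the marker-effect prior:

* BRR    — common normal prior, u_k ~ N(0, sigma_u^2);
* BayesA — per-marker variances with scaled-inverse-chi-square priors;
* BayesB — point mass at zero with probability pi, else a per-marker
  variance as in BayesA;
* BayesC — point mass at zero with probability pi, else a common variance;
* BL     — Bayesian LASSO: double-exponential shrinkage via per-marker
  exponential mixing variances (Park–Casella parameterization).

Residual and effect variances carry scaled-inverse-chi-square hyperpriors
whose scales follow the usual variance-partition heuristic: a prior trait
proportion R2 of var(y) is attributed to markers (spread over the summed
column variance of X) and 1 - R2 to the residual. Posterior summaries are
the post-burn-in thinned chain means. Both variances can be frozen with
``fix_sigma_u2`` / ``fix_sigma_e2``, which turns BRR into a Monte-Carlo
ridge whose posterior mean is the analytic ridge solution at
lam = sigma_e^2/sigma_u^2 — used as an estimator cross-check.
"""

from __future__ import annotations

import numpy as np

from megs.estimators.base import (
    Estimator,
    EstimatorFit,
    build_fixed_design,
    check_xy,
    split_fixed,
)


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    """Draw sigma^2 ~ scale * df / chi2_df  (scaled inverse chi-square)."""
    return scale * df / rng.chisquare(df)


class _GibbsWGR(Estimator):
    """Shared Gibbs engine; subclasses set ``prior``."""

    category = "parametric"
    prior = ""  # BRR | BayesA | BayesB | BayesC | BL
    defaults = {
        "iters": 6000,
        "burnin": 1000,
        "thin": 5,
        "pi": 0.95,          # prior exclusion probability (BayesB/C)
        "df_u": 5.0,
        "df_e": 5.0,
        "r2": 0.5,           # prior proportion of variance from markers
        "fix_sigma_u2": None,
        "fix_sigma_e2": None,
        "intercept": True,
    }

    def fit(self, y, X=None, K=None, covariates=None):
        y, X = check_xy(y, X)
        if X is None:
            raise ValueError(f"{self.name} needs a design matrix X")
        W = build_fixed_design(y.size, covariates, self.params["intercept"])
        rng = self.rng()
        p = self.params

        n, q = X.shape
        ck = np.einsum("ij,ij->j", X, X)  # column sums of squares
        vy = float(np.var(y)) or 1.0
        sum_colvar = float(np.sum(np.var(X, axis=0)))
        msx = sum_colvar if sum_colvar > 0 else float(np.mean(ck)) or 1.0
        S_u = vy * p["r2"] / msx * (p["df_u"] + 2) / p["df_u"]
        S_e = vy * (1 - p["r2"]) * (p["df_e"] + 2) / p["df_e"]

        fixed_u = p["fix_sigma_u2"]
        fixed_e = p["fix_sigma_e2"]
        sigma_e2 = float(fixed_e) if fixed_e is not None else vy * (1 - p["r2"]) or 1.0
        sigma_u2 = float(fixed_u) if fixed_u is not None else S_u
        var_k = np.full(q, sigma_u2)          # per-marker variance (A/B)
        tau2 = np.full(q, 1.0)                 # BL mixing variances
        lam2 = 1.0                              # BL lambda^2
        pi_excl = p["pi"]
        delta = np.ones(q, dtype=bool)          # inclusion indicators
        if self.prior in ("BayesB", "BayesC"):
            delta = rng.random(q) >= pi_excl

        u = np.zeros(q)
        nW = 0 if W is None else W.shape[1]
        beta = np.zeros(nW)
        wk = None if W is None else np.einsum("ij,ij->j", W, W)
        e = y - X @ u - (W @ beta if W is not None else 0.0)

        keep_iters = range(p["burnin"], p["iters"], p["thin"])
        n_keep = len(keep_iters)
        keep_set = set(keep_iters)
        u_sum = np.zeros(q)
        u_first = np.zeros(q)   # first half of kept draws, for diagnostics
        beta_sum = np.zeros(nW)
        ve_chain = np.empty(n_keep)
        mu_chain = np.empty(n_keep)
        kept = 0

        for it in range(p["iters"]):
            # fixed effects
            for j in range(nW):
                e += W[:, j] * beta[j]
                mean = (W[:, j] @ e) / wk[j]
                beta[j] = rng.normal(mean, np.sqrt(sigma_e2 / wk[j]))
                e -= W[:, j] * beta[j]

            # marker effects (single-site)
            if self.prior == "BRR":
                eff_var = np.full(q, sigma_u2)
            elif self.prior in ("BayesA", "BayesB"):
                eff_var = var_k
            elif self.prior == "BayesC":
                eff_var = np.full(q, sigma_u2)
            else:  # BL
                eff_var = tau2 * sigma_e2

            for k in range(q):
                if ck[k] == 0:
                    u[k] = 0.0
                    continue
                e += X[:, k] * u[k]
                rk = X[:, k] @ e
                vk = eff_var[k]
                if self.prior in ("BayesB", "BayesC"):
                    # integrated likelihood ratio for inclusion
                    v1 = ck[k] * vk + sigma_e2
                    log_bf = (
                        0.5 * np.log(sigma_e2 / v1)
                        + 0.5 * rk**2 * vk / (sigma_e2 * v1)
                    )
                    p_in = (1 - pi_excl) / ((1 - pi_excl) + pi_excl * np.exp(-log_bf))
                    delta[k] = rng.random() < p_in
                    if not delta[k]:
                        u[k] = 0.0
                        continue
                denom = ck[k] + sigma_e2 / vk
                mean = rk / denom
                u[k] = rng.normal(mean, np.sqrt(sigma_e2 / denom))
                e -= X[:, k] * u[k]

            # prior-variance updates
            if self.prior == "BayesA" and fixed_u is None:
                var_k = (S_u * p["df_u"] + u**2) / rng.chisquare(p["df_u"] + 1, size=q)
            elif self.prior == "BayesB" and fixed_u is None:
                ss = np.where(delta, u**2, 0.0)
                dfk = p["df_u"] + delta.astype(float)
                var_k = (S_u * p["df_u"] + ss) / rng.chisquare(dfk)
            elif self.prior == "BRR" and fixed_u is None:
                sigma_u2 = _scaled_inv_chi2(
                    rng, p["df_u"] + q, (S_u * p["df_u"] + u @ u) / (p["df_u"] + q)
                )
            elif self.prior == "BayesC" and fixed_u is None:
                m_in = int(delta.sum())
                sigma_u2 = _scaled_inv_chi2(
                    rng,
                    p["df_u"] + m_in,
                    (S_u * p["df_u"] + u @ u) / (p["df_u"] + m_in),
                )
            elif self.prior == "BL":
                nz = np.abs(u) > 1e-12
                mu_ig = np.sqrt(lam2 * sigma_e2 / np.maximum(u**2, 1e-24))
                inv_tau2 = rng.wald(np.minimum(mu_ig, 1e8), lam2)
                # for u_k ~ 0 the conditional degenerates; draw from the prior
                tau2 = np.where(
                    nz,
                    1.0 / np.maximum(inv_tau2, 1e-12),
                    rng.exponential(2.0 / lam2, q),
                )
                lam2 = rng.gamma(q + 1.0, 1.0 / (0.5 * np.sum(tau2) + 1.0))

            if not np.all(np.isfinite(u)):
                raise FloatingPointError(
                    f"{self.name}: sampler state non-finite at iteration {it}"
                )

            # residual variance
            if fixed_e is None:
                sse = e @ e
                sigma_e2 = _scaled_inv_chi2(
                    rng, p["df_e"] + n, (S_e * p["df_e"] + sse) / (p["df_e"] + n)
                )

            if it in keep_set:
                u_sum += u
                if kept < n_keep // 2:
                    u_first += u
                beta_sum += beta
                ve_chain[kept] = sigma_e2
                mu_chain[kept] = beta[0] if nW else 0.0
                kept += 1

        u_mean = u_sum / max(kept, 1)
        beta_mean = beta_sum / max(kept, 1)
        half = max(n_keep // 2, 1)
        u_half1 = u_first / half
        u_half2 = (u_sum - u_first) / max(kept - half, 1)
        mu, cov_eff = split_fixed(beta_mean, self.params["intercept"] and nW > 0)
        return EstimatorFit(
            spec=self.spec,
            mu=mu,
            covariate_effects=cov_eff,
            marker_effects=u_mean,
            variance_components={
                "sigma_u2": float(fixed_u) if fixed_u is not None else float(sigma_u2),
                "sigma_e2": float(np.mean(ve_chain[:kept])),
            },
            diagnostics={
                "converged": True,
                "n_kept": kept,
                "u_half_means": (u_half1, u_half2),
                "ve_chain": ve_chain[:kept],
                "mu_chain": mu_chain[:kept],
            },
        )

    def predict(self, fit, X_new=None, K_cross=None, covariates_new=None):
        if X_new is None:
            raise ValueError(f"{self.name} predicts from a design matrix")
        X_new = np.asarray(X_new, dtype=float)
        if X_new.shape[1] != fit.marker_effects.size:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, expected {fit.marker_effects.size}"
            )
        return fit.fixed_part(covariates_new, X_new.shape[0]) + X_new @ fit.marker_effects


class BRR(_GibbsWGR):
    name = "BRR"
    prior = "BRR"


class BayesA(_GibbsWGR):
    name = "BayesA"
    prior = "BayesA"


class BayesB(_GibbsWGR):
    name = "BayesB"
    prior = "BayesB"


class BayesC(_GibbsWGR):
    name = "BayesC"
    prior = "BayesC"


class BayesianLasso(_GibbsWGR):
    name = "BL"
    prior = "BL"
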