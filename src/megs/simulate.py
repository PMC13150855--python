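"""Synthetic multi-environment-trial generator with known ground truth.

Emulates the three inputs the frameworks consume — biallelic dosages,
smooth daily weather-like series per environment, and G-by-E phenotypes —
so every estimator and framework is testable end to end without external
data. Phenotypes follow the interaction model

    y_ijr = mu + beta x_j + sum_k m_ik (a_k + b_k x_j) + eps_ijr

where x_j is the centred window mean of one designated causal factor, a
and b are sparse main and interaction marker effects, and the residual
variance is calibrated on the realized genetic values so the broad-sense
heritability H = Vg / (Vg + Vge/L + Ve/(R L)) hits the configured target.

The generator returns a truth record (effects, index, noise draws,
variance components) sufficient to regenerate every phenotype exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from megs.data import EnvIndex, EnvSeries, GenotypeMatrix, PhenoTable


@dataclass
class SimConfig:
    """Study conditions for one simulated MET.

    Defaults describe a modest trial: 200 genotypes x 100 independent
    markers, six environments monitored daily for 60 days over three
    weather-like factors, sparse genetic architecture (20 main-effect and
    10 interaction QTL), heritability 0.5, one replicate.
    """

    n: int = 200
    p: int = 100
    maf_range: tuple[float, float] = (0.1, 0.5)
    m: int = 6
    days: int = 60
    factors: tuple[str, ...] = ("F1", "F2", "F3")
    causal_factor: str = "F2"
    causal_window: tuple[int, int] = (21, 35)
    n_qtl_main: int = 20
    n_qtl_inter: int = 10
    effect_sd_main: float = 1.0
    effect_sd_inter: float = 0.5
    mu: float = 10.0
    beta: float = 0.5
    h2: float = 0.5
    replicates: int = 1
    noise_sd: float | None = None   # overrides h2 calibration when set
    # environment-series shape
    factor_base: float = 20.0
    factor_amplitude: float = 8.0
    env_offset_sd: float = 1.0
    day_noise_sd: float = 0.5
    # optional AR(1) correlation between neighbouring marker frequencies
    maf_ar1: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        s, e = self.causal_window
        if not (1 <= s <= e <= self.days):
            raise ValueError(f"causal window {self.causal_window} outside day range 1..{self.days}")
        if self.causal_factor not in self.factors:
            raise ValueError(f"causal factor {self.causal_factor!r} not among {self.factors}")
        if self.n_qtl_main > self.p or self.n_qtl_inter > self.p:
            raise ValueError("more QTL requested than markers")

    def env_ids(self) -> list[str]:
        return [f"E{j + 1}" for j in range(self.m)]


@dataclass
class SimPhenotypes:
    """Simulated phenotypes plus the generative truth.

    ``pheno`` carries replicate means (one record per genotype x
    environment); ``replicated`` the raw per-replicate records with a
    ``rep`` column; ``truth`` everything needed to regenerate the data.
    """

    pheno: PhenoTable
    replicated: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _rngs(seed: int, n_streams: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_streams)]


def sim_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Independent biallelic dosages ~ Binomial(2, p_k), p_k uniform in
    maf_range (optionally AR(1)-smoothed along the genome)."""
    rng = _rngs(cfg.seed, 3)[0]
    lo, hi = cfg.maf_range
    if cfg.maf_ar1:
        z = np.empty(cfg.p)
        z[0] = rng.standard_normal()
        for k in range(1, cfg.p):
            z[k] = cfg.maf_ar1 * z[k - 1] + np.sqrt(1 - cfg.maf_ar1**2) * rng.standard_normal()
        from scipy.stats import norm

        freqs = lo + (hi - lo) * norm.cdf(z)
    else:
        freqs = rng.uniform(lo, hi, size=cfg.p)
    dosages = rng.binomial(2, freqs, size=(cfg.n, cfg.p)).astype(float)
    sample_ids = [f"G{i + 1:04d}" for i in range(cfg.n)]
    marker_ids = [f"M{k + 1:04d}" for k in range(cfg.p)]
    return GenotypeMatrix(sample_ids, marker_ids, dosages)


def sim_environments(cfg: SimConfig) -> EnvSeries:
    """Smooth seasonal curves per (environment, factor): a sinusoid with a
    factor-specific phase, an environment-level offset (the source of
    between-environment index variance), and day-level noise."""
    rng = _rngs(cfg.seed, 3)[1]
    days = np.arange(1, cfg.days + 1)
    # environment offsets form a symmetric ladder with sd exactly
    # env_offset_sd (permuted per factor), so the between-environment
    # spread of any window mean is controlled rather than a small-sample
    # draw — with few environments a random draw would make the index
    # spread (and hence the interaction variance) wildly seed-dependent
    if cfg.m > 1 and cfg.env_offset_sd:
        ladder = np.linspace(-1.0, 1.0, cfg.m)
        ladder = ladder / ladder.std() * cfg.env_offset_sd
    else:
        ladder = np.zeros(cfg.m)
    rows = []
    for f_i, factor in enumerate(cfg.factors):
        phase = 2 * np.pi * f_i / max(len(cfg.factors), 1)
        season = cfg.factor_base + cfg.factor_amplitude * np.sin(
            2 * np.pi * days / cfg.days + phase
        )
        offsets = rng.permutation(ladder)
        for env, offset in zip(cfg.env_ids(), offsets):
            noise = (
                rng.normal(0.0, cfg.day_noise_sd, size=cfg.days)
                if cfg.day_noise_sd
                else np.zeros(cfg.days)
            )
            vals = season + offset + noise
            rows += [(env, int(d), factor, float(v)) for d, v in zip(days, vals)]
    return EnvSeries(pd.DataFrame(rows, columns=["environment", "day", "factor", "value"]))


def true_index(cfg: SimConfig, series: EnvSeries) -> EnvIndex:
    """The generative environmental index: window mean of the causal factor."""
    from megs.ceris import window_mean

    raw = window_mean(series, cfg.causal_factor, cfg.causal_window)
    return EnvIndex(cfg.causal_factor, cfg.causal_window, raw)


def _balanced_components(g: np.ndarray) -> tuple[float, float]:
    """Variance decomposition of a noiseless genotype x environment value
    table into genotype main (Vg) and interaction (Vge) variance."""
    g_mean = g.mean(axis=1, keepdims=True)
    e_mean = g.mean(axis=0, keepdims=True)
    grand = g.mean()
    Vg = float(np.var(g_mean.ravel(), ddof=1))
    inter = g - g_mean - e_mean + grand
    # per-cell interaction variance with genotype/environment df removed
    n, m = g.shape
    Vge = float(np.sum(inter**2) / ((n - 1) * (m - 1))) if m > 1 else 0.0
    return Vg, Vge


def sim_phenotypes(
    geno: GenotypeMatrix, series: EnvSeries, cfg: SimConfig
) -> SimPhenotypes:
    """Generate phenotypes under the interaction model with calibrated noise."""
    rng = _rngs(cfg.seed, 3)[2]
    index = true_index(cfg, series)
    envs = cfg.env_ids()
    x = np.array([index.centred_index[e] for e in envs])
    M = geno.dosages

    a = np.zeros(cfg.p)
    b = np.zeros(cfg.p)
    if cfg.h2 > 0:
        qtl_main = rng.choice(cfg.p, size=cfg.n_qtl_main, replace=False)
        qtl_inter = rng.choice(cfg.p, size=cfg.n_qtl_inter, replace=False)
        a[qtl_main] = rng.normal(0.0, cfg.effect_sd_main, size=cfg.n_qtl_main)
        b[qtl_inter] = rng.normal(0.0, cfg.effect_sd_inter, size=cfg.n_qtl_inter)
    else:
        qtl_main = np.array([], dtype=int)
        qtl_inter = np.array([], dtype=int)

    # genetic value of genotype i in environment j
    G_val = (M @ a)[:, None] + (M @ b)[:, None] * x[None, :]
    signal = cfg.mu + cfg.beta * x[None, :] + G_val

    # beta*x is a fixed environmental term; only G_val feeds Vg and Vge
    Vg, Vge = _balanced_components(G_val)
    L, R = cfg.m, cfg.replicates
    if cfg.noise_sd is not None:
        Ve = float(cfg.noise_sd) ** 2
    elif cfg.h2 <= 0:
        Ve = 1.0
    elif cfg.h2 >= 1:
        Ve = 0.0
    else:
        # solve H = Vg / (Vg + Vge/L + Ve/(R L)) for Ve
        Ve = R * (L * Vg * (1 - cfg.h2) / cfg.h2 - Vge)
        if Ve < 0:
            raise ValueError(
                f"target h2={cfg.h2} unattainable: interaction variance "
                f"Vge={Vge:.3g} already exceeds the allowed denominator share"
            )
    eps = rng.normal(0.0, np.sqrt(Ve), size=(cfg.n, cfg.m, R)) if Ve > 0 else np.zeros(
        (cfg.n, cfg.m, R)
    )
    y = signal[:, :, None] + eps

    rep_rows = []
    for j, env in enumerate(envs):
        for r in range(R):
            for i, gid in enumerate(geno.sample_ids):
                rep_rows.append((gid, env, "sim", r + 1, float(y[i, j, r])))
    replicated = pd.DataFrame(
        rep_rows, columns=["genotype", "environment", "trait", "rep", "value"]
    )
    means = replicated.groupby(["genotype", "environment", "trait"], sort=False)[
        "value"
    ].mean().reset_index()
    pheno = PhenoTable(means)

    truth = {
        "a": a,
        "b": b,
        "qtl_main": qtl_main,
        "qtl_inter": qtl_inter,
        "e_j": {e: index.raw_index[e] for e in envs},
        "x_j": {e: float(v) for e, v in zip(envs, x)},
        "index": index,
        "mu": cfg.mu,
        "beta": cfg.beta,
        "Vg": Vg,
        "Vge": Vge,
        "Ve": Ve,
        "eps": eps,
        "signal": signal,
        "config": cfg,
    }
    return SimPhenotypes(pheno=pheno, replicated=replicated, truth=truth)


def regenerate(geno: GenotypeMatrix, truth: dict) -> np.ndarray:
    """Recompute the full phenotype array from the truth record alone."""
    cfg: SimConfig = truth["config"]
    envs = cfg.env_ids()
    x = np.array([truth["x_j"][e] for e in envs])
    M = geno.dosages
    signal = cfg.mu + cfg.beta * x[None, :] + (M @ truth["a"])[:, None] + (
        M @ truth["b"]
    )[:, None] * x[None, :]
    return signal[:, :, None] + truth["eps"]
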