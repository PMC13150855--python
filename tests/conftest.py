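import numpy as np
import pandas as pd
import pytest

from megs.data import EnvIndex, EnvSeries, GenotypeMatrix, PhenoTable
from megs.simulate import SimConfig, sim_environments, sim_genotypes, sim_phenotypes


@pytest.fixture
def toy_geno() -> GenotypeMatrix:
    rng = np.random.default_rng(11)
    M = rng.binomial(2, 0.4, size=(24, 15)).astype(float)
    return GenotypeMatrix(
        [f"g{i:02d}" for i in range(24)], [f"m{k:02d}" for k in range(15)], M
    )


@pytest.fixture
def toy_index() -> EnvIndex:
    return EnvIndex("TEMP", (1, 10), {"A": 10.0, "B": 12.0, "C": 15.0, "D": 19.0})


def make_pheno(values: dict[tuple[str, str], float], trait: str = "t") -> PhenoTable:
    rows = [(g, e, trait, v) for (g, e), v in values.items()]
    return PhenoTable(
        pd.DataFrame(rows, columns=["genotype", "environment", "trait", "value"])
    )


@pytest.fixture
def noiseless_sim():
    """Deterministic MET with zero residual and zero day-level noise: the
    environment-mean phenotype is an exact linear function of the causal
    window mean."""
    cfg = SimConfig(n=80, p=50, m=6, seed=7, noise_sd=0.0, day_noise_sd=0.0)
    geno = sim_genotypes(cfg)
    series = sim_environments(cfg)
    sim = sim_phenotypes(geno, series, cfg)
    return cfg, geno, series, sim


@pytest.fixture
def noisy_sim():
    cfg = SimConfig(n=120, p=60, m=5, seed=19, h2=0.6)
    geno = sim_genotypes(cfg)
    series = sim_environments(cfg)
    sim = sim_phenotypes(geno, series, cfg)
    return cfg, geno, series, sim
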