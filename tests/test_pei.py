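"""PEI framework: interaction design and kinship construction oracles,
marker/kinship equivalence, generative recovery and the interaction-vs-
main-effects contrast."""

import numpy as np
import pandas as pd
import pytest

from megs.data import EnvIndex, GenotypeMatrix, PhenoTable
from megs.estimators import EstimatorSpec
from megs.pei import (
    PEIModel,
    build_design,
    build_interaction_block,
    build_kinship,
    fit_predict_pei,
    genomic_relationship,
)
from tests.conftest import make_pheno


def random_instance(seed, n=20, p=40, envs=("A", "B", "C")):
    rng = np.random.default_rng(seed)
    M = rng.binomial(2, 0.4, size=(n, p)).astype(float)
    geno = GenotypeMatrix([f"g{i}" for i in range(n)], [f"m{k}" for k in range(p)], M)
    raw = {e: float(v) for e, v in zip(envs, rng.uniform(5, 15, len(envs)))}
    index = EnvIndex("F", (1, 5), raw)
    return rng, geno, index


class TestInteractionBlock:
    def test_scalar_multiple(self):
        M = np.array([[1.0, 0.0], [2.0, 1.0]])
        np.testing.assert_array_equal(
            build_interaction_block(M, 2.0), [[2.0, 0.0], [4.0, 2.0]]
        )

    def test_zero_index_gives_zero_block(self):
        M = np.array([[1.0, 2.0]])
        np.testing.assert_array_equal(build_interaction_block(M, 0.0), [[0.0, 0.0]])

    def test_unit_index_returns_matrix(self):
        M = np.array([[1.0, 2.0], [0.0, 1.0]])
        np.testing.assert_array_equal(build_interaction_block(M, 1.0), M)


class TestDesign:
    def test_block_structure_at_zero_one(self):
        M = np.array([[1.0, 0.0], [2.0, 1.0]])
        geno = GenotypeMatrix(["a", "b"], ["m1", "m2"], M)
        index = EnvIndex("F", (1, 2), {"E1": 1.0, "E2": 2.0})  # centred x = (-0.5, +0.5)
        # force centred values 0 and 1 via raw 1.0/2.0 is not possible; use cells
        index = EnvIndex.__new__(EnvIndex)
        index.factor_name = "F"
        index.window = (1, 2)
        index.raw_index = {"E1": 0.0, "E2": 1.0}
        index.centre = 0.0
        index.centred_index = {"E1": 0.0, "E2": 1.0}
        index.r2 = 0.0
        design = build_design(geno, index, ["E1", "E2"])
        assert design.X_all.shape == (4, 4)
        np.testing.assert_array_equal(design.X_all[:2, 2:], 0.0)       # env-1: [M | 0]
        np.testing.assert_array_equal(design.X_all[2:, 2:], M)         # env-2: [M | M]
        np.testing.assert_array_equal(design.X_all[:2, :2], M)
        assert design.covariate.tolist() == [0.0, 0.0, 1.0, 1.0]

    def test_column_count_doubles_markers(self):
        _, geno, index = random_instance(0)
        design = build_design(geno, index)
        assert design.X_all.shape[1] == 2 * geno.p
        assert len(design.rows) == geno.n * 3

    def test_unknown_environment_rejected(self):
        _, geno, index = random_instance(1)
        with pytest.raises(KeyError):
            build_design(geno, index, ["A", "Z"])


class TestKinship:
    def test_zero_index_collapses_to_ones_kron_G(self):
        _, geno, _ = random_instance(2)
        index = EnvIndex("F", (1, 2), {"A": 3.0, "B": 3.0, "C": 3.0})  # x = 0 everywhere
        K = build_kinship(geno, index, grm="crossprod")
        G = geno.dosages @ geno.dosages.T
        n = geno.n
        for bi in range(3):
            for bj in range(3):
                np.testing.assert_allclose(
                    K[bi * n:(bi + 1) * n, bj * n:(bj + 1) * n], G, atol=1e-12
                )

    def test_single_environment_scaling(self):
        _, geno, _ = random_instance(3)
        index = EnvIndex.__new__(EnvIndex)
        index.factor_name, index.window = "F", (1, 2)
        index.raw_index = {"A": 2.0}
        index.centre = 0.0
        index.centred_index = {"A": 2.0}
        index.r2 = 0.0
        K = build_kinship(geno, index, environments=["A"], grm="crossprod")
        G = geno.dosages @ geno.dosages.T
        np.testing.assert_allclose(K, (1 + 4.0) * G, atol=1e-9)

    def test_blocks_equal_design_crossproduct(self):
        """(1 + x_j x_j') G blocks == X_all X_all' when G = MM'."""
        _, geno, index = random_instance(4)
        K = build_kinship(geno, index, grm="crossprod")
        design = build_design(geno, index)
        np.testing.assert_allclose(K, design.X_all @ design.X_all.T, atol=1e-9)

    def test_kinship_psd(self):
        _, geno, index = random_instance(5)
        for grm in ("crossprod", "vanraden"):
            K = build_kinship(geno, index, grm=grm)
            w = np.linalg.eigvalsh(K)
            assert w.min() >= -1e-8 * np.trace(K) / K.shape[0]

    def test_vanraden_diagonal_scale(self):
        _, geno, index = random_instance(6)
        G = genomic_relationship(geno.dosages, "vanraden")
        # standardized GRM: mean diagonal near 1 for binomial dosages
        assert 0.5 < np.mean(np.diag(G)) < 2.0


def _pei_pheno(geno, index, a, b, mu=1.0, beta=0.5, noise=0.0, rng=None):
    envs = list(index.centred_index)
    x = np.array([index.centred_index[e] for e in envs])
    M = geno.dosages
    signal = mu + beta * x[None, :] + (M @ a)[:, None] + (M @ b)[:, None] * x[None, :]
    if noise and rng is not None:
        signal = signal + rng.normal(scale=noise, size=signal.shape)
    vals = {
        (g, e): float(signal[i, j])
        for i, g in enumerate(geno.sample_ids)
        for j, e in enumerate(envs)
    }
    return make_pheno(vals)


class TestFitPredict:
    def test_constant_phenotype_predicts_constant(self):
        _, geno, index = random_instance(7)
        pheno = make_pheno(
            {(g, e): 4.2 for g in geno.sample_ids for e in index.centred_index}
        )
        test = [(geno.sample_ids[0], "A"), (geno.sample_ids[1], "C")]
        pred = fit_predict_pei(pheno, geno, index, EstimatorSpec("rrBLUP", {"lam": 1.0}), test)
        np.testing.assert_allclose(pred["yhat"], 4.2, atol=1e-8)

    def test_noiseless_generative_recovery(self):
        """Phenotypes exactly mu + beta x + M(a + b x), shrinkage -> 0:
        held-out genotypes recovered to small relative error."""
        rng = np.random.default_rng(23)
        n, p = 200, 100
        M = rng.binomial(2, 0.4, size=(n, p)).astype(float)
        geno = GenotypeMatrix([f"g{i}" for i in range(n)], [f"m{k}" for k in range(p)], M)
        raw = {e: float(v) for e, v in zip("ABCD", rng.uniform(5, 15, 4))}
        index = EnvIndex("F", (1, 5), raw)
        a = rng.normal(scale=0.3, size=p)
        b = rng.normal(scale=0.15, size=p)
        pheno = _pei_pheno(geno, index, a, b)
        held = geno.sample_ids[160:]
        test_cells = [(g, e) for g in held for e in "ABCD"]
        pred = fit_predict_pei(
            pheno, geno, index, EstimatorSpec("rrBLUP", {"lam": 1e-8}), test_cells
        )
        obs = pheno.records.rename(columns={"value": "y"})
        merged = pred.merge(obs, on=["genotype", "environment"])
        rel = np.abs(merged["yhat"] - merged["y"]) / (np.abs(merged["y"]) + 1e-9)
        assert float(rel.max()) < 1e-3

    def test_marker_vs_kinship_forms_agree(self):
        rng, geno, index = random_instance(8)
        a = rng.normal(scale=0.3, size=geno.p)
        b = rng.normal(scale=0.2, size=geno.p)
        pheno = _pei_pheno(geno, index, a, b, noise=0.5, rng=rng)
        held = geno.sample_ids[15:]
        cells = [(g, e) for g in held for e in "ABC"]
        lam = 2.5
        pm = fit_predict_pei(pheno, geno, index, EstimatorSpec("rrBLUP", {"lam": lam}),
                             cells, grm="crossprod")
        pk = fit_predict_pei(pheno, geno, index, EstimatorSpec("GBLUP", {"lam": lam}),
                             cells, grm="crossprod")
        assert np.max(np.abs(pm["yhat"].to_numpy() - pk["yhat"].to_numpy())) < 1e-8

    def test_environment_order_invariance(self):
        rng, geno, index = random_instance(9)
        a = rng.normal(scale=0.3, size=geno.p)
        b = rng.normal(scale=0.2, size=geno.p)
        pheno = _pei_pheno(geno, index, a, b, noise=0.3, rng=rng)
        cells = [(geno.sample_ids[0], "B"), (geno.sample_ids[1], "A")]
        spec = EstimatorSpec("rrBLUP", {"lam": 1.0})
        p1 = fit_predict_pei(pheno, geno, index, spec, cells)
        # same records, environment blocks shuffled
        shuffled = PhenoTable(
            pheno.records.sort_values(["environment", "genotype"],
                                      ascending=[False, False]).reset_index(drop=True)
        )
        p2 = fit_predict_pei(shuffled, geno, index, spec, cells)
        m = p1.merge(p2, on=["genotype", "environment"])
        np.testing.assert_allclose(m["yhat_x"], m["yhat_y"], atol=1e-8)

    def test_novel_environment_prediction(self):
        rng, geno, index = random_instance(10, envs=("A", "B", "C", "D"))
        a = rng.normal(scale=0.3, size=geno.p)
        b = rng.normal(scale=0.2, size=geno.p)
        pheno_full = _pei_pheno(geno, index, a, b)
        # train without environment D entirely
        train_rec = pheno_full.records[pheno_full.records["environment"] != "D"]
        model = PEIModel(PhenoTable(train_rec.reset_index(drop=True)), geno,
                         _drop_env(index, "D"), grm="crossprod")
        res = model.fit(spec=EstimatorSpec("rrBLUP", {"lam": 1e-8}))
        idx_ext = model.index.extend({"D": index.raw_index["D"]})
        cells = [(g, "D") for g in geno.sample_ids]
        pred = res.predict_cells(cells, index=idx_ext)
        obs = pheno_full.records[pheno_full.records["environment"] == "D"]
        merged = pred.merge(obs, on=["genotype", "environment"])
        r = np.corrcoef(merged["yhat"], merged["value"])[0, 1]
        assert r > 0.99

    def test_unknown_test_genotype_rejected(self):
        _, geno, index = random_instance(11)
        pheno = make_pheno({(g, e): 1.0 for g in geno.sample_ids for e in "ABC"})
        model = PEIModel(pheno, geno, index)
        with pytest.raises(KeyError, match="absent"):
            model.fit(test_cells=[("ghost", "A")])

    def test_blockdiag_mode_refuses_novel_environment(self):
        rng, geno, index = random_instance(12)
        a = rng.normal(scale=0.3, size=geno.p)
        pheno = _pei_pheno(geno, index, a, np.zeros(geno.p))
        train_rec = pheno.records[pheno.records["environment"] != "C"]
        model = PEIModel(PhenoTable(train_rec.reset_index(drop=True)), geno, index,
                         shared_effects=False)
        with pytest.raises(ValueError, match="block-diagonal"):
            model.fit(spec=EstimatorSpec("rrBLUP", {"lam": 1.0}),
                      test_cells=[(geno.sample_ids[0], "C")])


def _drop_env(index, env):
    raw = {e: v for e, v in index.raw_index.items() if e != env}
    return EnvIndex(index.factor_name, index.window, raw, index.r2 if not np.isnan(index.r2) else np.nan)


class TestInteractionContrast:
    def test_pei_beats_main_effects_under_strong_interaction(self):
        """On data with strong polygenic interaction, the interaction model
        out-predicts the main-effects baseline for held-out genotypes in
        nearly all replicates (full contrast incl. the null arm runs in the
        acceptance suite)."""
        from megs.simulate import (
            SimConfig,
            sim_environments,
            sim_genotypes,
            sim_phenotypes,
            true_index,
        )

        wins = 0
        n_rep = 5
        for s in range(n_rep):
            cfg = SimConfig(n=120, p=60, m=4, h2=0.5, effect_sd_inter=1.0,
                            causal_window=(21, 35), seed=4000 + s)
            geno = sim_genotypes(cfg)
            series = sim_environments(cfg)
            sim = sim_phenotypes(geno, series, cfg)
            idx = true_index(cfg, series)
            held = geno.sample_ids[96:]
            cells = [(g, e) for g in held for e in cfg.env_ids()]
            obs = sim.pheno.records.rename(columns={"value": "y"})
            accs = {}
            for inter in (True, False):
                pred = fit_predict_pei(sim.pheno, geno, idx, "rrBLUP", cells,
                                       interaction=inter)
                m = pred.merge(obs, on=["genotype", "environment"])
                accs[inter] = np.mean(
                    [np.corrcoef(sub["yhat"], sub["y"])[0, 1]
                     for _, sub in m.groupby("environment")]
                )
            wins += accs[True] > accs[False]
        assert wins >= n_rep - 1
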