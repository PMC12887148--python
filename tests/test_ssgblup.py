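import warnings

import numpy as np
import pandas as pd
import pytest

from ssprofit import SimConfig, simulate_dataset
from ssprofit.containers import GenotypeMatrix, PedigreeTable
from ssprofit.errors import ConfigError
from ssprofit.kinship import build_A, build_A_inverse, build_relationships
from ssprofit.ssgblup import (
    EvaluationModel,
    SingleStepModel,
    assemble_mme,
    backsolve_snp_effects,
    normalize_weights,
    run_weighted_iterations,
    snp_variance,
    solve_mme,
    update_weights_linear,
    update_weights_nonlinear,
    window_variance,
)


def _phen(ped, y, trait="y", **extra):
    df = pd.DataFrame({"animal": ped.ids, "farm": 1, "year": 2000,
                       "season": "dry", "mg": 1, "sex": "M"})
    for k, v in extra.items():
        df[k] = v
    df[trait] = y
    return df


@pytest.fixture
def chain_pedigree():
    rng = np.random.default_rng(31)
    n = 30
    sire = [0] * 6 + [int(rng.integers(1, i)) for i in range(7, n + 1)]
    dam = [0] * 6 + [int(rng.integers(1, i)) for i in range(7, n + 1)]
    sire, dam = np.array(sire), np.array(dam)
    clash = sire == dam
    dam[clash] = np.maximum(dam[clash] - 1, 0)
    df = pd.DataFrame({"id": np.arange(1, n + 1), "sire": sire, "dam": dam})
    df.loc[df["sire"] == df["id"], "sire"] = 0
    df.loc[df["dam"] == df["id"], "dam"] = 0
    return PedigreeTable(df)


class TestAssembleSolve:
    def test_matches_dense_gls_with_missing_multitrait(self, chain_pedigree):
        """Two traits, partial missingness: MME solution equals direct GLS
        on the equivalent multivariate-normal model."""
        ped = chain_pedigree
        n = len(ped)
        rng = np.random.default_rng(5)
        G0 = np.array([[2.0, 1.0], [1.0, 3.0]])
        R0 = np.array([[4.0, 0.8], [0.8, 5.0]])
        y = rng.normal(10, 2, size=(n, 2))
        y[rng.random(n) < 0.3, 1] = np.nan  # trait 2 missing for some
        sexes = np.where(np.arange(n) % 2 == 0, "M", "F")
        phen = _phen(ped, y[:, 0], trait="t1", sex=sexes)
        phen["t2"] = y[:, 1]

        em = EvaluationModel(traits=("t1", "t2"), scheme="MT_ss", G0=G0, R0=R0)
        A, F = build_A(ped)
        A_inv = build_A_inverse(ped, F)
        sol = solve_mme(assemble_mme(phen, em, ped, A_inv))

        # dense GLS oracle over observed (animal, trait) records
        obs = [(i, t) for i in range(n) for t in range(2)
               if not np.isnan(y[i, t])]
        yv = np.array([y[i, t] for i, t in obs])
        cg_keys = sorted({(t, sexes[i]) for i, t in obs})
        X = np.zeros((len(obs), len(cg_keys)))
        for r, (i, t) in enumerate(obs):
            X[r, cg_keys.index((t, sexes[i]))] = 1.0
        V = np.zeros((len(obs), len(obs)))
        for r, (i, t) in enumerate(obs):
            for c, (j, s) in enumerate(obs):
                V[r, c] = G0[t, s] * A[i, j] + (R0[t, s] if i == j else 0.0)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ yv)
        resid = Vi @ (yv - X @ beta)
        C = np.zeros((n * 2, len(obs)))  # cov(u_(a,t), y_obs)
        for a in range(n):
            for t in range(2):
                for c, (j, s) in enumerate(obs):
                    C[t * n + a, c] = G0[t, s] * A[a, j]
        u = C @ resid
        got = np.concatenate([sol.gebv["t1"].to_numpy(), sol.gebv["t2"].to_numpy()])
        assert np.abs(got - u).max() < 1e-8

    def test_uncorrelated_traits_split_into_single_trait_systems(self, chain_pedigree):
        ped = chain_pedigree
        rng = np.random.default_rng(6)
        y1 = rng.normal(0, 1, len(ped))
        y2 = rng.normal(0, 1, len(ped))
        phen = _phen(ped, y1, trait="t1")
        phen["t2"] = y2
        A_inv = build_A_inverse(ped)
        em2 = EvaluationModel(traits=("t1", "t2"), scheme="MT_ss",
                              G0=np.diag([2.0, 3.0]), R0=np.diag([4.0, 5.0]))
        joint = solve_mme(assemble_mme(phen, em2, ped, A_inv))
        for tr, g, r in (("t1", 2.0, 4.0), ("t2", 3.0, 5.0)):
            em1 = EvaluationModel(traits=(tr,), scheme="ST_ss",
                                  G0=[[g]], R0=[[r]])
            single = solve_mme(assemble_mme(phen, em1, ped, A_inv))
            assert np.abs(joint.gebv[tr] - single.gebv[tr]).max() < 1e-9

    def test_direct_and_pcg_agree(self, chain_pedigree):
        ped = chain_pedigree
        rng = np.random.default_rng(7)
        phen = _phen(ped, rng.normal(5, 2, len(ped)))
        em = EvaluationModel(traits=("y",), scheme="ST_ss", G0=[[1.5]], R0=[[3.0]])
        sys_ = assemble_mme(phen, em, ped, build_A_inverse(ped))
        a = solve_mme(sys_, method="pcg")
        b = solve_mme(sys_, method="direct")
        assert np.abs(a.gebv["y"] - b.gebv["y"]).max() < 1e-8

    def test_solution_invariant_to_record_order(self, chain_pedigree):
        ped = chain_pedigree
        rng = np.random.default_rng(8)
        phen = _phen(ped, rng.normal(5, 2, len(ped)))
        em = EvaluationModel(traits=("y",), scheme="ST_ss", G0=[[1.5]], R0=[[3.0]])
        A_inv = build_A_inverse(ped)
        base = solve_mme(assemble_mme(phen, em, ped, A_inv))
        shuffled = phen.sample(frac=1.0, random_state=1).reset_index(drop=True)
        perm = solve_mme(assemble_mme(shuffled, em, ped, A_inv))
        assert np.abs(base.gebv["y"] - perm.gebv["y"]).max() < 1e-9

    def test_missing_cg_factor_errors(self, chain_pedigree):
        ped = chain_pedigree
        phen = _phen(ped, np.ones(len(ped))).drop(columns=["season"])
        em = EvaluationModel(traits=("y",), scheme="ST_ss", G0=[[1.0]], R0=[[1.0]])
        from ssprofit.errors import DataError
        with pytest.raises(DataError):
            assemble_mme(phen, em, ped, build_A_inverse(ped))


class TestReductions:
    def test_no_genotypes_equals_pedigree_blup(self, small_dataset):
        ds = small_dataset
        em = EvaluationModel(traits=("PFT",), scheme="ST_ss",
                             G0=ds.config.G0, R0=ds.config.R0)
        ped_fit = SingleStepModel(ds.phenotypes, ds.pedigree, None, em).fit()
        A_inv = build_A_inverse(ds.pedigree)
        direct = solve_mme(assemble_mme(ds.phenotypes, em, ds.pedigree, A_inv))
        assert np.abs(ped_fit.gebv["PFT"] - direct.gebv["PFT"]).max() < 1e-8

    def test_all_genotyped_equals_gblup_with_G(self):
        cfg = SimConfig(n_founders=60, n_generations=1, n_snps=300, seed=19,
                        trait_names=("PFT",), G0=np.array([[30.0]]),
                        R0=np.array([[70.0]]), genotyped_fraction=1.0)
        ds = simulate_dataset(cfg)
        em = EvaluationModel(traits=("PFT",), scheme="ST_ss",
                             G0=cfg.G0, R0=cfg.R0)
        ss = SingleStepModel(ds.phenotypes, ds.pedigree, ds.genotypes, em).fit()
        rel = build_relationships(ds.pedigree, ds.genotypes)
        # all animals genotyped: H^-1 reduces to G_adj^-1
        import scipy.sparse as sp
        K_inv = sp.csr_matrix(np.linalg.inv(rel.G_adj))
        # reorder K_inv to pedigree order of genotyped ids
        order = np.argsort(ds.pedigree.index_of(ds.genotypes.ids))
        K_inv = sp.csr_matrix(np.linalg.inv(rel.G_adj)[np.ix_(order, order)])
        gblup = solve_mme(assemble_mme(ds.phenotypes, em, ds.pedigree, K_inv))
        assert np.abs(ss.gebv["PFT"] - gblup.gebv["PFT"]).max() < 1e-6


class TestSnpEffects:
    def _geno(self, n=40, m=60, seed=9):
        rng = np.random.default_rng(seed)
        mat = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        return GenotypeMatrix(ids=np.arange(1, n + 1), matrix=mat)

    def test_zero_gebv_zero_effects(self):
        g = self._geno()
        u = backsolve_snp_effects(np.zeros(g.n_animals), g)
        assert np.allclose(u, 0.0)

    def test_projection_identity_in_column_space(self):
        g = self._geno()
        p = g.allele_freqs()
        Z = g.imputed() - 2 * p
        v = np.random.default_rng(1).normal(0, 1, g.n_snps)
        a_g = Z @ v  # lies in the column space of Z
        u = backsolve_snp_effects(a_g, g)
        assert np.abs(Z @ u - a_g).max() < 1e-6

    def test_single_snp_scalar_solution(self):
        # 1 SNP, D = I: u = lam * z' (z z' lam)^-1 a = regression through solve
        mat = np.array([[2.0], [0.0], [1.0], [1.0]])
        g = GenotypeMatrix(ids=[1, 2, 3, 4], matrix=mat)
        a_g = np.array([1.0, -1.0, 0.0, 0.0])
        p = g.allele_freqs()[0]
        z = mat[:, 0] - 2 * p
        lam = 1.0 / (2 * p * (1 - p))
        Gs = np.outer(z, z) * lam + 1e-9 * np.eye(4)
        expected = lam * z @ np.linalg.solve(Gs, a_g)
        got = backsolve_snp_effects(a_g, g, ridge=1e-9)
        assert got[0] == pytest.approx(expected, rel=1e-5)

    def test_snp_variance_values(self):
        assert snp_variance(np.array([0.0]), np.array([0.3]))[0] == 0.0
        assert snp_variance(np.array([1.0]), np.array([0.5]))[0] == pytest.approx(0.5)
        # allele-label flip: p <-> 1-p with sign-flipped effect
        a = snp_variance(np.array([0.7]), np.array([0.2]))[0]
        b = snp_variance(np.array([-0.7]), np.array([0.8]))[0]
        assert a == pytest.approx(b)


class TestWeights:
    def test_linear_weights_track_effect_size(self):
        p = np.full(4, 0.5)
        u = np.array([0.0, 1.0, -2.0, 3.0])
        d = update_weights_linear(u, p)
        assert d[0] == 0.0
        assert (np.diff(d) > 0).all()

    def test_uniform_effects_uniform_weights(self):
        p = np.full(5, 0.3)
        d = normalize_weights(update_weights_linear(np.full(5, 1.7), p), p)
        assert np.allclose(d, 1.0)

    def test_nonlinear_reference_points(self):
        u = np.array([4.0, -4.0, 0.0, 2.0, -2.0])
        d = update_weights_nonlinear(u)
        assert d[np.abs(u) == 0][0] == pytest.approx(1.125 ** (-2), rel=1e-10)
        # increasing in |u|
        order = np.argsort(np.abs(u))
        assert (np.diff(d[order]) >= 0).all()

    def test_nonlinear_unit_weight_at_two_sd(self):
        # symmetric vector with sd exactly 1 and extreme entries at +-2:
        # mean(v^2) = (2*4 + 8*0.25)/10 = 1, so |v|/sd = 2 at the extremes
        v = np.array([2.0, -2.0] + [0.5, -0.5] * 4)
        assert np.std(v) == pytest.approx(1.0)
        d = update_weights_nonlinear(v)
        assert d[0] == pytest.approx(1.0, rel=1e-10)
        assert d[1] == pytest.approx(1.0, rel=1e-10)

    def test_nonlinear_zero_sd_warns_unit_weights(self):
        with pytest.warns(UserWarning):
            d = update_weights_nonlinear(np.zeros(4))
        assert np.allclose(d, 1.0)

    def test_normalize_identity_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.1, 0.9, 30)
        assert np.allclose(normalize_weights(np.ones(30), p), 1.0)
        d = rng.uniform(0.1, 5.0, 30)
        assert np.allclose(normalize_weights(7 * d, p), normalize_weights(d, p))

    def test_normalize_conserves_total_variance(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.05, 0.95, 200)
        het = 2 * p * (1 - p)
        d = rng.exponential(1.0, 200)
        out = normalize_weights(d, p)
        assert abs(np.sum(out * het) - np.sum(het)) < 1e-10


class TestWeightedIterations:
    def _setup(self, seed=23, n_founders=80, n_snps=300, qtl_fraction=0.02):
        cfg = SimConfig(n_founders=n_founders, n_generations=2, n_snps=n_snps,
                        seed=seed, trait_names=("PFT",),
                        G0=np.array([[60.0]]), R0=np.array([[40.0]]),
                        genotyped_fraction=1.0, qtl_fraction=qtl_fraction)
        return cfg, simulate_dataset(cfg)

    def test_first_iteration_is_plain_ssgblup(self):
        cfg, ds = self._setup()
        em = EvaluationModel(traits=("PFT",), scheme="ST_ss",
                             G0=cfg.G0, R0=cfg.R0)
        iters = run_weighted_iterations(ds.phenotypes, ds.pedigree, ds.genotypes,
                                        em, n_iter=1, scheme="linear")
        st = SingleStepModel(ds.phenotypes, ds.pedigree, ds.genotypes, em).fit()
        assert len(iters) == 1
        assert np.allclose(iters[0]["weights"], 1.0)
        assert np.abs(iters[0]["gebv_set"].gebv["PFT"] - st.gebv["PFT"]).max() < 1e-8

    def test_linear_weights_concentrate_on_true_qtl_windows(self):
        cfg, ds = self._setup(seed=29)
        em = EvaluationModel(traits=("PFT",), scheme="ST_ss",
                             G0=cfg.G0, R0=cfg.R0)
        iters = run_weighted_iterations(ds.phenotypes, ds.pedigree, ds.genotypes,
                                        em, n_iter=2, scheme="linear")
        w2 = iters[1]["weights"]
        qtl = np.flatnonzero(ds.truth.qtl_effects[:, 0] != 0)
        # window (10-SNP) weight mass; true-QTL windows should rank high
        n_win = cfg.n_snps // 10
        mass = w2[: n_win * 10].reshape(n_win, 10).sum(axis=1)
        qtl_windows = np.unique(qtl // 10)
        ranks = pd.Series(mass).rank(ascending=False)[qtl_windows]
        top_decile = max(1, int(np.ceil(n_win / 10)))
        big5 = np.argsort(np.abs(ds.truth.qtl_effects[qtl, 0]))[::-1][:5]
        assert (ranks.iloc[:].min() <= top_decile)  # best QTL window in top decile
        assert (pd.Series(mass).rank(ascending=False)[np.unique(qtl[big5] // 10)]
                <= top_decile * 2).any()

    def test_weighted_scheme_fit_runs_and_differs(self):
        cfg, ds = self._setup(seed=31)
        m = SingleStepModel.from_scheme("ST_sswl1", "PFT", ds.phenotypes,
                                        ds.pedigree, ds.genotypes,
                                        cfg.G0, cfg.R0, cfg.trait_names)
        res = m.fit()
        assert res.weights is not None and len(res.weight_history) == 1
        st = SingleStepModel.from_scheme("ST_ss", "PFT", ds.phenotypes,
                                         ds.pedigree, ds.genotypes,
                                         cfg.G0, cfg.R0, cfg.trait_names).fit()
        assert not np.allclose(res.gebv["PFT"], st.gebv["PFT"])
        assert "ST_sswl1" in res.summary()


class TestWindowVariance:
    def _toy(self, m=30, n=25, seed=17, chroms=(1, 2, 3)):
        rng = np.random.default_rng(seed)
        mat = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        snp_map = pd.DataFrame({"snp": [f"s{j}" for j in range(m)],
                                "chrom": np.repeat(chroms, m // len(chroms)),
                                "pos": np.tile(np.arange(1, m // len(chroms) + 1), len(chroms))})
        return GenotypeMatrix(ids=np.arange(n), matrix=mat, snp_map=snp_map)

    def test_zero_effects_zero_windows(self):
        g = self._toy()
        tab = window_variance(np.zeros(30), g)
        assert (tab["pct_variance"] == 0).all()

    def test_single_nonzero_snp_hits_only_its_window(self):
        g = self._toy()
        u = np.zeros(30)
        u[12] = 1.0
        tab = window_variance(u, g)
        nz = tab[tab["pct_variance"] > 0]
        assert len(nz) == 1
        assert nz.iloc[0]["chrom"] == g.snp_map["chrom"].iloc[12]

    def test_matches_brute_force_on_toy(self):
        g = self._toy()
        rng = np.random.default_rng(3)
        u = rng.normal(0, 0.2, 30)
        tab = window_variance(u, g, window=10)
        p = g.allele_freqs()
        Z = g.imputed() - 2 * p
        sigma2 = np.var(Z @ u)
        for _, row in tab.iterrows():
            idx = np.flatnonzero(
                (g.snp_map["chrom"] == row["chrom"]).to_numpy())
            idx = idx[np.argsort(g.snp_map["pos"].iloc[idx].to_numpy())]
            # windows are per-chromosome; toy has 10 SNPs per chromosome
            expected = 100.0 * np.var(Z[:, idx] @ u[idx]) / sigma2
            assert row["pct_variance"] == pytest.approx(expected, rel=1e-10)

    def test_windows_do_not_span_chromosomes_and_flag_truncation(self):
        g = self._toy(m=24, chroms=(1, 2, 3))  # 8 SNPs per chromosome
        tab = window_variance(np.ones(24), g, window=10)
        assert len(tab) == 3
        assert tab["truncated"].all()
        assert (tab.groupby("chrom")["n_snps"].sum() == 8).all()


class TestEvaluationModelValidation:
    def test_unknown_scheme(self):
        with pytest.raises(ConfigError):
            EvaluationModel.from_scheme("XX", "PFT", np.eye(1), np.eye(1), ("PFT",))

    def test_weighted_multi_trait_rejected(self):
        with pytest.raises(ConfigError):
            EvaluationModel(traits=("a", "b"), scheme="ST_sswl1",
                            G0=np.eye(2), R0=np.eye(2),
                            weight_scheme="linear", weight_rounds=1)

    def test_missing_all_helpers_rejected(self):
        with pytest.raises(ConfigError):
            EvaluationModel.from_scheme("TT_W450", "PFT", np.eye(1), np.eye(1),
                                        ("PFT",))

    def test_partial_helpers_warn(self):
        with pytest.warns(UserWarning):
            em = EvaluationModel.from_scheme("MT_ss", "PFT", np.eye(2) * 2,
                                             np.eye(2) * 3, ("PFT", "W450"))
        assert em.traits == ("PFT", "W450")
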