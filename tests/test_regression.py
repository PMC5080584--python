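"""Block-decomposition regression engine vs independent OLS oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, special

import hdassoc as hd
from hdassoc.regression import (AnalysisConfig, CovariateMatrix,
                                PartialDerivatives, RegressionError,
                                impute_missing, run_single_site, solve_block,
                                t_to_p, with_intercept)
from hdassoc.simulate import SimulationConfig, save_dataset, simulate_dataset
from hdassoc.store import CovariateStore, GenotypeStore, PhenotypeStore

from conftest import ols_oracle


class TestPartialDerivatives:
    def test_a1_hand_arithmetic(self):
        Z = CovariateMatrix(np.array([[1.0, 0], [1, 1], [1, 2]]), ("intercept", "x"))
        np.testing.assert_array_equal(hd.compute_a1(Z), [[3, 3], [3, 5]])

    def test_a1_intercept_only(self):
        Z = CovariateMatrix(np.ones((5, 1)), ("intercept",))
        np.testing.assert_array_equal(hd.compute_a1(Z), [[5.0]])

    def test_rank_deficiency_names_columns(self):
        Z = np.ones((10, 3))
        Z[:, 1] = np.arange(10)
        Z[:, 2] = 2 * np.arange(10)  # collinear with column 1
        with pytest.raises(RegressionError, match="collinear"):
            CovariateMatrix(Z, ("intercept", "a", "b"))

    def test_a2_a3_trivial_and_degenerate(self):
        Z = CovariateMatrix(np.ones((3, 1)), ("intercept",))
        a2, a3 = hd.compute_a2_a3(Z, np.array([[0.0, 0], [1, 0], [2, 0]]))
        np.testing.assert_array_equal(a2, [[3.0], [0.0]])
        np.testing.assert_array_equal(a3, [5.0, 0.0])

    def test_b_cov_self_consistency_with_a1(self, rng):
        # a phenotype equal to a covariate column reproduces a1's column
        Z = with_intercept(rng.normal(size=(30, 2)), ("age", "sex"))
        Y = Z.Z[:, [1]]
        np.testing.assert_allclose(hd.compute_b_cov(Z, Y)[:, 0],
                                   hd.compute_a1(Z)[:, 1])

    def test_derivatives_match_loop_oracle(self, rng):
        Z = with_intercept(rng.normal(size=(100, 3)), ("c1", "c2", "c3"))
        G = rng.binomial(2, 0.3, (100, 7)).astype(float)
        Y = rng.normal(size=(100, 5))
        a2, a3 = hd.compute_a2_a3(Z, G)
        for t in range(7):
            np.testing.assert_allclose(a2[t], Z.Z.T @ G[:, t], rtol=1e-12)
            np.testing.assert_allclose(a3[t], G[:, t] @ G[:, t], rtol=1e-12)
        b_cov = hd.compute_b_cov(Z, Y)
        C = hd.compute_c(Y)
        for p in range(5):
            np.testing.assert_allclose(b_cov[:, p], Z.Z.T @ Y[:, p], rtol=1e-12)
            np.testing.assert_allclose(C[p], Y[:, p] @ Y[:, p], rtol=1e-12)


class TestTtoP:
    def test_t_zero_gives_p_one(self):
        assert t_to_p(0.0, 10) == 1.0

    def test_large_t_limit(self):
        assert t_to_p(1e6, 5) < 1e-20

    def test_matches_numerical_integration(self):
        # independent oracle: integrate the Student-t density directly
        def t_pdf(x, df):
            c = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi)
                                               * special.gamma(df / 2))
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        for t, df in [(2.0, 10), (0.5, 3), (4.2, 60)]:
            tail, _ = integrate.quad(t_pdf, abs(t), np.inf, args=(df,))
            np.testing.assert_allclose(t_to_p(t, df), 2 * tail, rtol=1e-8)

    def test_monotone_in_abs_t(self):
        ts = np.linspace(0, 8, 50)
        p = t_to_p(ts, 12)
        assert np.all(np.diff(p) < 0)


class TestSolveBlock:
    @staticmethod
    def _fit(Z, Y, G):
        pd_ = hd.build_partial_derivatives(Z, Y, G)
        df = Z.n_samples - Z.n_c
        return solve_block(pd_, hd.compute_b4(Y, G), df)

    def test_constant_phenotype_zero_beta(self, rng):
        Z = CovariateMatrix(np.ones((20, 1)), ("intercept",))
        G = rng.binomial(2, 0.4, (20, 3)).astype(float)
        Y = np.full((20, 1), 3.5)
        stats = self._fit(Z, Y, G)
        np.testing.assert_allclose(stats.beta, 0.0, atol=1e-12)
        np.testing.assert_allclose(stats.t, 0.0, atol=1e-9)

    def test_perfect_fit_flagged_na(self):
        Z = CovariateMatrix(np.ones((5, 1)), ("intercept",))
        g = np.array([0.0, 1, 2, 1, 0])[:, None]
        Y = 2.0 * g
        stats = self._fit(Z, Y, g)
        assert stats.n_perfect == 1
        assert stats.na_mask[0, 0]
        assert np.isnan(stats.t[0, 0]) and np.isnan(stats.p[0, 0])

    def test_monomorphic_variant_na(self, rng):
        Z = CovariateMatrix(np.ones((30, 1)), ("intercept",))
        G = np.column_stack([np.zeros(30), rng.binomial(2, 0.3, 30)]).astype(float)
        Y = rng.normal(size=(30, 2))
        stats = self._fit(Z, Y, G)
        assert stats.n_singular == 1
        assert np.all(stats.na_mask[:, 0])
        assert not np.any(stats.na_mask[:, 1])

    def test_matches_per_pair_ols_oracle(self):
        cfg = SimulationConfig(n_i=50, n_t=20, n_p=10, n_sites=1, seed=1,
                               effects=((0, 0, 0.5),))
        d = simulate_dataset(cfg)
        stats = self._fit(d.Z, d.Y, d.G)
        assert stats.df == 50 - 4
        for t in range(20):
            X = np.column_stack([d.Z.Z, d.G[:, t]])
            for p in range(10):
                b, se, tt = ols_oracle(X, d.Y[:, p])
                np.testing.assert_allclose(stats.beta[p, t], b, rtol=1e-8)
                np.testing.assert_allclose(stats.se[p, t], se, rtol=1e-8)
                np.testing.assert_allclose(stats.t[p, t], tt, rtol=1e-8)

    def test_all_covariates_mode_matches_statsmodels(self):
        import statsmodels.api as sm

        d = simulate_dataset(SimulationConfig(n_i=40, n_t=3, n_p=2, seed=5))
        pd_ = hd.build_partial_derivatives(d.Z, d.Y, d.G)
        stats = solve_block(pd_, hd.compute_b4(d.Y, d.G), 40 - 4,
                            all_covariates=True)
        fit = sm.OLS(d.Y[:, 1], np.column_stack([d.Z.Z, d.G[:, 2]])).fit()
        np.testing.assert_allclose(stats.beta_all[:, 1, 2], fit.params, rtol=1e-8)
        np.testing.assert_allclose(stats.se_all[:, 1, 2], fit.bse, rtol=1e-8)
        np.testing.assert_allclose(stats.t_all[:, 1, 2], fit.tvalues, rtol=1e-8)

    def test_sign_antisymmetry_under_genotype_flip(self):
        d = simulate_dataset(SimulationConfig(n_i=60, n_t=8, n_p=4, seed=9,
                                              effects=((1, 1, 0.6),)))
        s_pos = self._fit(d.Z, d.Y, d.G)
        s_neg = self._fit(d.Z, d.Y, -d.G)
        np.testing.assert_allclose(s_neg.beta, -s_pos.beta, rtol=1e-10)
        np.testing.assert_allclose(s_neg.se, s_pos.se, rtol=1e-10)
        np.testing.assert_allclose(s_neg.t, -s_pos.t, rtol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(25, 80),
           n_t=st.integers(1, 6), n_p=st.integers(1, 4))
    def test_property_oracle_equivalence(self, seed, n, n_t, n_p):
        """Any simulated dataset: block solver == per-pair least squares."""
        d = simulate_dataset(SimulationConfig(n_i=n, n_t=n_t, n_p=n_p,
                                              seed=seed))
        stats = self._fit(d.Z, d.Y, d.G)
        rng_local = np.random.default_rng(seed)
        t = int(rng_local.integers(n_t))
        p = int(rng_local.integers(n_p))
        if stats.na_mask[p, t]:
            return
        b, se, tt = ols_oracle(np.column_stack([d.Z.Z, d.G[:, t]]), d.Y[:, p])
        np.testing.assert_allclose(stats.beta[p, t], b, rtol=1e-8)
        np.testing.assert_allclose(stats.t[p, t], tt, rtol=1e-8)


class TestMissingPolicy:
    def test_mean_imputation_keeps_n(self):
        G = np.array([[0.0, np.nan], [1, 1], [2, 1]])
        out, drop = impute_missing(G, "mean")
        assert not drop.any()
        np.testing.assert_allclose(out[:, 1], [1.0, 1, 1])

    def test_drop_stat_flags_variant(self):
        G = np.array([[0.0, np.nan], [1, 1]])
        _, drop = impute_missing(G, "drop-stat")
        np.testing.assert_array_equal(drop, [False, True])

    def test_unknown_policy_errors(self):
        with pytest.raises(RegressionError, match="unknown missing policy"):
            impute_missing(np.array([[np.nan]]), "zap")


class TestRunSingleSite:
    @pytest.fixture()
    def stores(self, tmp_path, small_dataset):
        _, d = small_dataset
        paths = save_dataset(d, tmp_path / "sim")
        return (GenotypeStore(paths["genotype"]),
                PhenotypeStore(paths["phenotype"]),
                CovariateStore(paths["covariates"]), d)

    def test_single_pair_equals_direct_fit(self, stores):
        g, p, c, d = stores
        recs = [r for r in run_single_site(g, p, c)
                if r.variant_id == "rs3" and r.phenotype_id == "pheno4"]
        assert len(recs) == 1
        b, se, tt = ols_oracle(np.column_stack([d.Z.Z, d.G[:, 2]]), d.Y[:, 3])
        np.testing.assert_allclose(recs[0].beta, b, rtol=1e-8)
        np.testing.assert_allclose(recs[0].t, tt, rtol=1e-8)
        assert recs[0].df == 50 - 4 and recs[0].n == 50

    def test_chunking_invariance(self, stores):
        g, p, c, _ = stores
        small = list(run_single_site(g, p, c, AnalysisConfig(7, 3)))
        big = list(run_single_site(g, p, c, AnalysisConfig(1000, 1000)))
        key = lambda r: (r.variant_id, r.phenotype_id)
        for a, b in zip(sorted(small, key=key), sorted(big, key=key)):
            assert f"{a.t:.12g}" == f"{b.t:.12g}"
            assert f"{a.beta:.12g}" == f"{b.beta:.12g}"
            assert f"{a.se:.12g}" == f"{b.se:.12g}"

    def test_maf_filter_removes_monomorphic(self, tmp_path, small_dataset):
        _, d = small_dataset
        G = d.G.copy()
        G[:, 0] = 0.0  # force monomorphic
        from hdassoc.simulate import SimulatedData
        import dataclasses
        d2 = dataclasses.replace(d, G=G)
        paths = save_dataset(d2, tmp_path / "sim2")
        recs = list(run_single_site(GenotypeStore(paths["genotype"]),
                                    PhenotypeStore(paths["phenotype"]),
                                    CovariateStore(paths["covariates"]),
                                    AnalysisConfig(maf_min=0.01)))
        assert all(r.variant_id != "rs1" for r in recs)
        assert len(recs) == 19 * 10

    def test_row_permutation_invariance(self, tmp_path, small_dataset, rng):
        """Shuffling phenotype-store rows must not change any statistic."""
        _, d = small_dataset
        paths = save_dataset(d, tmp_path / "orig")
        perm = rng.permutation(50)
        from hdassoc.store import SampleIndex, write_phenotype_store
        write_phenotype_store(tmp_path / "shuf.h5", d.Y[perm],
                              SampleIndex(tuple(d.samples.ids[i] for i in perm)),
                              d.phenotype_ids)
        base = list(run_single_site(GenotypeStore(paths["genotype"]),
                                    PhenotypeStore(paths["phenotype"]),
                                    CovariateStore(paths["covariates"])))
        shuf = list(run_single_site(GenotypeStore(paths["genotype"]),
                                    PhenotypeStore(tmp_path / "shuf.h5"),
                                    CovariateStore(paths["covariates"])))
        for a, b in zip(base, shuf):
            assert (a.variant_id, a.phenotype_id) == (b.variant_id, b.phenotype_id)
            np.testing.assert_allclose(a.t, b.t, rtol=1e-10)

    def test_null_rejection_rate_calibrated(self):
        """Pure null: ~5% of p-values below 0.05 (3 binomial SE band)."""
        d = simulate_dataset(SimulationConfig(n_i=150, n_t=100, n_p=20,
                                              seed=11))
        pd_ = hd.build_partial_derivatives(d.Z, d.Y, d.G)
        stats = solve_block(pd_, hd.compute_b4(d.Y, d.G), 150 - 4)
        p = stats.p[~stats.na_mask]
        rate = float(np.mean(p < 0.05))
        n = p.size
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)
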