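"""Mixed-model machinery: OLS correction, Gibbs samplers, DIC."""

import numpy as np
import pandas as pd
import pytest

from plsgp.bayes import (MCMCConfig, compute_dic, correct_phenotypes,
                         gaussian_deviance, gibbs_multitrait,
                         gibbs_univariate, summarize_posterior)
from plsgp.genio import PhenotypeTable
from plsgp.relmat import RelMatrix, build_G


def make_pheno(df, factors, traits, id_col="id"):
    return PhenotypeTable(df, id_col, factors, traits)


class TestCorrectPhenotypes:
    def test_intercept_only_is_identity(self):
        df = pd.DataFrame({"id": ["a", "b", "c"],
                           "y": [1.0, 2.0, 4.0]})
        tbl = make_pheno(df, [], ["y"])
        out = correct_phenotypes(tbl, [], "residual_plus_intercept")
        np.testing.assert_allclose(out["y"].to_numpy(), [1, 2, 4])

    def test_balanced_replicate_shift_removed_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        delta = 3.7
        df = pd.DataFrame({
            "id": [f"g{i}" for i in range(6)] * 2,
            "rep": ["r1"] * 6 + ["r2"] * 6,
            "y": np.concatenate([base, base + delta]),
        })
        tbl = make_pheno(df, ["rep"], ["y"])
        out = correct_phenotypes(tbl, ["rep"], "residual_plus_intercept")
        # per-genotype means: replicate shift gone, ranking preserved
        resid = out["y"].to_numpy()
        assert np.std(resid - (base - base.mean())) < 1e-10

    def test_blue_of_clone_mean(self):
        df = pd.DataFrame({"id": ["c1"] * 4, "y": [1.0, 2.0, 3.0, 4.0]})
        tbl = make_pheno(df, [], ["y"])
        out = correct_phenotypes(tbl, [], "genotype_blues")
        assert out.loc["c1", "y"] == pytest.approx(2.5)

    def test_blues_recover_clone_means_balanced(self):
        rng = np.random.default_rng(1)
        means = {"c1": 1.0, "c2": 3.0, "c3": -2.0}
        rep_eff = {"r1": 0.0, "r2": 5.0}
        rows = []
        for cid, m in means.items():
            for rep, re in rep_eff.items():
                rows.append({"id": cid, "rep": rep, "y": m + re})
        tbl = make_pheno(pd.DataFrame(rows), ["rep"], ["y"])
        out = correct_phenotypes(tbl, ["rep"], "genotype_blues")
        got = out["y"]
        # differences between clones are exact; grand centering preserved
        assert got["c2"] - got["c1"] == pytest.approx(2.0, abs=1e-10)
        assert got["c3"] - got["c1"] == pytest.approx(-3.0, abs=1e-10)

    def test_rank_deficient_design_reports_alias(self):
        df = pd.DataFrame({"id": list("abcd"),
                           "f1": ["x", "x", "y", "y"],
                           "f2": ["u", "u", "v", "v"],  # aliased with f1
                           "y": [1.0, 2, 3, 4]})
        tbl = make_pheno(df, ["f1", "f2"], ["y"])
        with pytest.raises(ValueError, match="aliased"):
            correct_phenotypes(tbl, ["f1", "f2"])


class TestSummaries:
    def _degenerate_samples(self, sa, se, cov=0.0, n=250):
        t = np.atleast_1d(sa).size
        Sa = np.diag(np.atleast_1d(sa)).astype(float)
        if t == 2:
            Sa[0, 1] = Sa[1, 0] = cov
        Se = np.diag(np.atleast_1d(se)).astype(float)
        return {
            "trait_names": [f"t{j}" for j in range(t)],
            "ids": ["i0"],
            "Sigma_a": np.repeat(Sa[None], n, axis=0),
            "Sigma_e": np.repeat(Se[None], n, axis=0),
            "deviance": np.full(n, 12.0),
            "deviance_at_mean": 12.0,
            "gebv_mean": np.zeros((1, t)),
        }

    def test_h2_formula_exact(self):
        ps = summarize_posterior(self._degenerate_samples([1.0], [3.0]))
        assert ps.h2_mean[0] == pytest.approx(0.25)

    def test_rg_formula_exact(self):
        ps = summarize_posterior(
            self._degenerate_samples([1.0, 1.0], [1.0, 1.0], cov=0.5))
        assert ps.rG_mean[0, 1] == pytest.approx(0.5)

    def test_sample_wise_differs_from_ratio_of_means(self):
        rng = np.random.default_rng(2)
        n = 400
        sa = rng.lognormal(0.0, 1.5, size=n)
        se = rng.lognormal(0.0, 1.5, size=n)
        samples = self._degenerate_samples([1.0], [1.0], n=n)
        samples["Sigma_a"] = sa.reshape(n, 1, 1)
        samples["Sigma_e"] = se.reshape(n, 1, 1)
        ps = summarize_posterior(samples)
        samplewise = np.mean(sa / (sa + se))
        ratio_of_means = sa.mean() / (sa.mean() + se.mean())
        assert ps.h2_mean[0] == pytest.approx(samplewise)
        assert abs(samplewise - ratio_of_means) > 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="retained"):
            summarize_posterior(self._degenerate_samples([1.0], [1.0], n=50))

    def test_point_mass_posterior_dic(self):
        samples = self._degenerate_samples([1.0], [3.0])
        dic, p_d = compute_dic(samples)
        assert p_d == pytest.approx(0.0)
        assert dic == pytest.approx(12.0)


class TestDeviance:
    def test_hand_computed_univariate(self):
        y = np.array([[1.0], [2.0], [4.0]])
        mu = np.array([[1.5], [1.5], [3.0]])
        s2 = 2.0
        expected = sum(
            -2 * (-0.5 * np.log(2 * np.pi * s2)
                  - (yi - mi) ** 2 / (2 * s2))
            for yi, mi in zip(y[:, 0], mu[:, 0]))
        assert gaussian_deviance(y, mu, [[s2]]) == \
            pytest.approx(expected, abs=1e-10)

    def test_missing_cells_marginalized(self):
        y = np.array([[1.0, np.nan], [2.0, 0.5]])
        mu = np.zeros((2, 2))
        S = np.array([[1.0, 0.3], [0.3, 2.0]])
        from scipy.stats import multivariate_normal as mvn

        expected = -2 * (mvn.logpdf(y[1], mu[1], S)
                         + mvn.logpdf(y[0, 0], mu[0, 0], S[0, 0]))
        assert gaussian_deviance(y, mu, S) == pytest.approx(expected)


def naive_multitrait_gibbs(Y, K, config):
    """Direct full-covariance sampler (no eigen/diagonalization tricks).

    Independent oracle for the production sampler: samples the n*t breeding
    values jointly from the exact multivariate normal full conditional.
    """
    from scipy import stats

    n, t = Y.shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    Ki = np.linalg.inv(K + 1e-8 * np.eye(n))
    varp = Y.var(axis=0, ddof=1)
    nu = t + 2
    S_a = np.diag(0.5 * varp) * (nu - t - 1)
    S_e = np.diag(0.5 * varp) * (nu - t - 1)
    Sigma_a = np.diag(0.5 * varp)
    Sigma_e = np.diag(0.5 * varp)
    beta = Y.mean(axis=0)
    A = np.zeros((n, t))
    keep_a, keep_e = [], []
    for it in range(config.n_iter):
        R = Y - beta
        Sei = np.linalg.inv(Sigma_e)
        prec = np.kron(np.linalg.inv(Sigma_a), Ki) + np.kron(Sei, np.eye(n))
        L = np.linalg.cholesky(prec)
        rhs = (R @ Sei).T.ravel()  # vec over traits-major layout
        mean = np.linalg.solve(prec, rhs)
        z = np.linalg.solve(L.T, rng.standard_normal(n * t))
        A = (mean + z).reshape(t, n).T
        resid = R - A
        beta = (Y - A).mean(axis=0) + \
            np.linalg.cholesky(Sigma_e / n) @ rng.standard_normal(t)
        Sigma_a = stats.invwishart.rvs(nu + n, S_a + A.T @ Ki @ A,
                                       random_state=rng).reshape(t, t)
        resid = Y - beta - A
        Sigma_e = stats.invwishart.rvs(nu + n, S_e + resid.T @ resid,
                                       random_state=rng).reshape(t, t)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep_a.append(Sigma_a.copy())
            keep_e.append(Sigma_e.copy())
    return np.mean(keep_a, axis=0), np.mean(keep_e, axis=0)


@pytest.fixture(scope="module")
def tiny_problem():
    rng = np.random.default_rng(3)
    n, t = 18, 2
    K = np.eye(n) * 0.6 + 0.4  # compound symmetry kernel
    La = np.linalg.cholesky(np.array([[1.0, 0.5], [0.5, 1.0]]))
    A = np.linalg.cholesky(K) @ rng.standard_normal((n, t)) @ La.T
    Y = A + rng.standard_normal((n, t))
    ids = [f"i{k}" for k in range(n)]
    return pd.DataFrame(Y, index=ids), RelMatrix(ids, K, "vanraden_G")


class TestMultitraitSampler:
    def test_eigen_sampler_matches_naive_oracle(self, tiny_problem):
        Y, K = tiny_problem
        cfg = MCMCConfig(n_iter=6000, burn_in=1000, thin=2, seed=4)
        fast = gibbs_multitrait(Y, K, cfg)
        Sa_f = fast["Sigma_a"].mean(axis=0)
        Se_f = fast["Sigma_e"].mean(axis=0)
        Sa_n, Se_n = naive_multitrait_gibbs(Y.to_numpy(), K.values, cfg)
        # agreement within Monte-Carlo error of two independent chains
        assert np.abs(Sa_f - Sa_n).max() < 0.35
        assert np.abs(Se_f - Se_n).max() < 0.35

    def test_chain_reproducibility(self, tiny_problem):
        Y, K = tiny_problem
        cfg = MCMCConfig(n_iter=1500, burn_in=500, thin=2, seed=5)
        a = gibbs_multitrait(Y, K, cfg)
        b = gibbs_multitrait(Y, K, cfg)
        np.testing.assert_array_equal(a["Sigma_a"], b["Sigma_a"])
        np.testing.assert_array_equal(a["gebv_mean"], b["gebv_mean"])

    def test_duplicated_trait_forces_high_rg(self, small_study):
        rng = np.random.default_rng(6)
        truth = small_study["truth"]
        G = build_G(small_study["genotypes"])
        bv = pd.Series(truth.breeding_values[:, 1],
                       index=truth.genotype_ids).loc[G.labels]
        y1 = bv + 0.15 * rng.standard_normal(len(bv))
        Y = pd.DataFrame({"a": y1,
                          "b": y1 + 1e-3 * rng.standard_normal(len(y1))})
        s = gibbs_multitrait(Y, G, MCMCConfig(n_iter=5000, burn_in=1500,
                                              thin=2, seed=7))
        ps = summarize_posterior(s)
        assert ps.rG_mean[0, 1] > 0.98

    def test_masked_individuals_get_relatedness_gebvs(self, small_study):
        """Masking phenotypes leaves GEBVs defined and correlated with
        truth through family structure alone."""
        geno = small_study["genotypes"]
        truth = small_study["truth"]
        Y = small_study["corrected"].copy()
        masked_ids = Y.index[:40]
        Y.loc[masked_ids] = np.nan
        G = build_G(geno)
        s = gibbs_multitrait(Y, G, MCMCConfig(n_iter=3000, burn_in=1000,
                                              thin=2, seed=8))
        gebv = pd.DataFrame(s["gebv_mean"], index=s["ids"],
                            columns=Y.columns)
        bv = pd.DataFrame(truth.breeding_values, index=truth.genotype_ids,
                          columns=Y.columns)
        r = np.corrcoef(gebv.loc[masked_ids, "trait2"],
                        bv.loc[masked_ids, "trait2"])[0, 1]
        assert r > 0.3

    def test_h2_rg_bounds_by_construction(self, small_study):
        Y = small_study["corrected"]
        G = build_G(small_study["genotypes"])
        s = gibbs_multitrait(Y, G, MCMCConfig(n_iter=3000, burn_in=1000,
                                              thin=2, seed=9))
        va = np.einsum("sii->si", s["Sigma_a"])
        ve = np.einsum("sii->si", s["Sigma_e"])
        h2 = va / (va + ve)
        assert ((h2 >= 0) & (h2 <= 1)).all()
        sd = np.sqrt(va)
        rg = s["Sigma_a"][:, 0, 1] / (sd[:, 0] * sd[:, 1])
        assert ((rg >= -1) & (rg <= 1)).all()


class TestUnivariateSampler:
    def test_null_heritability_identity_kernel_with_replication(self):
        """Pure-noise phenotypes show no spurious heritability.

        Two records per genotype identify the between-genotype variance;
        an unstructured kernel and i.i.d. noise must drive it to ~0."""
        rng = np.random.default_rng(10)
        n = 500
        ids = [f"i{k}" for k in range(n)]
        K = RelMatrix(ids, np.eye(n), "vanraden_G")
        y = pd.Series(rng.standard_normal(2 * n), index=ids * 2)
        s = gibbs_univariate(y, K, MCMCConfig(n_iter=3000, burn_in=1000,
                                              thin=2, seed=11))
        ps = summarize_posterior(s)
        assert ps.h2_mean[0] < 0.15

    def test_recovery_with_pedigree_kernel(self, small_study):
        """Posterior h2 from the pedigree model covers the simulated value."""
        from plsgp.relmat import build_A

        truth = small_study["truth"]
        Y = small_study["corrected"]
        A = build_A(small_study["pedigree"]).align(list(Y.index))
        s = gibbs_univariate(Y["trait2"], A,
                             MCMCConfig(n_iter=5000, burn_in=1500, thin=2,
                                        seed=12))
        ps = summarize_posterior(s)
        assert abs(ps.h2_mean[0] - truth.h2[1]) < max(0.15,
                                                      2.5 * ps.h2_sd[0])

    def test_gls_beta_with_tight_variance_priors(self):
        """With variances pinned by a degenerate prior, the posterior mean
        of the fixed effect matches the closed-form GLS solution."""
        rng = np.random.default_rng(13)
        n = 60
        ids = [f"i{k}" for k in range(n)]
        K = np.eye(n) * 0.4 + 0.6
        sg2, se2 = 1.0, 1.0
        g = np.linalg.cholesky(K) @ rng.standard_normal(n) * np.sqrt(sg2)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        beta_true = np.array([1.0, -2.0])
        y = X @ beta_true + g + np.sqrt(se2) * rng.standard_normal(n)
        V = sg2 * K + se2 * np.eye(n)
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        kern = RelMatrix(ids, K, "vanraden_G")
        # pin variances at truth through an overwhelming prior
        cfg = MCMCConfig(n_iter=8000, burn_in=2000, thin=2, seed=14,
                         nu_a=2e6, nu_e=2e6,
                         s_a_frac=sg2 / np.var(y, ddof=1),
                         s_e_frac=se2 / np.var(y, ddof=1))
        s = gibbs_univariate(pd.Series(y, index=ids), kern, cfg, X=X)
        beta_post = s["beta"].mean(axis=0)[:, 0]
        np.testing.assert_allclose(beta_post, beta_gls, atol=0.1)

    def test_block_effect_absorbs_variance(self):
        rng = np.random.default_rng(15)
        n = 200
        ids = [f"i{k}" for k in range(n)]
        blocks = np.repeat(np.arange(20), 10)
        blk_eff = rng.normal(0, 1.0, size=20)
        y = blk_eff[blocks] + 0.5 * rng.standard_normal(n)
        kern = RelMatrix(ids, np.eye(n), "vanraden_G")
        s = gibbs_univariate(pd.Series(y, index=ids), kern,
                             MCMCConfig(n_iter=3000, burn_in=1000, thin=2,
                                        seed=16), block=blocks)
        assert s["sigma_b2"].mean() > 3 * s["Sigma_a"].mean()

    def test_unbalanced_replication_rejected(self):
        ids = ["a", "b"]
        kern = RelMatrix(ids, np.eye(2), "vanraden_G")
        y = pd.Series([1.0, 2.0, 3.0], index=["a", "a", "b"])
        with pytest.raises(ValueError, match="unbalanced"):
            gibbs_univariate(y, kern, MCMCConfig(n_iter=300, burn_in=100))
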