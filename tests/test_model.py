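import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

import hapnet as hn
from hapnet.model import GridSettings, ModelPriors, RandomTerm


def single_node_dag():
    return hn.parse_dag(pd.DataFrame({"child": ["i"], "parent": [""]}))


def small_dataset(dag, p, rho=0.6, ve=1.0, seed=0):
    named = [n for n in dag.topo_order if not dag.is_phantom[n]]
    rng = np.random.default_rng(seed)
    V = hn.covariance_oracle(dag, hn.ARHyperParams.from_conditional(rho, 1.0))
    h = rng.multivariate_normal(np.zeros(len(named)), V)
    Z = np.zeros((p, len(named)))
    Z[np.arange(p), rng.integers(0, len(named), p)] = 1.0
    y = Z @ h + rng.normal(0, np.sqrt(ve), p)
    return y, Z, named, h


class TestAssembly:
    def test_hn_latent_includes_phantoms(self, table1_alleles):
        df = pd.DataFrame({"child": ["g", "a", "b", "d", "e"],
                           "parent": ["i", "g", "g", "i", "d"],
                           "n_mutations": [2, 1, 1, 2, 1]})
        dag = hn.insert_phantom_haplotypes(hn.parse_dag(df))
        p = 5
        carried = ["a", "b", "d", "e", "i"]
        Z = np.zeros((p, 5))
        Z[np.arange(p), np.arange(5)] = 1
        m = hn.HaplotypeModel(np.zeros(p), Z, term="hn", dag=dag,
                              haplotype_ids=carried)
        assert len(m.hap_labels) == dag.n_nodes == 8
        # phantom columns of the latent design stay zero
        W_hap = m.W[:, m.hap_slice]
        phantom_cols = [j for j, lab in enumerate(m.hap_labels)
                        if dag.is_phantom[lab]]
        assert (W_hap[:, phantom_cols] == 0).all()

    def test_ih_prior_precision_is_identity_scaled(self):
        Z = np.eye(4)
        m = hn.HaplotypeModel(np.zeros(4), Z, term="ih")
        P, _ = m._prior_precision({"sigma2_I": 2.0, "sigma2_e": 1.0})
        np.testing.assert_allclose(P, np.eye(4) / 2.0)

    def test_mutation_term_has_one_latent_per_site(self, table1_alleles):
        p = 5
        Z = np.eye(5)
        m = hn.HaplotypeModel(np.zeros(p), Z, term="mutation",
                              allele_matrix=table1_alleles)
        assert m.hap_slice.stop - m.hap_slice.start == 7

    def test_intercept_column_rejected(self):
        Z = np.eye(3)
        X = np.ones((3, 1))
        with pytest.raises(ValueError, match="intercept"):
            hn.HaplotypeModel(np.zeros(3), Z, term="ih", X=X)
        hn.HaplotypeModel(np.zeros(3), Z, term="ih", X=X,
                          allow_intercept=True)

    def test_bad_row_sums_rejected(self):
        Z = np.zeros((2, 3))
        Z[0, 0] = 1
        Z[1, :3] = 1  # row sum 3
        with pytest.raises(ValueError, match="row sums"):
            hn.HaplotypeModel(np.zeros(2), Z, term="ih")


class TestLogMarginalLikelihood:
    def test_single_observation_closed_form(self):
        """One haplotype, one observation: y ~ N(0, sigma2_hm + sigma2_e)."""
        dag = single_node_dag()
        y = np.array([0.83])
        m = hn.HaplotypeModel(y, np.ones((1, 1)), term="hn", dag=dag)
        theta = {"rho": 0.3, "sigma2_hm": 2.0, "sigma2_e": 0.5}
        assert m.log_marginal_likelihood(theta) == pytest.approx(
            norm.logpdf(0.83, 0.0, np.sqrt(2.5)), abs=1e-10)

    def test_vanishing_haplotype_variance_leaves_residual_only(self):
        dag = single_node_dag()
        y = np.array([0.4, -0.2, 1.1])
        Z = np.ones((3, 1))
        m = hn.HaplotypeModel(y, Z, term="hn", dag=dag)
        got = m.log_marginal_likelihood(
            {"rho": 0.0, "sigma2_hm": 1e-14, "sigma2_e": 0.7})
        want = norm.logpdf(y, 0.0, np.sqrt(0.7)).sum()
        assert got == pytest.approx(want, abs=1e-5)

    def test_matches_dense_gaussian_integral(self, fig1_dag):
        """Equality with log N(y; 0, W V_x W^T + sigma2_e I) on a small case,
        including fixed effects and an extra iid random term."""
        rng = np.random.default_rng(3)
        y, Z, named, _ = small_dataset(fig1_dag, p=12, seed=3)
        X = rng.normal(size=(12, 2))
        F = np.zeros((12, 3))
        F[np.arange(12), rng.integers(0, 3, 12)] = 1.0
        term = RandomTerm("pen", F, "iid")
        m = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                              haplotype_ids=named, X=X, extra_terms=[term])
        theta = {"rho": 0.4, "sigma2_hm": 1.5, "sigma2_pen": 0.8,
                 "sigma2_e": 0.9}
        got = m.log_marginal_likelihood(theta)

        V_h = hn.covariance_oracle(
            fig1_dag, hn.ARHyperParams(0.4, 1.5))
        V_x = np.zeros((m.n_latent, m.n_latent))
        V_x[:2, :2] = np.eye(2) * 1000.0
        V_x[2:5, 2:5] = np.eye(3) * 0.8
        V_x[5:, 5:] = V_h
        cov = m.W @ V_x @ m.W.T + 0.9 * np.eye(12)
        want = multivariate_normal.logpdf(y, mean=np.zeros(12), cov=cov)
        assert got == pytest.approx(want, abs=1e-8)

    def test_fixed_theta_mean_equals_dense_mixed_model_solution(self, fig1_dag):
        """mu = V_x W^T (W V_x W^T + sigma2_e I)^{-1} y, computed by an
        independent covariance-space route."""
        y, Z, named, _ = small_dataset(fig1_dag, p=10, seed=4)
        m = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                              haplotype_ids=named)
        theta = {"rho": 0.5, "sigma2_hm": 1.2, "sigma2_e": 0.6}
        mu, cov = m.conditional(theta)
        V_h = hn.covariance_oracle(fig1_dag, hn.ARHyperParams(0.5, 1.2))
        K = m.W @ V_h @ m.W.T + 0.6 * np.eye(10)
        want = V_h @ m.W.T @ np.linalg.solve(K, y)
        np.testing.assert_allclose(mu, want, atol=1e-8)
        want_cov = V_h - V_h @ m.W.T @ np.linalg.solve(K, m.W @ V_h)
        np.testing.assert_allclose(cov, want_cov, atol=1e-8)


class TestFit:
    def test_deterministic(self, fig1_dag):
        y, Z, named, _ = small_dataset(fig1_dag, p=12, seed=5)
        m = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                              haplotype_ids=named)
        r1, r2 = m.fit(), m.fit()
        np.testing.assert_array_equal(r1.latent_mean, r2.latent_mean)
        np.testing.assert_array_equal(r1.weights, r2.weights)

    def test_exchangeability_under_row_permutation(self, fig1_dag):
        y, Z, named, _ = small_dataset(fig1_dag, p=14, seed=6)
        perm = np.random.default_rng(1).permutation(14)
        m1 = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                               haplotype_ids=named)
        m2 = hn.HaplotypeModel(y[perm], Z[perm], term="hn", dag=fig1_dag,
                               haplotype_ids=named)
        r1, r2 = m1.fit(), m2.fit()
        np.testing.assert_allclose(r1.latent_mean, r2.latent_mean, atol=1e-10)
        np.testing.assert_allclose(r1.latent_var, r2.latent_var, atol=1e-10)

    def test_ih_equals_hn_with_rho_fixed_at_zero(self):
        """On a tree, fixing rho = 0 in the HN model reproduces the IH model
        (same sd parameterisation)."""
        rng = np.random.default_rng(11)
        from conftest import make_random_tree
        dag = make_random_tree(rng, n_max=8)
        y, Z, named, _ = small_dataset(dag, p=16, seed=12)
        m_hn = hn.HaplotypeModel(y, Z, term="hn", dag=dag,
                                 haplotype_ids=named, rho_fixed=0.0)
        m_ih = hn.HaplotypeModel(y, Z, term="ih", haplotype_ids=named)
        r_hn, r_ih = m_hn.fit(), m_ih.fit()
        eff_hn = r_hn.haplotype_effects().set_index("id").loc[named]
        eff_ih = r_ih.haplotype_effects().set_index("id").loc[named]
        np.testing.assert_allclose(eff_hn["mean"], eff_ih["mean"], atol=1e-8)
        np.testing.assert_allclose(eff_hn["sd"], eff_ih["sd"], atol=1e-8)

    def test_no_data_limit(self):
        """Empty y: latent means zero, hyper posterior proportional to the
        prior (mode of the grid at the prior mode)."""
        dag = single_node_dag()
        m = hn.HaplotypeModel(np.zeros(0), np.zeros((0, 1)), term="hn",
                              dag=dag)
        res = m.fit()
        np.testing.assert_allclose(res.latent_mean, 0.0, atol=1e-12)
        lp = np.array([m.log_prior_internal(t)
                       for t in res.theta_grid_internal])
        w = np.exp(lp - lp.max())
        np.testing.assert_allclose(res.weights, w / w.sum(), atol=1e-10)

    def test_grid_refinement_consistency(self, fig1_dag):
        y, Z, named, _ = small_dataset(fig1_dag, p=14, seed=13)
        m = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                              haplotype_ids=named)
        base = m.fit(GridSettings(points_per_dim=7))
        fine = m.fit(GridSettings(points_per_dim=13))
        shift = np.abs(base.latent_mean - fine.latent_mean)
        assert (shift < 0.01 * np.sqrt(fine.latent_var) + 1e-12).all()

    def test_summary_mentions_key_quantities(self, fig1_dag):
        y, Z, named, _ = small_dataset(fig1_dag, p=12, seed=14)
        res = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                                haplotype_ids=named).fit()
        text = res.summary()
        assert "rho" in text and "sigma2_e" in text
        assert "converged" in text


class TestDerivedQuantities:
    def test_mutation_backsolve_identity_U(self):
        """U = I: back-solved mutation effects coincide with the haplotype
        effects."""
        rng = np.random.default_rng(15)
        n = 5
        am = hn.AlleleMatrix(np.eye(n, dtype=int),
                             [f"s{j}" for j in range(n)],
                             [f"h{j}" for j in range(n)])
        y = rng.normal(size=12)
        Z = np.zeros((12, n))
        Z[np.arange(12), rng.integers(0, n, 12)] = 1
        res = hn.HaplotypeModel(y, Z, term="ih",
                                haplotype_ids=am.haplotype_ids).fit()
        eff = res.mutation_effects(am)
        hap = res.haplotype_effects().set_index("id").loc[am.haplotype_ids]
        np.testing.assert_allclose(eff["mean"], hap["mean"], atol=1e-12)
        np.testing.assert_allclose(eff["sd"], hap["sd"], atol=1e-12)

    def test_mutation_backsolve_matches_dense_least_squares(self):
        """Full-rank 8 x 4 allele matrix: posterior mean of v equals the
        least-squares solve of the haplotype posterior mean."""
        rng = np.random.default_rng(16)
        while True:
            U = rng.integers(0, 2, size=(8, 4))
            if (np.linalg.matrix_rank(U) == 4
                    and len(np.unique(U, axis=0)) == 8):
                break
        am = hn.AlleleMatrix(U, [f"s{j}" for j in range(4)],
                             [f"h{j}" for j in range(8)])
        y = rng.normal(size=20)
        Z = np.zeros((20, 8))
        Z[np.arange(20), rng.integers(0, 8, 20)] = 1
        res = hn.HaplotypeModel(y, Z, term="ih",
                                haplotype_ids=am.haplotype_ids).fit()
        eff = res.mutation_effects(am)
        h_mean, _ = res.haplotype_posterior(am.haplotype_ids)
        want = np.linalg.lstsq(U.astype(float), h_mean, rcond=None)[0]
        np.testing.assert_allclose(eff["mean"], want, atol=1e-10)

    def test_rank_deficient_backsolve_rejected(self):
        U = np.array([[0, 0, 0], [1, 1, 0], [1, 1, 1]])  # cols 0,1 identical
        am = hn.AlleleMatrix(U, ["s0", "s1", "s2"], ["h0", "h1", "h2"])
        y = np.array([0.3, -0.5, 0.8])
        res = hn.HaplotypeModel(y, np.eye(3), term="ih",
                                haplotype_ids=am.haplotype_ids).fit()
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            res.mutation_effects(am)

    def test_conditional_variance_transform(self, fig1_dag):
        """sigma2_hc samples equal sigma2_hm (1 - rho^2); with rho fixed the
        transform is exact, and the sampled mean matches the grid-exact
        expectation within Monte Carlo error."""
        y, Z, named, _ = small_dataset(fig1_dag, p=14, seed=17)
        res = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                                haplotype_ids=named, rho_fixed=0.5).fit()
        out = res.conditional_variance_posterior(n_samples=20000, seed=1)
        grid_exact = 0.75 * res.hyper_mean("sigma2_hm")
        s = res.sample_hyper(["sigma2_hm"], 20000, 1)["sigma2_hm"] * 0.75
        mc_se = s.std() / np.sqrt(len(s))
        assert out["mean"] == pytest.approx(grid_exact, abs=3 * mc_se + 0.02)

    def test_conditional_variance_seeded(self, fig1_dag):
        y, Z, named, _ = small_dataset(fig1_dag, p=12, seed=18)
        res = hn.HaplotypeModel(y, Z, term="hn", dag=fig1_dag,
                                haplotype_ids=named).fit()
        a = res.conditional_variance_posterior(seed=42)
        b = res.conditional_variance_posterior(seed=42)
        assert a == b


class TestCaseStudyStructure:
    def test_extra_random_effects_and_variance_proportions(self, fig1_dag):
        """Phenotype model with contemporary-group (iid) and pedigree-style
        (user-covariance) random effects plus HN haplotypes: five variance
        components, proportions summing to one, sigma2_hc posterior from the
        sampling transform."""
        rng = np.random.default_rng(19)
        p = 30
        y, Z, named, _ = small_dataset(fig1_dag, p=p, seed=19)
        herd = np.zeros((p, 4))
        herd[np.arange(p), rng.integers(0, 4, p)] = 1
        A = 0.5 * np.eye(p) + 0.5  # compound-symmetry stand-in relationship
        X = rng.normal(size=(p, 1))
        m = hn.HaplotypeModel(
            y + herd @ rng.normal(0, 0.5, 4), Z, term="hn", dag=fig1_dag,
            haplotype_ids=named, X=X,
            extra_terms=[
                RandomTerm("c", herd, "iid"),
                RandomTerm("a", np.eye(p), "user_covariance", covariance=A),
            ],
        )
        assert m.hyper_names == ["sigma2_c", "sigma2_a", "rho", "sigma2_hm",
                                 "sigma2_e"]
        res = m.fit(GridSettings(points_per_dim=3))
        assert res.converged
        comps = {nm: res.hyper_mean(nm) for nm in
                 ("sigma2_c", "sigma2_a", "sigma2_hm", "sigma2_e")}
        props = hn.variance_proportions(comps)
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
        s2hc = res.conditional_variance_posterior(seed=0)
        assert 0 < s2hc["lower"] < s2hc["mean"] < s2hc["upper"]
        assert s2hc["mean"] < res.hyper_mean("sigma2_hm")
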