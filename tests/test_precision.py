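import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hapnet as hn
from conftest import make_random_dag, make_random_tree


def dense_oracle_precision(dag, params):
    """Independent construction (1/sigma2_hc) T^-T D^-1 T^-1 from first
    principles (explicit T^-1 and D^-1, no shared assembly code)."""
    order = dag.topo_order
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    t_inv = np.eye(n)
    d_inv = np.empty(n)
    for node in order:
        i = idx[node]
        prs = dag.parents[node]
        if not prs:
            d_inv[i] = 1.0 - params.rho**2
        else:
            d_inv[i] = len(prs)
            for p in prs:
                t_inv[i, idx[p]] = -params.rho / len(prs)
    return t_inv.T @ np.diag(d_inv) @ t_inv / params.sigma2_hc


class TestBuildPrecision:
    def test_single_starting_node(self):
        dag = hn.parse_dag(pd.DataFrame({"child": ["i"], "parent": [""]}))
        for rho in (-0.7, 0.0, 0.4):
            pr = hn.build_precision(dag, hn.ARHyperParams.from_conditional(rho, 1.0))
            np.testing.assert_allclose(pr.Q.toarray(), [[1 - rho**2]],
                                       atol=1e-14)

    def test_chain_example(self, chain3):
        pr = hn.build_precision(chain3, hn.ARHyperParams.from_conditional(0.5, 1.0))
        expected = np.array([[1.0, -0.5, 0.0],
                             [-0.5, 1.25, -0.5],
                             [0.0, -0.5, 1.0]])
        np.testing.assert_allclose(pr.Q.toarray(), expected, atol=1e-12)

    def test_three_parent_star(self, star_dag):
        params = hn.ARHyperParams.from_conditional(0.6, 1.0)
        Q = hn.build_precision(star_dag, params).Q.toarray()
        order = star_dag.topo_order
        i = {n: j for j, n in enumerate(order)}
        for root in "abc":
            assert Q[i[root], i[root]] == pytest.approx(0.76)
            assert Q[i["d"], i[root]] == pytest.approx(-0.6)
        assert Q[i["d"], i["d"]] == pytest.approx(3.0)
        assert Q[i["a"], i["b"]] == pytest.approx(0.12)
        assert Q[i["a"], i["c"]] == pytest.approx(0.12)
        assert Q[i["b"], i["c"]] == pytest.approx(0.12)

    def test_multiparent_conditional_law_from_Q(self, star_dag):
        """-Q_dd^-1 Q_d,parents = (rho/k) 1 and 1/Q_dd = sigma2_hc/k."""
        rho, s2hc = 0.6, 1.7
        Q = hn.build_precision(
            star_dag, hn.ARHyperParams.from_conditional(rho, s2hc)).Q.toarray()
        order = star_dag.topo_order
        i = {n: j for j, n in enumerate(order)}
        d = i["d"]
        prs = [i[p] for p in "abc"]
        np.testing.assert_allclose(-Q[d, prs] / Q[d, d],
                                   np.full(3, rho / 3), atol=1e-12)
        assert 1.0 / Q[d, d] == pytest.approx(s2hc / 3)

    def test_multimutation_edge_rejected(self):
        df = pd.DataFrame({"child": ["g"], "parent": ["i"], "n_mutations": [2]})
        dag = hn.parse_dag(df)
        with pytest.raises(ValueError, match="insert_phantom_haplotypes"):
            hn.build_precision(dag, hn.ARHyperParams(0.5, 1.0))

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError, match="stationarity"):
            hn.ARHyperParams(1.0, 1.0)
        with pytest.raises(ValueError):
            hn.ARHyperParams(0.5, -1.0)

    def test_sigma2_hc_identity(self):
        p = hn.ARHyperParams(0.3, 2.0)
        assert p.sigma2_hc == pytest.approx(2.0 * (1 - 0.09))


class TestOracleEquivalence:
    def test_random_dags_match_triangular_construction(self):
        rng = np.random.default_rng(20240917)
        for _ in range(60):
            dag = make_random_dag(rng)
            rho = float(rng.uniform(-0.99, 0.99))
            s2hc = float(rng.uniform(0.2, 3.0))
            params = hn.ARHyperParams.from_conditional(rho, s2hc)
            Q = hn.build_precision(dag, params).Q.toarray()
            np.testing.assert_allclose(Q, dense_oracle_precision(dag, params),
                                       atol=1e-10)
            V = hn.covariance_oracle(dag, params)
            np.testing.assert_allclose(Q @ V, np.eye(dag.n_nodes), atol=1e-8)
            assert np.linalg.eigvalsh(Q).min() > 0

    def test_tree_stationarity(self):
        """On single-parent DAGs every marginal variance equals sigma2_hm."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            dag = make_random_tree(rng)
            rho = float(rng.uniform(-0.95, 0.95))
            params = hn.ARHyperParams(rho, 1.8)
            V = hn.covariance_oracle(dag, params)
            np.testing.assert_allclose(np.diag(V), 1.8, atol=1e-10)

    def test_rho_zero_gives_iid_on_trees(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            dag = make_random_tree(rng)
            params = hn.ARHyperParams(0.0, 2.5)
            V = hn.covariance_oracle(dag, params)
            np.testing.assert_allclose(V, 2.5 * np.eye(dag.n_nodes), atol=1e-12)

    def test_chain2_covariance_is_ar1(self):
        df = pd.DataFrame({"child": ["i", "j"], "parent": ["", "i"]})
        dag = hn.parse_dag(df)
        rho = 0.37
        params = hn.ARHyperParams(rho, 1.3)
        V = hn.covariance_oracle(dag, params)
        np.testing.assert_allclose(V, 1.3 * np.array([[1, rho], [rho, 1]]),
                                   atol=1e-12)

    def test_log_det_matches_dense(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            dag = make_random_dag(rng)
            comp = hn.precision_components(dag)
            rho = float(rng.uniform(-0.9, 0.9))
            s2hc = float(rng.uniform(0.5, 2.0))
            sign, ld = np.linalg.slogdet(comp.q_dense(rho, s2hc))
            assert sign > 0
            assert comp.log_det(rho, s2hc) == pytest.approx(ld, abs=1e-8)


class TestMultiRegion:
    def test_single_region_identical(self, chain3):
        params = hn.ARHyperParams.from_conditional(0.5, 1.0)
        a = hn.build_precision(chain3, params).Q.toarray()
        b = hn.build_multiregion_precision([chain3], params).Q.toarray()
        np.testing.assert_allclose(a, b)

    def test_two_chain_blocks(self, chain3):
        params = hn.ARHyperParams.from_conditional(0.5, 1.0)
        blk = hn.build_precision(chain3, params).Q.toarray()
        Q = hn.build_multiregion_precision([chain3, chain3], params).Q.toarray()
        assert Q.shape == (6, 6)
        np.testing.assert_allclose(Q[:3, :3], blk)
        np.testing.assert_allclose(Q[3:, 3:], blk)
        np.testing.assert_allclose(Q[:3, 3:], 0.0)

    def test_normalising_constant_exponent_per_region(self, chain3):
        """det Q over m regions carries (1 - rho^2)^m: one starting node per
        region contributes one factor."""
        rho, s2hc = 0.5, 1.0
        params = hn.ARHyperParams.from_conditional(rho, s2hc)
        single = np.linalg.slogdet(
            hn.build_precision(chain3, params).Q.toarray())[1]
        double = np.linalg.slogdet(
            hn.build_multiregion_precision([chain3, chain3],
                                           params).Q.toarray())[1]
        assert double == pytest.approx(2 * single, abs=1e-10)
        # and the single-region determinant itself carries one (1-rho^2)
        comp = hn.precision_components(chain3)
        d = comp.d_inv(rho)
        assert np.isclose(np.prod(d), (1 - rho**2) * 1 * 1)

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            hn.build_multiregion_precision([], hn.ARHyperParams(0.5, 1.0))


def test_matrix_market_export(tmp_path, chain3):
    from scipy.io import mmread

    pr = hn.build_precision(chain3, hn.ARHyperParams.from_conditional(0.5, 1.0))
    path = tmp_path / "Q.mtx"
    pr.to_matrix_market(path)
    back = mmread(path)
    np.testing.assert_allclose(sp.csr_matrix(back).toarray(), pr.Q.toarray())
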