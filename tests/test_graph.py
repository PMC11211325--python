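import networkx as nx
import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from fcsubtype.connectome import ConnectivityMatrix
from fcsubtype.graph import (ThresholdedGraph, fdr_adjust, gce_optimal_psw,
                             glm_node_test, global_efficiency, node_metrics,
                             normalize_within_subject, shortest_path_lengths,
                             threshold_at_psw)


def _cm(r, sid="s"):
    return ConnectivityMatrix(sid, np.asarray(r, dtype=float))


def _random_cm(rng, n):
    a = rng.uniform(-1, 1, (n, n))
    r = (a + a.T) / 2
    np.fill_diagonal(r, 1.0)
    return _cm(r)


def _graph(adj, sid="s"):
    return ThresholdedGraph(sid, 0.5, np.asarray(adj, dtype=np.int8))


class TestThresholding:
    def test_psw_zero_empty_graph(self, rng):
        g = threshold_at_psw(_random_cm(rng, 6), 0.0)
        assert g.adjacency.sum() == 0

    def test_psw_one_complete_graph(self, rng):
        g = threshold_at_psw(_random_cm(rng, 6), 1.0)
        expected = np.ones((6, 6), dtype=np.int8) - np.eye(6, dtype=np.int8)
        np.testing.assert_array_equal(g.adjacency, expected)

    def test_half_keeps_three_strongest_of_six(self, rng):
        cm = _random_cm(rng, 4)
        g = threshold_at_psw(cm, 0.5)
        iu = np.triu_indices(4, 1)
        order = np.argsort(-np.abs(cm.r[iu]))  # brute-force ranking
        kept = set(zip(iu[0][order[:3]], iu[1][order[:3]]))
        assert g.adjacency.sum() // 2 == 3
        for i, j in kept:
            assert g.adjacency[i, j] == 1

    def test_edge_count_formula(self, rng):
        cm = _random_cm(rng, 10)
        for psw in (0.0, 0.13, 0.5, 0.77, 1.0):
            g = threshold_at_psw(cm, psw)
            assert g.adjacency.sum() // 2 == int(np.floor(psw * 45 + 0.5))

    def test_diagonal_always_zero_and_symmetric(self, rng):
        g = threshold_at_psw(_random_cm(rng, 8), 0.4)
        assert np.all(np.diag(g.adjacency) == 0)
        np.testing.assert_array_equal(g.adjacency, g.adjacency.T)


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        n = 5
        adj = np.ones((n, n)) - np.eye(n)
        e, e_i = global_efficiency(_graph(adj))
        assert e == pytest.approx(1.0)
        np.testing.assert_allclose(e_i, 1.0)

    def test_empty_graph_is_zero(self):
        e, e_i = global_efficiency(_graph(np.zeros((4, 4))))
        assert e == 0.0
        np.testing.assert_array_equal(e_i, 0.0)

    def test_path_graph_closed_form(self):
        # path 0-1-2-3: node 0 sees distances 1,2,3
        adj = np.zeros((4, 4))
        for i in range(3):
            adj[i, i + 1] = adj[i + 1, i] = 1
        e, e_i = global_efficiency(_graph(adj))
        assert e_i[0] == pytest.approx((1 + 1 / 2 + 1 / 3) / 3)
        assert e == pytest.approx(np.mean(e_i))

    def test_distances_match_floyd_warshall(self, rng):
        for _ in range(10):
            adj = (rng.random((12, 12)) < 0.25).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            d_bfs = shortest_path_lengths(adj)
            # independent Floyd-Warshall oracle
            d_fw = np.where(adj > 0, 1.0, np.inf)
            np.fill_diagonal(d_fw, 0.0)
            for k in range(12):
                d_fw = np.minimum(d_fw, d_fw[:, [k]] + d_fw[[k], :])
            np.testing.assert_array_equal(d_bfs, d_fw)


class TestGCECurve:
    def test_curve_has_101_points_and_internal_consistency(self, rng):
        curve = gce_optimal_psw(_random_cm(rng, 12))
        assert len(curve.psw_grid) == 101
        np.testing.assert_allclose(curve.gce_values, curve.e_values - curve.psw_grid)
        assert np.all((curve.e_values >= 0) & (curve.e_values <= 1))

    def test_efficiency_monotone_in_psw(self, rng):
        curve = gce_optimal_psw(_random_cm(rng, 15))
        assert np.all(np.diff(curve.e_values) >= -1e-12)

    def test_optimal_matches_exhaustive_reevaluation(self, rng):
        cm = _random_cm(rng, 10)
        curve = gce_optimal_psw(cm)
        # naive second code path over the same grid
        best_psw, best_gce = None, -np.inf
        for k in range(101):
            psw = k / 100
            e, _ = global_efficiency(threshold_at_psw(cm, psw))
            if e - psw > best_gce + 1e-15:
                best_gce, best_psw = e - psw, psw
        assert curve.optimal_psw == pytest.approx(best_psw)

    def test_star_dominated_matrix_peaks_early(self):
        # strongest edges form a star over all 8 nodes; the star (7 of 28
        # edges, psw=0.25) already reaches every node, so GCE peaks at
        # small psw, well before half the edges are in
        n = 8
        r = np.full((n, n), 0.1)
        r[0, 1:] = r[1:, 0] = 0.9
        np.fill_diagonal(r, 1.0)
        curve = gce_optimal_psw(_cm(r))
        assert curve.optimal_psw <= 0.3
        assert curve.gce_values[np.where(curve.psw_grid == curve.optimal_psw)][0] > 0


class TestNodeMetrics:
    def test_triangle_closed_form(self):
        adj = np.ones((3, 3)) - np.eye(3)
        t = node_metrics(_graph(adj))
        assert (t["clustering_coefficient"] == 1.0).all()
        assert (t["kcoreness"] == 2).all()
        assert (t["local_efficiency"] == 1.0).all()
        assert (t["strength"] == 2).all()

    def test_star_closed_form(self):
        n = 5
        adj = np.zeros((n, n))
        adj[0, 1:] = adj[1:, 0] = 1
        t = node_metrics(_graph(adj)).set_index("region_label")
        center, leaf = "R000", "R001"
        assert t.loc[center, "clustering_coefficient"] == 0.0
        assert t.loc[center, "strength"] == 4
        assert t.loc[leaf, "kcoreness"] == 1
        assert t.loc[center, "local_efficiency"] == 0.0  # leaves are disconnected

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_networkx_reference(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = rng.integers(6, 15)
        adj = np.triu((rng.random((n, n)) < rng.uniform(0.15, 0.6)).astype(int), 1)
        adj = adj + adj.T
        t = node_metrics(_graph(adj))
        G = nx.from_numpy_array(adj)
        cc = nx.clustering(G)
        core = nx.core_number(G)
        for i in range(n):
            assert t.loc[i, "clustering_coefficient"] == pytest.approx(cc[i], abs=1e-10)
            assert t.loc[i, "kcoreness"] == core[i]
            assert t.loc[i, "strength"] == G.degree[i]
            nbrs = list(G.neighbors(i))
            ref = nx.global_efficiency(G.subgraph(nbrs)) if len(nbrs) >= 2 else 0.0
            assert t.loc[i, "local_efficiency"] == pytest.approx(ref, abs=1e-10)

    def test_weighted_strength_option(self, rng):
        cm = _random_cm(rng, 6)
        g = threshold_at_psw(cm, 0.5)
        t = node_metrics(g, weighted_strength=True)
        np.testing.assert_allclose(t["strength"], np.abs(g.retained_weights).sum(axis=1))


class TestNormalization:
    def _table(self, rng, n_subj=3, n_reg=10):
        rows = []
        for s in range(n_subj):
            g = _graph((lambda a: np.triu(a, 1) + np.triu(a, 1).T)(
                (rng.random((n_reg, n_reg)) < 0.4).astype(int)), sid=f"s{s}")
            rows.append(node_metrics(g))
        return pd.concat(rows, ignore_index=True)

    def test_zscore_properties(self, rng):
        t = normalize_within_subject(self._table(rng))
        for _, sub in t.groupby("subject_id"):
            for m in ("strength_norm", "local_efficiency_norm"):
                assert sub[m].mean() == pytest.approx(0.0, abs=1e-10)
                assert sub[m].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_scale_invariance(self, rng):
        t = self._table(rng)
        t2 = t.copy()
        t2["strength"] = t2["strength"] * 2
        a = normalize_within_subject(t)["strength_norm"]
        b = normalize_within_subject(t2)["strength_norm"]
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_constant_metric_normalises_to_zero(self, rng):
        t = self._table(rng)
        t["kcoreness"] = 3.0
        out = normalize_within_subject(t)
        assert (out["kcoreness_norm"] == 0.0).all()


class TestGLM:
    def _meta(self, n, rng):
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["subtype_I"] * (n // 2) + ["CN"] * (n - n // 2),
            "age": rng.uniform(60, 85, n),
            "sex": rng.choice(["M", "F"], n),
        })

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(12)
        n = 200
        meta = self._meta(n, rng)
        ind = (meta["group"] == "subtype_I").astype(float)
        y = 2.0 * ind + 0.1 * meta["age"] + rng.normal(0, 0.01, n)
        table = pd.DataFrame({"subject_id": meta["subject_id"], "region_label": "R000",
                              "m": y})
        res = glm_node_test(table, meta, ("subtype_I", "CN"), metrics=("m",),
                            use_normalized=False)
        assert 1.9 <= res.loc[0, "beta_subtype"] <= 2.1

    def test_null_age_coefficient_near_zero(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(13)
        n = 200
        meta = self._meta(n, rng)
        ind = (meta["group"] == "subtype_I").astype(float)
        y = 1.0 * ind + rng.normal(0, 1.0, n)  # age truly has no effect
        X = sm.add_constant(np.column_stack([ind, meta["age"],
                                             (meta["sex"] == "M").astype(float)]))
        fit = sm.OLS(np.asarray(y), X).fit()
        assert abs(fit.params[2]) <= 3 * fit.bse[2]

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(14)
        n = 80
        ps = []
        for rep in range(100):
            meta = self._meta(n, rng)
            table = pd.DataFrame({"subject_id": meta["subject_id"],
                                  "region_label": "R000", "m": rng.standard_normal(n)})
            res = glm_node_test(table, meta, ("subtype_I", "CN"), metrics=("m",),
                                use_normalized=False)
            ps.append(res.loc[0, "p"])
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_sex_design_is_rank_deficient(self, rng):
        meta = self._meta(20, rng)
        meta["sex"] = "F"
        table = pd.DataFrame({"subject_id": meta["subject_id"], "region_label": "R000",
                              "m": rng.standard_normal(20)})
        with pytest.raises(ValueError, match="rank deficient"):
            glm_node_test(table, meta, ("subtype_I", "CN"), metrics=("m",),
                          use_normalized=False)


class TestFDR:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.04]), [0.04])

    def test_hand_computed_stepup(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, 50)
            q_ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(fdr_adjust(p), q_ref, atol=1e-12)

    def test_q_at_least_p_and_in_unit_interval(self, rng):
        p = rng.uniform(1e-9, 1, 200)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all((q > 0) & (q <= 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_controls_any_discovery_rate_under_null(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(1000):
            q = fdr_adjust(rng.uniform(np.finfo(float).tiny, 1, 360))
            hits += bool((q < 0.05).any())
        assert hits / 1000 <= 0.07
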