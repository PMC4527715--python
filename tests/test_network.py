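import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envepi.exceptions import (
    ConfigError,
    DegenerateFitError,
    NormalizationError,
    ZeroVarianceError,
)
from envepi.network import (
    NetworkConfig,
    SparsePartialCorrelationModel,
    build_network,
    classify_edges,
    default_tuning,
    estimate_partial_correlations,
    find_hubs,
    fit_power_law,
    glog_scale,
    pqn_normalize,
    sample_discrete_power_law,
    standardize,
)


class TestPQN:
    def test_constructed_dilution_removed(self, rng):
        s1 = rng.uniform(0.5, 2.0, size=40)
        df = pd.DataFrame({"s1": s1, "s2": 2 * s1})
        out, factors = pqn_normalize(df)
        np.testing.assert_allclose(out["s1"], out["s2"], atol=1e-12)

    def test_identical_columns_unchanged(self, rng):
        s = rng.uniform(0.5, 2.0, size=30)
        df = pd.DataFrame({"a": s, "b": s, "c": s})
        out, factors = pqn_normalize(df)
        np.testing.assert_allclose(factors, 1.0, atol=1e-12)
        np.testing.assert_allclose(out.to_numpy(), df.to_numpy(), atol=1e-12)

    def test_median_quotient_property(self, rng):
        """Post-PQN, each sample's median quotient vs the reference is 1."""
        df = pd.DataFrame(rng.uniform(0.2, 3.0, size=(60, 5)))
        out, _ = pqn_normalize(df)
        reference = df.median(axis=1)
        q = out.div(reference, axis=0)
        np.testing.assert_allclose(q.median(axis=0), 1.0, atol=1e-12)

    def test_zero_reference_rejected(self):
        df = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(NormalizationError):
            pqn_normalize(df)


class TestGlog:
    def test_value_at_zero(self):
        np.testing.assert_allclose(glog_scale(np.array([0.0]), 1.0),
                                   np.log(0.5), atol=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(x=st.floats(-50, 50, allow_nan=False),
           y=st.floats(-50, 50, allow_nan=False))
    def test_strictly_increasing(self, x, y):
        if abs(x - y) < 1e-9 * (1 + abs(x)):  # below float resolution of g
            return
        lo, hi = sorted((x, y))
        g = glog_scale(np.array([lo, hi]), 1.0)
        assert g[0] < g[1]

    def test_asymptotic_log(self):
        x = 1e6
        assert abs(glog_scale(np.array([x]), 1.0)[0] / np.log(x) - 1) < 1e-6

    def test_defined_for_negatives(self):
        assert np.isfinite(glog_scale(np.array([-5.0]), 1.0)).all()


class TestStandardize:
    def test_row_moments(self, rng):
        df = pd.DataFrame(rng.normal(2, 3, size=(10, 8)))
        out = standardize(df)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        df = standardize(pd.DataFrame(rng.normal(size=(5, 9))))
        np.testing.assert_allclose(
            standardize(df).to_numpy(), df.to_numpy(), atol=1e-12
        )

    def test_single_feature(self):
        out = standardize(pd.DataFrame([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_zero_variance_reported(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["z", "ok"])
        with pytest.raises(ZeroVarianceError, match="z"):
            standardize(df)


class TestPartialCorrelations:
    def test_symmetric_and_bounded(self, rng):
        X = rng.normal(size=(30, 6))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        pc = estimate_partial_correlations(X)
        np.testing.assert_allclose(pc, pc.T, atol=1e-10)
        assert np.all(np.abs(pc) <= 1 + 1e-9)

    def test_bivariate_equals_correlation(self, rng):
        X = rng.normal(size=(200, 2))
        X[:, 1] = 0.6 * X[:, 0] + 0.8 * X[:, 1]
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        r = np.corrcoef(X.T)[0, 1]
        pc = estimate_partial_correlations(X, 0.0)
        np.testing.assert_allclose(pc[0, 1], r, atol=1e-6)

    def test_saturating_penalty_empties_matrix(self, rng):
        X = rng.normal(size=(20, 5))
        pc = estimate_partial_correlations(X, 1e9)
        assert np.all(pc[~np.eye(5, dtype=bool)] == 0.0)

    def test_dense_limit_matches_precision_inversion(self, rng):
        X = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 3))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        # the dense limit requires the residual-precision weights to converge
        pc = estimate_partial_correlations(X, 0.0, n_outer=25)
        prec = np.linalg.inv(np.cov(X.T))
        ref = -prec / np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
        np.fill_diagonal(ref, 1.0)
        np.testing.assert_allclose(pc, ref, atol=1e-6)

    def test_chain_graph_support_recovery(self, rng):
        p, n, r = 10, 500, 0.4
        omega = np.eye(p)
        for i in range(p - 1):
            omega[i, i + 1] = omega[i + 1, i] = -r
        X = rng.multivariate_normal(np.zeros(p), np.linalg.inv(omega), size=n)
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        pc = estimate_partial_correlations(X, default_tuning(n, p))
        for i in range(p - 1):
            assert pc[i, i + 1] > 0  # true edges recovered with correct sign


class TestBuildNetwork:
    def test_mean_rule_brute_force(self):
        pc = np.eye(3)
        pc[0, 1] = pc[1, 0] = 0.8
        pc[0, 2] = pc[2, 0] = 0.1
        pc[1, 2] = pc[2, 1] = 0.3
        net = build_network(pc, ["a", "b", "c"])
        # mean |offdiag| = 0.4 -> only the 0.8 edge survives
        assert net.n_edges == 1
        assert net.edges.iloc[0][["node1", "node2"]].tolist() == ["a", "b"]
        assert net.degrees.tolist() == [1, 1, 0]

    def test_all_equal_offdiag_gives_no_edges(self):
        pc = np.full((4, 4), 0.5)
        np.fill_diagonal(pc, 1.0)
        net = build_network(pc, list("abcd"))
        assert net.n_edges == 0  # strict inequality at the boundary

    def test_empty_matrix(self):
        net = build_network(np.eye(5), list("abcde"))
        assert net.n_edges == 0
        assert net.connected_node_ids() == []


class TestPowerLaw:
    def test_mle_recovers_exponent(self):
        rng = np.random.default_rng(42)
        ks = sample_discrete_power_law(3.0, 5000, rng)
        fit = fit_power_law(ks)
        assert abs(fit.alpha - 3.0) < 0.15

    def test_scale_free_graph_range(self):
        import networkx as nx

        g = nx.barabasi_albert_graph(1000, 2, seed=7)
        degrees = [d for _, d in g.degree()]
        fit = fit_power_law(degrees, x_min=2)
        assert 2.0 <= fit.alpha <= 4.0

    def test_all_equal_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_power_law([3] * 50)

    def test_two_value_poor_fit_flagged(self):
        fit = fit_power_law([1] * 30 + [2] * 10)
        assert fit.poor_fit


class TestHubs:
    def star_network(self, n=100):
        pc = np.eye(n)
        pc[0, 1:] = pc[1:, 0] = 0.9
        return build_network(pc, [f"n{i:03d}" for i in range(n)])

    def test_star_center_is_hub(self):
        net = self.star_network()
        res = find_hubs(net, hub_fraction=0.01)
        assert res.hubs == ["n000"]
        assert res.jaccard == 1.0  # single network: identity by convention

    def test_wilcoxon_detects_degree_separation(self):
        # five fully connected centers among 100 nodes, hub_fraction 0.05
        n = 100
        pc = np.eye(n)
        for c in range(5):
            pc[c, c + 1:] = pc[c + 1:, c] = 0.9
        net = build_network(pc, [f"n{i:03d}" for i in range(n)])
        res = find_hubs(net, hub_fraction=0.05)
        assert res.hubs == [f"n{i:03d}" for i in range(5)]
        assert res.wilcoxon_p < 0.05

    def test_jaccard_across_grid(self):
        net = self.star_network()
        res = find_hubs(net, 0.01, grid_networks=[net, net, net])
        assert res.jaccard == 1.0

    def test_edgeless_rejected(self):
        net = build_network(np.eye(4), list("abcd"))
        with pytest.raises(ConfigError):
            find_hubs(net)


class TestClassifyEdges:
    def random_annotated_network(self, rng, p=12):
        pc = np.zeros((p, p))
        iu = np.triu_indices(p, 1)
        vals = rng.uniform(-1, 1, size=len(iu[0]))
        pc[iu] = vals
        pc = pc + pc.T
        np.fill_diagonal(pc, 1.0)
        ids = [f"n{i}" for i in range(p)]
        ann = pd.DataFrame(
            {
                "class": rng.choice(["NER", "SUPPRESSION", "DISCORDANT"], size=p),
                "epistatic": rng.choice([True, False], size=p),
            },
            index=ids,
        )
        return build_network(pc, ids, ann)

    def test_tallies_partition_edges(self, rng):
        for _ in range(10):
            net = self.random_annotated_network(rng)
            t = classify_edges(net)
            assert (
                t["both_epistatic"] + t["neither_epistatic"] + t["mixed_epistatic"]
                == t["n_edges"]
            )
            assert t["within_class"] + t["between_class"] == t["n_edges"]

    def test_all_epistatic_trivial(self, rng):
        net = self.random_annotated_network(rng)
        net.annotations["epistatic"] = True
        t = classify_edges(net)
        assert t["mixed_epistatic"] == 0 and t["neither_epistatic"] == 0

    def test_unannotated_endpoint_rejected(self, rng):
        net = self.random_annotated_network(rng)
        net.annotations = net.annotations.iloc[:-1]
        if net.degrees.iloc[-1] > 0:
            with pytest.raises(ConfigError):
                classify_edges(net)


class TestModelWrapper:
    def test_pipeline_order_and_summary(self, rng):
        from envepi.simulate import (
            GeneratorConfig, generate_truth_table, simulate_fold_changes,
        )

        cfg = GeneratorConfig(n_features=30, seed=3)
        m = simulate_fold_changes(generate_truth_table(cfg), cfg)
        model = SparsePartialCorrelationModel(
            m, NetworkConfig(apply_pqn=False, tuning_grid=(1.0,))
        )
        # processed data is standardized
        np.testing.assert_allclose(model.processed.mean(axis=1), 0, atol=1e-12)
        res = model.fit()
        assert "coexpression network" in res.summary()
        assert res.network.pcorr.shape == (30, 30)
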