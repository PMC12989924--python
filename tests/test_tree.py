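"""Survival tree growth, routing, prediction, ordering, serialization."""

import json

import numpy as np
import pytest
from sklearn.base import clone

from cgtree import CGESurvivalTree, SurvivalSample, copula_graphic, cv_select_tau
from cgtree.copulas import archimedean_copula


def two_group_data(rng, n=100, hazard_ratio=np.exp(2.0), censor=False):
    """One strong binary covariate separating two exponential groups."""
    z = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(size=n) / np.where(z == 1, hazard_ratio, 1.0)
    if censor:
        c = rng.exponential(size=n)
        x = np.minimum(t, c)
        delta = (t <= c).astype(int)
    else:
        x, delta = t, np.ones(n, dtype=int)
    X = np.column_stack([z, rng.random(n).round(1)])
    return X, (x, delta)


class TestGrowth:
    def test_strong_binary_covariate_depth_one(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=0).fit(X, y)
        assert tree.n_terminal_nodes_ >= 2
        assert tree.tree_.feature == 0
        assert tree.tree_.cutoff == pytest.approx(0.0)

    def test_node_one_is_longer_surviving_group(self, rng):
        """z=0 has the lower hazard ... no: z=1 has hazard_ratio e^2, so
        z=0 survives longer and must be routed to terminal node 1."""
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=0).fit(X, y)
        node_z0 = tree.predict([[0.0, 0.5]])[0]
        node_z1 = tree.predict([[1.0, 0.5]])[0]
        assert node_z0 < node_z1
        assert node_z0 == 1

    def test_pure_noise_rarely_splits(self, rng):
        """With one binary noise covariate and threshold 0.01 the root split
        is accepted at about the 1% level, so nearly all trees stay single
        nodes."""
        single = 0
        reps = 30
        for i in range(reps):
            n = 60
            X = rng.integers(0, 2, (n, 1)).astype(float)
            t = rng.exponential(size=n)
            tree = CGESurvivalTree(
                tau=0.0, nperm=200, p_threshold=0.01, random_state=i
            ).fit(X, (t, np.ones(n, int)))
            single += tree.n_terminal_nodes_ == 1
        assert single >= reps - 3

    def test_zero_threshold_never_splits(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=100, p_threshold=0.0,
                               random_state=1).fit(X, y)
        assert tree.n_terminal_nodes_ == 1

    def test_constant_covariates_no_split(self, rng):
        n = 40
        X = np.ones((n, 3))
        t = rng.exponential(size=n)
        tree = CGESurvivalTree(tau=0.0, nperm=100, random_state=1).fit(
            X, (t, np.ones(n, int))
        )
        assert tree.n_terminal_nodes_ == 1

    def test_min_child_respected(self, rng):
        X, y = two_group_data(rng, n=60, censor=True)
        tree = CGESurvivalTree(tau=0.25, nperm=200, min_child=10,
                               random_state=3).fit(X, y)
        for node in tree.terminal_nodes():
            assert node.n_members >= 10

    def test_partition_property(self, rng):
        X, y = two_group_data(rng, n=80, censor=True)
        tree = CGESurvivalTree(tau=0.25, nperm=200, random_state=4).fit(X, y)
        all_idx = np.concatenate(
            [n.member_idx for n in tree.terminal_nodes()]
        )
        assert sorted(all_idx) == list(range(80))

    def test_reproducible_given_seed(self, rng):
        X, y = two_group_data(rng, n=70, censor=True)
        t1 = CGESurvivalTree(tau=0.25, nperm=200, random_state=9).fit(X, y)
        t2 = CGESurvivalTree(tau=0.25, nperm=200, random_state=9).fit(X, y)
        assert t1.to_json() == t2.to_json()

    def test_internal_split_pvalues_below_threshold(self, rng):
        X, y = two_group_data(rng, n=90, censor=True)
        tree = CGESurvivalTree(tau=0.0, nperm=200, p_threshold=0.05,
                               random_state=5).fit(X, y)

        def visit(node):
            if node.is_terminal:
                return
            assert node.p_value <= 0.05
            visit(node.left)
            visit(node.right)

        visit(tree.tree_)

    def test_logrank_comparator_same_engine(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(split_test="logrank", tau=0.0,
                               random_state=6).fit(X, y)
        assert tree.tree_.feature == 0
        assert tree.predict([[0.0, 0.5]])[0] == 1


class TestRoutingAndPrediction:
    def test_depth_zero_routes_to_node_one(self, rng):
        n = 30
        X = np.ones((n, 2))
        tree = CGESurvivalTree(tau=0.0, nperm=100, random_state=1).fit(
            X, (rng.exponential(size=n), np.ones(n, int))
        )
        assert tree.predict([[5.0, -3.0]])[0] == 1

    def test_boundary_value_goes_to_le_branch(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=0).fit(X, y)
        cutoff = tree.tree_.cutoff
        # value exactly at the cutoff belongs to the <= group
        le_node = tree._route(np.array([cutoff, 0.5]))
        gt_node = tree._route(np.array([cutoff + 1e-9, 0.5]))
        assert le_node is not gt_node

    def test_routing_matches_brute_force_interpreter(self, rng):
        X, y = two_group_data(rng, n=120, censor=True)
        tree = CGESurvivalTree(tau=0.25, nperm=200, p_threshold=0.05,
                               random_state=7).fit(X, y)
        spec = tree.to_dict()["root"]

        def interpret(node, z):
            if node["type"] == "terminal":
                return node["node_number"]
            goes_le = z[node["covariate_index"]] <= node["cutoff"]
            child = (
                node["left"]
                if (node["le_side"] == "left") == goes_le
                else node["right"]
            )
            return interpret(child, z)

        Z = np.column_stack([rng.random(100).round(2), rng.random(100).round(1)])
        expected = [interpret(spec, z) for z in Z]
        np.testing.assert_array_equal(tree.predict(Z), expected)

    def test_missing_covariate_rejected(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="missing"):
            tree.predict([[np.nan, 0.5]])

    def test_survival_prediction_properties(self, rng):
        X, y = two_group_data(rng, n=80, censor=True)
        tree = CGESurvivalTree(tau=0.25, nperm=200, random_state=8).fit(X, y)
        z = np.array([[0.0, 0.5]])
        assert tree.predict_survival(z, 0.0)[0, 0] == 1.0
        # constant extrapolation beyond the node's domain
        node = tree._route(z[0])
        far = tree.predict_survival(z, node.curve.domain_max * 5)[0, 0]
        assert far == node.curve(node.curve.domain_max)

    def test_prediction_matches_direct_cge_recomputation(self, rng):
        X, (x, delta) = two_group_data(rng, n=80, censor=True)
        tau = 0.5
        tree = CGESurvivalTree(tau=tau, nperm=200, random_state=8).fit(
            X, (x, delta)
        )
        cop = archimedean_copula("clayton", tau)
        for node in tree.terminal_nodes():
            idx = node.member_idx
            direct = copula_graphic(SurvivalSample(x[idx], delta[idx]), cop)
            assert node.curve.sup_distance(direct) == 0.0


class TestOrdering:
    def test_terminal_numbers_are_consecutive(self, rng):
        X, y = two_group_data(rng, n=100, censor=True)
        tree = CGESurvivalTree(tau=0.25, nperm=200, p_threshold=0.05,
                               random_state=10).fit(X, y)
        numbers = sorted(n.node_number for n in tree.terminal_nodes())
        assert numbers == list(range(1, tree.n_terminal_nodes_ + 1))

    def test_node_numbers_track_median_survival(self, rng):
        """When terminal-node medians are totally ordered, the numbering
        (1 = best prognosis) agrees with the median-survival order."""
        checked = 0
        for i in range(10):
            X, y = two_group_data(rng, n=100, hazard_ratio=np.exp(2.5),
                                  censor=True)
            tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=i).fit(X, y)
            nodes = tree.terminal_nodes()
            if len(nodes) < 2:
                continue
            medians = [n.median_survival for n in nodes]
            if len(set(medians)) != len(medians):
                continue
            order_by_number = [
                n.median_survival
                for n in sorted(nodes, key=lambda n: n.node_number)
            ]
            assert order_by_number == sorted(medians, reverse=True)
            checked += 1
        assert checked >= 3


class TestSerialization:
    def test_json_round_trip_structure(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=0).fit(X, y)
        payload = json.loads(tree.to_json(feature_names=["grp", "noise"]))
        assert payload["n_terminal_nodes"] == tree.n_terminal_nodes_
        assert payload["root"]["covariate"] == "grp"

    def test_dot_export(self, rng):
        X, y = two_group_data(rng)
        tree = CGESurvivalTree(tau=0.0, nperm=200, random_state=0).fit(X, y)
        dot = tree.to_dot()
        assert dot.startswith("digraph")
        assert "node 1" in dot

    def test_sklearn_clone(self):
        est = CGESurvivalTree(tau=0.5, nperm=123, min_child=3)
        c = clone(est)
        assert c.get_params() == est.get_params()


class TestCVSelectTau:
    def test_single_tau_table(self, rng):
        X, y = two_group_data(rng, n=60, censor=True)
        table = cv_select_tau(X, y, tau_grid=[0.25], folds=3, nperm=100,
                              seed=1)
        assert len(table) == 1
        assert 0.0 <= table["mean_harrells_c"].iloc[0] <= 1.0
        assert table["mean_ibs"].iloc[0] >= 0.0

    def test_deterministic(self, rng):
        X, y = two_group_data(rng, n=60, censor=True)
        a = cv_select_tau(X, y, tau_grid=[0.0, 0.5], folds=3, nperm=100, seed=2)
        b = cv_select_tau(X, y, tau_grid=[0.0, 0.5], folds=3, nperm=100, seed=2)
        assert a.equals(b)

    def test_folds_validation(self, rng):
        X, y = two_group_data(rng, n=30)
        with pytest.raises(ValueError):
            cv_select_tau(X, y, tau_grid=[0.0], folds=1, nperm=100, seed=1)
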