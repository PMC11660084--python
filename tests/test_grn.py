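"""Network inference: expression filters, RF importances, thresholding,
subgraph extraction, and the TF-role classifier."""

import numpy as np
import pandas as pd
import pytest

import hypoxnet as hx
from hypoxnet.grn import RegulatoryNetwork


def _net(rows):
    return RegulatoryNetwork(
        pd.DataFrame(rows, columns=["tf", "target", "importance"])
    )


class TestFilters:
    def test_gene_filter_boundary_inclusive(self):
        vals = np.zeros((2, 20))
        vals[0, :10] = 3.0          # exactly 10 samples at exactly 3
        vals[1, :9] = 3.0
        vals[1, 9:] = 2.9
        norm = pd.DataFrame(vals, index=["keep", "drop"],
                            columns=[f"s{i}" for i in range(20)])
        out = hx.filter_network_genes(norm)
        assert list(out.index) == ["keep"]

    def test_all_zero_gene_removed(self):
        norm = pd.DataFrame(np.zeros((1, 15)), index=["z"],
                            columns=[f"s{i}" for i in range(15)])
        assert hx.filter_network_genes(norm).empty

    def test_tf_filter_strictly_above_ten(self):
        cols = [f"s{i}" for i in range(12)]
        raw = pd.DataFrame(0, index=["tf_hi", "tf_lo"], columns=cols)
        raw.loc["tf_hi", cols[:3]] = 11
        raw.loc["tf_lo", cols[:3]] = 10
        assert hx.filter_expressed_tfs(raw, ["tf_hi", "tf_lo"]) == ["tf_hi"]

    def test_unknown_tf_warned_and_skipped(self):
        raw = pd.DataFrame(
            [[20] * 5], index=["tf1"], columns=[f"s{i}" for i in range(5)]
        )
        with pytest.warns(UserWarning, match="ghost"):
            kept = hx.filter_expressed_tfs(raw, ["tf1", "ghost"])
        assert kept == ["tf1"]

    def test_empty_tf_list(self):
        raw = pd.DataFrame([[1]], index=["g"], columns=["s"])
        assert hx.filter_expressed_tfs(raw, []) == []


@pytest.fixture(scope="module")
def copy_setup():
    rng = np.random.default_rng(0)
    tf_ids = [f"TF{i:02d}" for i in range(31)]
    X = rng.normal(0, 1, (31, 60))
    target = X[7] + rng.normal(0, 1e-6, 60)
    expr = pd.DataFrame(
        np.vstack([X, target]), index=tf_ids + ["target"],
        columns=[f"s{i}" for i in range(60)],
    )
    return tf_ids, expr


class TestInference:
    def test_exact_copy_parent_ranked_first(self, copy_setup):
        tf_ids, expr = copy_setup
        net = hx.infer_network(expr, tf_ids, targets=["target"],
                               n_trees=300, seed=0)
        reg = net.regulators_of("target")
        assert reg.iloc[0]["tf"] == "TF07"
        share = reg.iloc[0]["importance"] / reg["importance"].sum()
        decoy_median = reg.iloc[1:]["importance"].median()
        assert share > 0.25
        assert reg.iloc[0]["importance"] > 5 * decoy_median
        # independent oracle: correlation ranking picks the same parent
        corr = expr.loc[tf_ids].T.corrwith(expr.loc["target"]).abs()
        assert corr.idxmax() == "TF07"

    def test_independent_target_r2_near_zero(self, copy_setup):
        tf_ids, expr = copy_setup
        rng = np.random.default_rng(5)
        r2s = []
        for k in range(5):
            expr2 = expr.copy()
            expr2.loc["target"] = rng.normal(0, 1, expr.shape[1])
            net = hx.infer_network(expr2, tf_ids, targets=["target"],
                                   n_trees=300, seed=k)
            r2s.append(net.r2["target"])
        assert abs(np.median(r2s)) < 0.15

    def test_constant_target_zero_importances(self, copy_setup):
        tf_ids, expr = copy_setup
        expr2 = expr.copy()
        expr2.loc["target"] = 4.0
        net = hx.infer_network(expr2, tf_ids, targets=["target"],
                               n_trees=50, seed=0)
        assert (net.edges["importance"] == 0).all()
        assert net.r2["target"] <= 0.0

    def test_tf_column_order_irrelevant_for_top5(self, copy_setup):
        tf_ids, expr = copy_setup
        n1 = hx.infer_network(expr, tf_ids, targets=["target"],
                              n_trees=200, seed=0)
        n2 = hx.infer_network(expr, list(reversed(tf_ids)), targets=["target"],
                              n_trees=200, seed=0)
        top1 = set(hx.threshold_top_k(n1, 5).edges["tf"])
        top2 = set(hx.threshold_top_k(n2, 5).edges["tf"])
        assert "TF07" in top1 and "TF07" in top2

    def test_tf_excluded_from_its_own_predictors(self, copy_setup):
        tf_ids, expr = copy_setup
        net = hx.infer_network(expr, tf_ids, targets=["TF03"],
                               n_trees=50, seed=0)
        assert "TF03" not in set(net.edges["tf"])

    def test_too_few_tfs_rejected(self, copy_setup):
        _, expr = copy_setup
        with pytest.raises(ValueError):
            hx.infer_network(expr, ["TF00"])


class TestThreshold:
    def test_fewer_candidates_than_k_all_kept(self):
        net = _net([("a", "t", 1.0), ("b", "t", 0.5), ("c", "t", 0.2)])
        assert len(hx.threshold_top_k(net, 5).edges) == 3

    def test_top5_of_eight(self):
        net = _net([(f"tf{i}", "t", float(i)) for i in range(8)])
        kept = hx.threshold_top_k(net, 5).edges
        assert sorted(kept["importance"]) == [3.0, 4.0, 5.0, 6.0, 7.0]

    def test_tie_at_rank_k_breaks_lexicographically(self):
        net = _net(
            [("a", "t", 5.0), ("b", "t", 4.0), ("c", "t", 3.0),
             ("d", "t", 2.0), ("f", "t", 1.0), ("e", "t", 1.0)]
        )
        kept = hx.threshold_top_k(net, 5).edges
        assert "e" in set(kept["tf"]) and "f" not in set(kept["tf"])

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            hx.threshold_top_k(_net([("a", "t", 1.0)]), 0)

    def test_edge_budget_bound(self):
        rows = [(f"tf{i}", f"t{j}", float(i)) for j in range(4) for i in range(9)]
        kept = hx.threshold_top_k(_net(rows), 5).edges
        assert len(kept) <= 5 * 4


class TestSubgraph:
    def _network(self):
        rows = []
        rows += [("tfA", f"h{i}", 1.0) for i in range(10)]   # exactly 10
        rows += [("tfB", f"h{i}", 1.0) for i in range(9)]    # only 9
        rows += [("tfC", f"x{i}", 1.0) for i in range(12)]   # none hypoxic
        return _net(rows)

    def test_degree_ten_boundary(self):
        hyp = {f"h{i}" for i in range(10)}
        sub = hx.extract_hypoxia_subgraph(self._network(), hyp, min_degree=10)
        assert set(sub.edges["tf"]) == {"tfA"}

    def test_tf_without_hypoxia_targets_dropped(self):
        hyp = {f"h{i}" for i in range(10)}
        sub = hx.extract_hypoxia_subgraph(self._network(), hyp)
        assert "tfC" not in set(sub.edges["tf"])

    def test_identity_when_all_qualify(self):
        rows = [("tfA", f"h{i}", 1.0) for i in range(12)]
        net = _net(rows)
        sub = hx.extract_hypoxia_subgraph(net, {f"h{i}" for i in range(12)})
        pd.testing.assert_frame_equal(
            sub.edges.reset_index(drop=True), net.edges.reset_index(drop=True)
        )

    def test_idempotent(self):
        hyp = {f"h{i}" for i in range(10)}
        once = hx.extract_hypoxia_subgraph(self._network(), hyp)
        twice = hx.extract_hypoxia_subgraph(once, hyp)
        pd.testing.assert_frame_equal(once.edges, twice.edges)

    def test_empty_hypoxia_set_gives_empty_subgraph(self):
        sub = hx.extract_hypoxia_subgraph(self._network(), set())
        assert sub.edges.empty


class TestClassifier:
    def test_on_the_line_is_standard(self):
        assert hx.classify_tf(143, 24, 24 / 143) == "standard"

    def test_above_the_line_is_ethylene(self):
        assert hx.classify_tf(10, 5, 24 / 143) == "ethylene_mediated"

    def test_zero_y_always_standard(self):
        for slope in (0.01, 1.0, 100.0):
            assert hx.classify_tf(100, 0, slope) == "standard"

    def test_scale_invariance_fuzz(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.integers(0, 200), rng.integers(0, 50)
            slope = rng.uniform(0.01, 2.0)
            c = rng.uniform(0.1, 50.0)
            assert hx.classify_tf(x, y, slope) == hx.classify_tf(
                x * c, y * c, slope
            )

    def test_network_classification_uses_scaled_diagonal(self):
        rows = [("tfA", f"s{i}", 1.0) for i in range(143)]
        rows += [("tfA", f"e{i}", 1.0) for i in range(24)]
        rows += [("tfB", f"s{i}", 1.0) for i in range(10)]
        rows += [("tfB", f"e{i}", 1.0) for i in range(5)]
        net = _net(rows)
        hyp = {f"s{i}" for i in range(143)} | {f"e{i}" for i in range(24)}
        eth = {f"e{i}" for i in range(24)}
        table = hx.classify_network_tfs(net, hyp, eth).set_index("tf")
        assert table.loc["tfA", "label"] == "standard"  # defines the line
        assert table.loc["tfB", "label"] == "ethylene_mediated"

    def test_degenerate_no_standard_targets(self):
        rows = [("tfA", "e0", 1.0), ("tfB", "z0", 1.0)]
        net = _net(rows)
        table = hx.classify_network_tfs(net, {"e0"}, {"e0"}).set_index("tf")
        assert table.loc["tfA", "label"] == "ethylene_mediated"
        assert table.loc["tfB", "label"] == "standard"


class TestFocalSubnetwork:
    def _net3(self, pools):
        rows = [(tf, t, 1.0) for tf, pool in pools.items() for t in pool]
        return _net(rows)

    def test_disjoint_pools_zero_overlap(self):
        net = self._net3({"A": ["t1", "t2"], "B": ["t3", "t4"]})
        _, overlap, _ = hx.focal_tf_subnetwork(net, ["A", "B"])
        assert overlap["overlap"].tolist() == [0]

    def test_identical_pools_full_overlap(self):
        net = self._net3({"A": ["t1", "t2", "t3"], "B": ["t1", "t2", "t3"]})
        _, overlap, shared = hx.focal_tf_subnetwork(net, ["A", "B"])
        assert overlap["overlap"].tolist() == [3]
        assert shared == {"t1", "t2", "t3"}

    def test_three_way_intersection_counted_by_brute_force(self):
        common = [f"c{i}" for i in range(5)]
        pools = {
            "A": common + ["a1", "a2"],
            "B": common + ["b1"],
            "C": common + ["c_extra1", "c_extra2", "c_extra3"],
        }
        net = self._net3(pools)
        _, overlap, shared = hx.focal_tf_subnetwork(net, list(pools))
        brute = set(pools["A"]) & set(pools["B"]) & set(pools["C"])
        assert shared == brute and len(shared) == 5

    def test_unknown_focal_id_rejected(self):
        net = self._net3({"A": ["t1"], "B": ["t2"]})
        with pytest.raises(KeyError):
            hx.focal_tf_subnetwork(net, ["A", "nope"])


class TestNetworkInvariants:
    def test_no_self_edges_and_nonnegative_importances_enforced(self):
        with pytest.raises(ValueError):
            _net([("a", "a", 1.0)])
        with pytest.raises(ValueError):
            _net([("a", "b", -0.1)])
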