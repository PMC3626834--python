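import itertools

import numpy as np
import pandas as pd
import pytest

from mobrf import (
    MobControl,
    MobTree,
    fit_node_model,
    grow_tree,
    parse_formula,
    search_split,
    tree_predict,
)
from mobrf.node_models import log_likelihood

SPEC = parse_formula("y ~ x")


def piecewise_data(n=200, seed=0, noise=0.0):
    """y = x left of z=0, y = -x right of it; z uniform on (-1, 1)."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(-1, 1, n)
    x = rng.standard_normal(n)
    y = np.where(z < 0, x, -x) + noise * rng.standard_normal(n)
    return pd.DataFrame({"y": y, "x": x, "z": z})


def brute_force_best_split(rows, variable, spec, control):
    """Enumerate every admissible threshold with fresh full fits."""
    z = np.sort(rows[variable].unique())
    best_obj, best_thr = -np.inf, None
    for lo, hi in zip(z[:-1], z[1:]):
        thr = (lo + hi) / 2.0
        left = rows[rows[variable] <= thr]
        right = rows[rows[variable] > thr]
        if len(left) < control.minsplit or len(right) < control.minsplit:
            continue
        try:
            ml = fit_node_model(spec, left)
            mr = fit_node_model(spec, right)
        except Exception:
            continue
        obj = log_likelihood(ml, left) + log_likelihood(mr, right)
        if obj > best_obj + 1e-12:
            best_obj, best_thr = obj, thr
    return best_thr


class TestSearchSplit:
    def test_noiseless_piecewise_threshold_near_zero(self):
        df = piecewise_data(n=200, seed=1)
        rule = search_split(df, "z", SPEC, MobControl())
        z = np.sort(df["z"].to_numpy())
        gap = np.diff(z).max()
        assert rule is not None and abs(rule.threshold) <= gap

    def test_minsplit_larger_than_half_returns_none(self):
        df = piecewise_data(n=40, seed=2)
        assert search_split(df, "z", SPEC, MobControl(minsplit=21)) is None

    def test_matches_brute_force_on_tiny_data(self):
        control = MobControl(minsplit=3)
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(8, 13))
            df = pd.DataFrame(
                {
                    "x": rng.standard_normal(n),
                    "z": rng.standard_normal(n),
                }
            )
            df["y"] = np.where(df["z"] < 0, 1.0, -1.0) * df["x"] + 0.1 * rng.standard_normal(n)
            rule = search_split(df, "z", SPEC, control)
            oracle = brute_force_best_split(df, "z", SPEC, control)
            if oracle is None:
                assert rule is None
            else:
                assert rule is not None
                assert rule.threshold == pytest.approx(oracle, abs=1e-12)

    def test_categorical_distinct_level_isolated(self):
        rng = np.random.default_rng(3)
        n = 120
        z = pd.Series(rng.choice(["A", "B", "C"], n))
        x = rng.standard_normal(n)
        y = x + np.where(z == "C", 3.0, 0.0) + 0.05 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        rule = search_split(df, "z", SPEC, MobControl(minsplit=10))
        assert rule is not None and rule.kind == "categorical_partition"
        assert rule.left_levels in (frozenset({"C"}), frozenset({"A", "B"}))

    def test_binomial_split_search(self):
        rng = np.random.default_rng(4)
        n = 300
        z = rng.uniform(-1, 1, n)
        x = rng.standard_normal(n)
        eta = np.where(z < 0.2, 2.0, -2.0) * x
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        rule = search_split(df, "z", parse_formula("y ~ x", "binomial"), MobControl())
        assert rule is not None and abs(rule.threshold - 0.2) < 0.15


class TestGrowTree:
    def test_minsplit_equal_n_gives_global_fit(self):
        df = piecewise_data(n=100, seed=5, noise=0.2)
        tree = grow_tree(df, SPEC, ["z"], MobControl(minsplit=100), 1, np.random.default_rng(0))
        assert tree.root.is_terminal
        global_fit = fit_node_model(SPEC, df)
        np.testing.assert_array_equal(tree.root.model.coefficients, global_fit.coefficients)

    def test_tiny_alpha_gives_single_node(self):
        df = piecewise_data(n=300, seed=6)
        tree = grow_tree(df, SPEC, ["z"], MobControl(alpha=1e-301), 1, np.random.default_rng(0))
        assert tree.root.is_terminal

    def test_determinism(self):
        df = piecewise_data(n=250, seed=7, noise=0.3)
        t1 = grow_tree(df, SPEC, ["z"], MobControl(), 1, np.random.default_rng(11))
        t2 = grow_tree(df, SPEC, ["z"], MobControl(), 1, np.random.default_rng(11))
        assert t1.to_json() == t2.to_json()

    def test_terminal_nodes_partition_training_rows(self):
        df = piecewise_data(n=300, seed=8, noise=0.3)
        tree = grow_tree(df, SPEC, ["z"], MobControl(), 1, np.random.default_rng(0))

        leaf_sizes = []

        def walk(node):
            if node.is_terminal:
                leaf_sizes.append(node.n_fit)
            else:
                walk(node.left)
                walk(node.right)

        walk(tree.root)
        assert sum(leaf_sizes) == len(df)
        assert min(leaf_sizes) >= MobControl().minsplit

    def test_monotone_stopping_in_minsplit(self):
        df = piecewise_data(n=300, seed=9, noise=0.3)

        def depth(node):
            if node.is_terminal:
                return 0
            return 1 + max(depth(node.left), depth(node.right))

        depths = []
        for minsplit in (20, 40, 80, 150):
            tree = grow_tree(df, SPEC, ["z"], MobControl(minsplit=minsplit), 1,
                             np.random.default_rng(1))
            depths.append(depth(tree.root))
        assert all(a >= b for a, b in zip(depths, depths[1:]))

    def test_mostly_single_node_under_null(self):
        # pure-noise outcome: with one variable tested at alpha=0.05 the tree
        # should stay a single node at roughly the nominal rate
        single = 0
        reps = 400
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "x": rng.standard_normal(200),
                    "z": rng.standard_normal(200),
                }
            )
            df["y"] = 0.5 + df["x"] + rng.standard_normal(200)
            tree = grow_tree(df, SPEC, ["z"], MobControl(alpha=0.05), 1, rng)
            single += tree.root.is_terminal
        assert single / reps >= 0.92

    def test_noiseless_piecewise_training_recovery(self):
        df = piecewise_data(n=200, seed=10)
        tree = grow_tree(df, SPEC, ["z"], MobControl(alpha=0.01), 1, np.random.default_rng(0))
        pred = tree_predict(tree, df)
        np.testing.assert_allclose(pred, df["y"], atol=1e-8)


class TestTreePredict:
    def test_single_node_tree_equals_root_model(self):
        from mobrf import predict_response

        df = piecewise_data(n=80, seed=11, noise=0.5)
        tree = grow_tree(df, SPEC, ["z"], MobControl(minsplit=80), 1, np.random.default_rng(0))
        np.testing.assert_array_equal(tree_predict(tree, df), predict_response(tree.root.model, df))

    def test_two_leaf_routing(self):
        rng = np.random.default_rng(12)
        z = np.concatenate([rng.uniform(-1, -0.1, 60), rng.uniform(0.1, 1, 60)])
        y = np.where(z < 0, 1.0, -1.0)
        # y is constant within each side, so each leaf fit is intercept +-1
        df = pd.DataFrame({"y": y, "x": rng.standard_normal(120), "z": z})
        spec = parse_formula("y ~ x")
        tree = grow_tree(df, spec, ["z"], MobControl(), 1, np.random.default_rng(0))
        assert not tree.root.is_terminal
        pred = tree_predict(tree, df)
        np.testing.assert_allclose(pred, y, atol=1e-8)

    def test_unseen_categorical_level_routes_left_with_warning(self):
        rng = np.random.default_rng(13)
        n = 160
        z = pd.Series(rng.choice(["A", "B"], n))
        x = rng.standard_normal(n)
        y = x + np.where(z == "A", 2.0, -2.0) + 0.05 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        tree = grow_tree(df, SPEC, ["z"], MobControl(), 1, np.random.default_rng(0))
        assert not tree.root.is_terminal
        new = pd.DataFrame({"x": [0.0], "z": ["UNSEEN"]})
        with pytest.warns(UserWarning, match="unseen"):
            pred = tree_predict(tree, new)
        left_pred = tree_predict(tree, pd.DataFrame({"x": [0.0], "z": [next(iter(tree.root.split.left_levels))]}))
        assert pred[0] == left_pred[0]


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self):
        df = piecewise_data(n=250, seed=14, noise=0.2)
        tree = grow_tree(df, SPEC, ["z"], MobControl(), 1, np.random.default_rng(2))
        restored = MobTree.from_json(tree.to_json())
        np.testing.assert_array_equal(tree_predict(tree, df), tree_predict(restored, df))
        assert restored.to_json() == tree.to_json()

    def test_text_rendering_mentions_every_split(self):
        df = piecewise_data(n=250, seed=15, noise=0.2)
        tree = grow_tree(df, SPEC, ["z"], MobControl(), 1, np.random.default_rng(2))
        text = tree.to_text()
        assert text.count("split:") == tree.n_terminal_nodes - 1
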