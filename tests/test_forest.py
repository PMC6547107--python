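import numpy as np
import pytest

from precisionrct import (
    RLTForest,
    RLTParams,
    TreeNode,
    embedded_importance,
    fit_forest,
    fit_tree,
    path_variables,
    predict,
)

# ---------------------------------------------------------------------------
# independent oracle: a deliberately naive greedy variance-reduction CART,
# written without reference to the forest module's internals.  Shared
# conventions: splits need >= min_leaf rows per child, cut at the midpoint of
# the adjacent sorted values, gain ties resolved to the lowest variable index
# and then the smallest cut.


def cart_best_split(X, y, min_leaf):
    best = None
    n, p = X.shape
    base = np.sum((y - y.mean()) ** 2)
    for var in range(p):
        xs = np.sort(np.unique(X[:, var]))
        for a, b in zip(xs[:-1], xs[1:]):
            cut = (a + b) / 2.0
            left = X[:, var] <= cut
            if left.sum() < min_leaf or (~left).sum() < min_leaf:
                continue
            sse = (
                np.sum((y[left] - y[left].mean()) ** 2)
                + np.sum((y[~left] - y[~left].mean()) ** 2)
            )
            gain = base - sse
            if best is None or gain > best[0] + 1e-12:
                best = (gain, var, cut)
    return best


def cart_grow(X, y, min_node_size):
    node = {"pred": float(y.mean())}
    if len(y) < 2 * min_node_size or len(np.unique(y)) < 2:
        return node
    best = cart_best_split(X, y, min_node_size)
    if best is None or best[0] <= 0:
        return node
    _, var, cut = best
    left = X[:, var] <= cut
    node.update(
        var=var,
        cut=cut,
        left=cart_grow(X[left], y[left], min_node_size),
        right=cart_grow(X[~left], y[~left], min_node_size),
    )
    return node


def trees_equal(rlt: TreeNode, cart: dict) -> bool:
    if rlt.is_leaf != ("var" not in cart):
        return False
    if rlt.is_leaf:
        return np.isclose(rlt.prediction, cart["pred"])
    return (
        rlt.split_var == cart["var"]
        and np.isclose(rlt.split_value, cart["cut"])
        and trees_equal(rlt.left, cart["left"])
        and trees_equal(rlt.right, cart["right"])
    )


# ---------------------------------------------------------------------------


class TestEmbeddedImportance:
    def test_constant_response_gives_zero(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.full(60, 3.0)
        imp = embedded_importance(X, y, range(4), rng)
        np.testing.assert_array_equal(imp, 0.0)

    def test_importances_nonnegative(self, rng):
        X = rng.normal(size=(80, 5))
        y = X[:, 1] + rng.normal(scale=0.5, size=80)
        imp = embedded_importance(X, y, range(5), rng, RLTParams())
        assert np.all(imp >= 0)

    def test_signal_beats_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 2))
            y = 3 * X[:, 0] + rng.normal(scale=0.05, size=100)
            imp = embedded_importance(X, y, [0, 1], rng, RLTParams())
            hits += imp[0] > imp[1]
        assert hits >= 95

    def test_single_candidate_is_top_ranked(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 2] + rng.normal(scale=0.1, size=60)
        imp = embedded_importance(X, y, [2], rng, RLTParams())
        assert imp.shape == (1,)
        assert imp[0] > 0

    def test_deterministic_given_rng_state(self):
        X = np.random.default_rng(0).normal(size=(80, 4))
        y = X[:, 0] + np.random.default_rng(1).normal(scale=0.2, size=80)
        a = embedded_importance(X, y, range(4), np.random.default_rng(5), RLTParams())
        b = embedded_importance(X, y, range(4), np.random.default_rng(5), RLTParams())
        np.testing.assert_array_equal(a, b)


class TestFitTree:
    def test_constant_response_single_leaf(self, rng):
        X = rng.normal(size=(50, 3))
        tree = fit_tree(X, np.ones(50), RLTParams(seed=0))
        assert tree.is_leaf
        assert tree.prediction == 1.0

    def test_degenerate_rows_single_leaf(self):
        X = np.ones((40, 3))
        y = np.random.default_rng(0).normal(size=40)
        tree = fit_tree(X, y, RLTParams(seed=0))
        assert tree.is_leaf

    def test_step_function_root_split(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 3))
        y = (X[:, 0] > 0).astype(float)
        tree = fit_tree(X, y, RLTParams(seed=0), rng=np.random.default_rng(0))
        assert tree.split_var == 0
        gap_lo = X[X[:, 0] <= 0, 0].max()
        gap_hi = X[X[:, 0] > 0, 0].min()
        assert gap_lo <= tree.split_value <= gap_hi

    def test_zero_muting_rate_keeps_candidate_sets(self, rng):
        X = rng.normal(size=(300, 4))
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(scale=0.2, size=300)
        tree = fit_tree(X, y, RLTParams(muting_rate=0.0, seed=0))

        def check(node):
            if node.is_leaf:
                return
            assert node.left.candidate_set == node.candidate_set
            assert node.right.candidate_set == node.candidate_set
            check(node.left)
            check(node.right)

        check(tree)

    def test_muting_monotone_and_split_var_in_candidates(self, rng):
        X = rng.normal(size=(400, 8))
        y = X[:, 0] - X[:, 3] + rng.normal(scale=0.3, size=400)
        tree = fit_tree(X, y, RLTParams(muting_rate=0.4, seed=1))
        shrank = []

        def check(node):
            if node.is_leaf:
                return
            assert node.split_var in node.candidate_set
            for child in (node.left, node.right):
                assert set(child.candidate_set) <= set(node.candidate_set)
                assert node.split_var in child.candidate_set
                shrank.append(len(child.candidate_set) < len(node.candidate_set))
                check(child)

        check(tree)
        assert any(shrank)  # muting actually removed variables somewhere


class TestCartOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_degenerate_parameters_reduce_to_greedy_cart(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        p = int(rng.integers(2, 5))
        X = rng.normal(size=(n, p))
        y = X[:, 0] + rng.normal(scale=0.5, size=n)
        params = RLTParams(
            n_trees=1, muting_rate=0.0, embedded_trees=1, subsample_frac=1.0,
            min_node_size=5, seed=seed,
        )
        forest = fit_forest(X, y, params)
        oracle = cart_grow(X, y, min_node_size=5)
        assert trees_equal(forest.trees[0], oracle)


class TestForest:
    def test_same_seed_identical_forest(self, rng):
        X = rng.normal(size=(200, 4))
        y = X[:, 0] + rng.normal(scale=0.3, size=200)
        p = RLTParams(n_trees=10, seed=3)
        a, b = fit_forest(X, y, p), fit_forest(X, y, p)
        assert a.to_json() == b.to_json()

    def test_single_tree_forest_matches_fit_tree_on_subsample(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 1] + rng.normal(scale=0.2, size=100)
        f = fit_forest(X, y, RLTParams(n_trees=1, subsample_frac=1.0, seed=2))
        assert len(f.trees) == 1
        assert len(f.oob_mse) == 1

    def test_forest_prediction_is_tree_average(self, rng):
        X = rng.normal(size=(150, 3))
        y = X[:, 0] ** 2 + rng.normal(scale=0.2, size=150)
        f = fit_forest(X, y, RLTParams(n_trees=7, seed=1))
        from precisionrct.forest import _predict_tree

        manual = np.mean([_predict_tree(t, X[:5]) for t in f.trees], axis=0)
        np.testing.assert_allclose(predict(f, X[:5]), manual)

    def test_training_mse_beats_variance_for_smooth_signal(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(500, 4))
            y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(scale=0.3, size=500)
            f = fit_forest(X, y, RLTParams(n_trees=20, seed=seed))
            ok += np.mean((predict(f, X) - y) ** 2) <= y.var()
        assert ok >= 19

    def test_signal_recovery_root_split_fraction(self):
        # 1 linear signal + 9 noise covariates at SNR 2
        rng = np.random.default_rng(0)
        n = 500
        X = rng.normal(size=(n, 10))
        signal = X[:, 0]
        noise_sd = signal.std() / np.sqrt(2)
        y = signal + rng.normal(scale=noise_sd, size=n)
        f = fit_forest(X, y, RLTParams(n_trees=100, seed=0))
        roots = [t.split_var for t in f.trees if not t.is_leaf]
        assert len(roots) == 100
        assert np.mean(np.array(roots) == 0) >= 0.8

    def test_prediction_ignores_variable_off_all_paths(self):
        # hand-built 2-tree forest: neither tree consults variable 2
        leaf = lambda v: TreeNode(v, 10, (0, 1))
        t1 = TreeNode(0.0, 20, (0, 1, 2), split_var=0, split_value=0.0,
                      left=leaf(0.2), right=leaf(0.8))
        t2 = TreeNode(0.0, 20, (0, 1, 2), split_var=1, split_value=1.0,
                      left=leaf(0.4), right=leaf(0.6))
        f = RLTForest([t1, t2], RLTParams(n_trees=2))
        x = np.array([0.5, 0.0, -3.0])
        x2 = np.array([0.5, 0.0, 42.0])
        assert predict(f, x) == predict(f, x2) == pytest.approx((0.8 + 0.4) / 2)
        assert path_variables(t1, x) == {0}

    def test_schema_mismatch_rejected(self, rng):
        X = rng.normal(size=(100, 4))
        y = X[:, 0]
        f = fit_forest(X, y, RLTParams(n_trees=2, seed=0))
        with pytest.raises(ValueError, match="columns"):
            predict(f, X[:, :2])

    def test_json_roundtrip(self, rng):
        X = rng.normal(size=(120, 3))
        y = X[:, 0] + rng.normal(scale=0.2, size=120)
        f = fit_forest(X, y, RLTParams(n_trees=3, seed=5), treatment_var=2,
                       feature_names=["a", "b", "arm"])
        g = RLTForest.from_json(f.to_json())
        assert g.treatment_var == 2
        assert g.feature_names == ["a", "b", "arm"]
        np.testing.assert_allclose(predict(g, X), predict(f, X))


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"muting_rate": 1.0},
            {"min_node_size": 1},
            {"n_trees": 0},
            {"embedded_trees": 0},
            {"subsample_frac": 0.0},
            {"importance_threshold": -1.0},
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            RLTParams(**kw).validate()
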