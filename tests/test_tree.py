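"""CART tree: impurity, fitting, prediction, serialization."""

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

import posturegrade as pg
from posturegrade.exceptions import InvalidInputError
from posturegrade.tree import TrainConfig, fit_tree, gini


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 0, 0, 0, 0), 0.0),
            ((2, 2, 2, 2, 2), 0.8),
            ((2, 1), 4 / 9),
        ],
    )
    def test_closed_form(self, counts, expected):
        assert gini(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_node_rejected(self):
        with pytest.raises(InvalidInputError):
            gini((0, 0, 0))

    def test_uniform_maximizes(self):
        """gini <= 1 - 1/K with equality only at the uniform mixture."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            counts = rng.integers(0, 30, size=k)
            if counts.sum() == 0:
                continue
            g = gini(counts)
            assert g <= 1 - 1 / k + 1e-12
            if len(set(counts)) == 1 and counts[0] > 0:
                assert g == pytest.approx(1 - 1 / k)


class TestFit:
    def test_single_class_gives_single_leaf(self):
        X = np.arange(8.0)[:, None]
        tree = fit_tree(X, np.full(8, 3), TrainConfig(max_depth=5))
        assert tree.root.is_leaf
        assert (tree.predict(X) == 3).all()

    def test_depth1_best_split_between_2_and_3(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 2, 2])
        tree = fit_tree(X, y, TrainConfig(max_depth=1, splitter="best"))
        assert 2.0 < tree.root.threshold < 3.0
        assert (tree.predict(X) == y).all()

    def test_random_splitter_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 5, size=40)
        cfg = TrainConfig(max_depth=4, splitter="random", seed=77)
        t1 = fit_tree(X, y, cfg)
        t2 = fit_tree(X, y, cfg)
        assert t1.to_json() == t2.to_json()

    def test_depth_limit_respected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 5, size=100)
        for d in (1, 2, 3):
            assert fit_tree(X, y, TrainConfig(max_depth=d)).depth() <= d

    def test_unrestricted_best_tree_reproduces_labels(self):
        """With no duplicate rows, a deep 'best' tree attains 100% training accuracy."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            X = rng.normal(size=(60, 2))
            y = rng.integers(0, 5, size=60)
            tree = fit_tree(X, y, TrainConfig(max_depth=60))
            assert (tree.predict(X) == y).all()

    def test_every_split_decreases_weighted_impurity(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 3))
        y = rng.integers(0, 5, size=80)
        tree = fit_tree(X, y, TrainConfig(max_depth=6))

        def walk(node):
            if node.is_leaf:
                return
            n = node.counts.sum()
            weighted = (
                node.left.counts.sum() * gini(node.left.counts)
                + node.right.counts.sum() * gini(node.right.counts)
            ) / n
            assert weighted < gini(node.counts)
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_root_split_gain_matches_sklearn(self):
        """Dual route: the root 'best' split gain equals sklearn's on the same data."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            X = rng.normal(size=(50, 3))
            y = rng.integers(0, 3, size=50)
            mine = fit_tree(X, y, TrainConfig(max_depth=1, splitter="best"))
            sk = DecisionTreeClassifier(criterion="gini", max_depth=1, random_state=0)
            sk.fit(X, y)
            if mine.root.is_leaf:
                assert sk.tree_.node_count == 1
                continue

            def gain(node_counts, l_counts, r_counts):
                n = node_counts.sum()
                return gini(node_counts) - (
                    l_counts.sum() * gini(l_counts) + r_counts.sum() * gini(r_counts)
                ) / n

            my_gain = gain(mine.root.counts, mine.root.left.counts, mine.root.right.counts)
            v = sk.tree_.value[:, 0, :] * sk.tree_.weighted_n_node_samples[:, None]
            sk_gain = gain(v[0], v[1], v[2])
            assert my_gain == pytest.approx(sk_gain, abs=1e-10)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_tree(np.empty((0, 2)), np.empty(0), TrainConfig(max_depth=2))
        with pytest.raises(InvalidInputError):
            fit_tree(np.ones((3, 2)), np.zeros(4), TrainConfig(max_depth=2))
        with pytest.raises(InvalidInputError):
            TrainConfig(max_depth=0)


class TestPredict:
    def test_leaf_tie_breaks_to_lowest_class(self):
        # duplicate x rows with different labels -> tied counts at the leaf
        tree = fit_tree(np.ones((2, 1)), np.array([1, 0]), TrainConfig(max_depth=3))
        assert (tree.predict(np.ones((2, 1))) == 0).all()

    def test_dimension_mismatch_rejected(self):
        tree = fit_tree(np.ones((4, 2)), np.zeros(4), TrainConfig(max_depth=1))
        with pytest.raises(InvalidInputError):
            tree.predict(np.ones((2, 3)))


class TestSerialization:
    def test_json_roundtrip_exact(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(50, 4))
        y = rng.integers(0, 5, size=50)
        tree = fit_tree(X, y, TrainConfig(max_depth=5, splitter="random", seed=3),
                        feature_names=("F1", "F2", "F3", "F4"))
        clone = pg.DecisionTree.from_json(tree.to_json())
        assert clone.to_json() == tree.to_json()
        assert (clone.predict(X) == tree.predict(X)).all()

    def test_importances_sum_to_one(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 4, size=60)
        tree = fit_tree(X, y, TrainConfig(max_depth=4))
        imp = tree.feature_importances()
        assert imp.sum() == pytest.approx(1.0)
        assert (imp >= 0).all()
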