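"""Binary CART decision tree with Gini splits.

Implements the classifier used for automated MDS-UPDRS-III 3.13 grading:
a depth-limited greedy binary tree minimizing Gini impurity, with either an
exhaustive ('best') or a seeded randomized ('random') split strategy.

Split strategies
----------------
best
    For every feature, scan the midpoints between consecutive sorted unique
    values and keep the split with the largest weighted impurity decrease.
random
    For every feature, draw a single uniform threshold inside the node's
    value range (extremely-randomized style), then keep the best feature.
    Seeded, hence reproducible.

All tie-breaks are deterministic: lowest feature index, then lowest
threshold, and leaf ties predict the lowest class label, so identical seeds
give byte-identical serialized models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "N_CLASSES",
    "TrainConfig",
    "TreeNode",
    "DecisionTree",
    "gini",
    "fit_tree",
    "predict",
]

#: severity classes 0..4 of MDS-UPDRS-III item 3.13
N_CLASSES = 5

# split gains below this are treated as zero (no improvement)
_GAIN_TOL = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters for one tree."""

    max_depth: int
    splitter: Literal["best", "random"] = "best"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise InvalidInputError("max_depth must be >= 1")
        if self.splitter not in ("best", "random"):
            raise InvalidInputError(f"unknown splitter: {self.splitter!r}")


def gini(class_counts: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a node's class counts.

    0 for a pure node; at most 1 - 1/K, attained by the uniform mixture.
    """
    c = np.asarray(class_counts, dtype=float)
    if np.any(c < 0):
        raise InvalidInputError("class counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise InvalidInputError("gini undefined for an empty node")
    p = c / total
    return float(1.0 - np.sum(p * p))


@dataclass
class TreeNode:
    """One node; internal nodes carry (feature, threshold), leaves a prediction."""

    counts: np.ndarray
    prediction: int
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    """A fitted CART tree for severity classes 0..4."""

    root: TreeNode
    config: TrainConfig
    n_features: int
    feature_names: tuple[str, ...] = field(default=())

    # -- prediction ---------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise InvalidInputError(
                f"expected {self.n_features} features, got shape {X.shape}"
            )
        out = np.empty(X.shape[0], dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def feature_importances(self) -> np.ndarray:
        """Impurity-decrease importances, normalized to sum to 1."""
        imp = np.zeros(self.n_features)

        def _walk(node: TreeNode) -> None:
            if node.is_leaf:
                return
            n = node.counts.sum()
            nl = node.left.counts.sum()
            nr = node.right.counts.sum()
            gain = gini(node.counts) - (
                nl * gini(node.left.counts) + nr * gini(node.right.counts)
            ) / n
            imp[node.feature] += n * gain
            _walk(node.left)
            _walk(node.right)

        _walk(self.root)
        s = imp.sum()
        return imp / s if s > 0 else imp

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        nodes: list[dict] = []

        def _add(node: TreeNode) -> int:
            nid = len(nodes)
            rec = {
                "id": nid,
                "feature": node.feature,
                "threshold": node.threshold,
                "left": None,
                "right": None,
                "counts": [int(c) for c in node.counts],
                "prediction": int(node.prediction),
            }
            nodes.append(rec)
            if not node.is_leaf:
                rec["left"] = _add(node.left)
                rec["right"] = _add(node.right)
            return nid

        _add(self.root)
        doc = {
            "config": {
                "max_depth": self.config.max_depth,
                "splitter": self.config.splitter,
                "seed": self.config.seed,
            },
            "n_features": self.n_features,
            "feature_names": list(self.feature_names),
            "nodes": nodes,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        doc = json.loads(text)
        nodes = doc["nodes"]

        def _build(nid: int) -> TreeNode:
            rec = nodes[nid]
            node = TreeNode(
                counts=np.asarray(rec["counts"], dtype=float),
                prediction=int(rec["prediction"]),
                feature=rec["feature"],
                threshold=rec["threshold"],
            )
            if rec["feature"] is not None:
                node.left = _build(rec["left"])
                node.right = _build(rec["right"])
            return node

        cfg = TrainConfig(**doc["config"])
        return cls(
            root=_build(0),
            config=cfg,
            n_features=int(doc["n_features"]),
            feature_names=tuple(doc["feature_names"]),
        )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=N_CLASSES).astype(float)


def _leaf(y: np.ndarray) -> TreeNode:
    counts = _class_counts(y)
    return TreeNode(counts=counts, prediction=int(np.argmax(counts)))


def _best_split_for_feature(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    """Best (gain, threshold) scanning midpoints of consecutive unique values."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    uniq = np.unique(xs)
    if uniq.size < 2:
        return None
    n = y.size
    parent = gini(_class_counts(y))
    best: tuple[float, float] | None = None
    left_counts = np.zeros(N_CLASSES)
    total_counts = _class_counts(y)
    i = 0
    for u_prev, u_next in zip(uniq[:-1], uniq[1:]):
        while i < n and xs[i] <= u_prev:
            left_counts[ys[i]] += 1
            i += 1
        thr = 0.5 * (u_prev + u_next)
        nl = left_counts.sum()
        right_counts = total_counts - left_counts
        gain = parent - (nl * gini(left_counts) + (n - nl) * gini(right_counts)) / n
        if best is None or gain > best[0] + _GAIN_TOL:
            best = (gain, float(thr))
    return best


def _random_split_for_feature(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[float, float] | None:
    """(gain, threshold) for one uniform threshold inside the node's range.

    Features that are constant within the node draw nothing from ``rng``,
    so the stream only advances for splittable features.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return None
    thr = float(rng.uniform(lo, hi))
    # uniform in [lo, hi) can land on lo: every point goes right, no split
    mask = x <= thr
    nl = int(mask.sum())
    n = y.size
    if nl == 0 or nl == n:
        return None
    parent = gini(_class_counts(y))
    gain = parent - (
        nl * gini(_class_counts(y[mask])) + (n - nl) * gini(_class_counts(y[~mask]))
    ) / n
    return (gain, thr)


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    depth: int,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> TreeNode:
    node = _leaf(y)
    if depth >= cfg.max_depth or np.unique(y).size == 1:
        return node

    best_gain, best_feat, best_thr = _GAIN_TOL, None, None
    for j in range(X.shape[1]):
        if cfg.splitter == "best":
            cand = _best_split_for_feature(X[:, j], y)
        else:
            cand = _random_split_for_feature(X[:, j], y, rng)
        if cand is not None and cand[0] > best_gain:
            best_gain, best_feat, best_thr = cand[0], j, cand[1]

    if best_feat is None:
        return node

    mask = X[:, best_feat] <= best_thr
    node.feature = best_feat
    node.threshold = best_thr
    node.left = _grow(X[mask], y[mask], depth + 1, cfg, rng)
    node.right = _grow(X[~mask], y[~mask], depth + 1, cfg, rng)
    return node


def fit_tree(
    X,
    y,
    cfg: TrainConfig,
    feature_names: Sequence[str] = (),
) -> DecisionTree:
    """Fit a CART tree on a feature matrix and severity scores 0..4.

    Greedy recursive partitioning: at each node the split maximizing the
    weighted Gini impurity decrease is taken; growth stops at ``max_depth``,
    at a pure node, or when no split improves impurity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidInputError("empty training data")
    if X.shape[0] != y.shape[0]:
        raise InvalidInputError("X and y length mismatch")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("features contain missing or non-finite values")
    y = y.astype(int)
    if np.any((y < 0) | (y >= N_CLASSES)):
        raise InvalidInputError(f"scores must lie in 0..{N_CLASSES - 1}")

    rng = np.random.default_rng(cfg.seed)
    root = _grow(X, y, 0, cfg, rng)
    return DecisionTree(
        root=root,
        config=cfg,
        n_features=X.shape[1],
        feature_names=tuple(feature_names),
    )


def predict(tree: DecisionTree, X) -> np.ndarray:
    """Predict severity scores; leaf ties resolve to the lowest class label."""
    return tree.predict(X)
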