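"""Model selection: stratified k-fold cross-validation and grid search.

The grid searches over feature subsets, tree depths and split strategies;
each candidate is scored by the human-machine objective evaluated on the
pooled out-of-fold predictions, so the winner is the configuration whose
cross-validated scores deviate least (and rarely grossly) from the
clinician's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .exceptions import InvalidInputError
from .metrics import ObjectiveConfig, objective
from .tree import TrainConfig, fit_tree

__all__ = [
    "CVConfig",
    "GridSpec",
    "GridResult",
    "stratified_folds",
    "cross_validate",
    "grid_search",
]


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation settings (stratified by severity class)."""

    k: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidInputError("k must be >= 2")


def stratified_folds(y, cv: CVConfig) -> np.ndarray:
    """Assign each subject a fold id in 0..k-1.

    Stratified assignment: within each class, the (seeded) shuffled members
    are dealt cyclically to folds starting at a random fold, so class
    proportions stay as equal across folds as integer rounding allows.
    With ``stratified=False`` a plain shuffled split is used.
    """
    y = np.asarray(y, dtype=int)
    n = y.size
    if cv.k > n:
        raise InvalidInputError(f"k={cv.k} exceeds sample size {n}")
    rng = np.random.default_rng(cv.seed)
    fold = np.empty(n, dtype=int)
    if not cv.stratified:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            fold[idx] = pos % cv.k
        return fold
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members.size)
        start = int(rng.integers(cv.k))
        for pos, m in enumerate(members[perm]):
            fold[m] = (start + pos) % cv.k
    return fold


def cross_validate(X, y, cfg: TrainConfig, cv: CVConfig) -> np.ndarray:
    """Out-of-fold predicted scores: each subject is predicted exactly once
    by a tree trained on the other folds.

    Per-fold trees receive distinct deterministic seeds derived from
    ``cfg.seed`` so the 'random' splitter differs between folds but the
    whole procedure is reproducible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise InvalidInputError("X and y length mismatch")
    fold = stratified_folds(y, cv)
    pred = np.empty_like(y)
    fold_seeds = np.random.default_rng(cfg.seed).integers(0, 2**31 - 1, size=cv.k)
    for f in range(cv.k):
        test = fold == f
        if not test.any():
            continue
        fold_cfg = TrainConfig(
            max_depth=cfg.max_depth, splitter=cfg.splitter, seed=int(fold_seeds[f])
        )
        tree = fit_tree(X[~test], y[~test], fold_cfg)
        pred[test] = tree.predict(X[test])
    return pred


@dataclass(frozen=True)
class GridSpec:
    """Search space: feature subsets x depths x split strategies."""

    feature_subsets: tuple[tuple[str, ...], ...]
    depths: tuple[int, ...]
    splitters: tuple[Literal["best", "random"], ...]

    def __post_init__(self) -> None:
        if not (self.feature_subsets and self.depths and self.splitters):
            raise InvalidInputError("grid must list at least one subset, depth and splitter")

    def __len__(self) -> int:
        return len(self.feature_subsets) * len(self.depths) * len(self.splitters)


@dataclass
class GridResult:
    """Outcome of the grid search."""

    best_config: TrainConfig
    best_subset: tuple[str, ...]
    best_objective: float
    report: list[dict] = field(default_factory=list)


def grid_search(
    X_full,
    y,
    feature_names: Sequence[str],
    grid: GridSpec,
    obj: ObjectiveConfig = ObjectiveConfig(),
    cv: CVConfig = CVConfig(),
    seed: int = 0,
) -> GridResult:
    """Exhaustive search over the grid, minimizing the human-machine objective
    on pooled out-of-fold predictions.

    Ties break deterministically: smaller depth first, then 'best' before
    'random', then the subset listed earlier in the grid.
    """
    X_full = np.asarray(X_full, dtype=float)
    y = np.asarray(y, dtype=int)
    name_to_col = {n: i for i, n in enumerate(feature_names)}
    report: list[dict] = []
    best: tuple[float, int, int, int] | None = None  # (f, depth, splitter_rank, subset_rank)
    best_entry: tuple[TrainConfig, tuple[str, ...], float] | None = None
    splitter_rank = {"best": 0, "random": 1}

    for si, subset in enumerate(grid.feature_subsets):
        missing = [n for n in subset if n not in name_to_col]
        if missing:
            raise InvalidInputError(f"unknown features in grid subset: {missing}")
        cols = [name_to_col[n] for n in subset]
        X = X_full[:, cols]
        for depth in grid.depths:
            for splitter in grid.splitters:
                cfg = TrainConfig(max_depth=depth, splitter=splitter, seed=seed)
                pred = cross_validate(X, y, cfg, cv)
                f = objective(y, pred, obj)
                report.append(
                    {
                        "features": list(subset),
                        "max_depth": depth,
                        "splitter": splitter,
                        "objective": f,
                    }
                )
                key = (f, depth, splitter_rank[splitter], si)
                if best is None or key < best:
                    best = key
                    best_entry = (cfg, tuple(subset), f)

    assert best_entry is not None
    return GridResult(
        best_config=best_entry[0],
        best_subset=best_entry[1],
        best_objective=best_entry[2],
        report=report,
    )
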