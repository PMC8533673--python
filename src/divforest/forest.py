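"""Forest fitting, probability aggregation and out-of-bag estimation.

Per-tree randomness is derived from the forest seed by a counter scheme:
tree ``t`` uses ``numpy.random.SeedSequence(seed, spawn_key=(t + 1,))`` and
the selector's one-off preparation (e.g. pair screening) uses spawn key
``(0,)``.  Fits are therefore reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .splitcore import NodeData
from .tree import GrowConfig, Tree, grow_tree, predict_tree


@dataclass
class Forest:
    """A fitted ensemble: trees, growth config and the training schema."""

    trees: list[Tree]
    config: GrowConfig
    n_features: int
    n_train: int
    seed: int

    @property
    def num_trees(self) -> int:
        return len(self.trees)


@dataclass
class OobEstimate:
    """Out-of-bag predictions and the derived error estimate.

    ``error`` is the misclassification rate at probability threshold 0.5
    over rows covered by at least one tree; ``brier`` is the OOB Brier
    score over the same rows.  Both are NaN when no row is covered.
    """

    per_row_probability: np.ndarray
    coverage: np.ndarray
    error: float
    brier: float

    @property
    def covered(self) -> np.ndarray:
        return self.coverage > 0


def _tree_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    config: GrowConfig,
    num_trees: int,
    seed: int | None = None,
) -> Forest:
    """Fit ``num_trees`` trees, each on an independent resample with an
    independent random stream derived from ``seed``."""
    if num_trees < 1:
        raise ValueError("num_trees must be >= 1")
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, p) and y of length n")
    if not np.isfinite(X).all():
        raise ValueError("X contains missing or non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("the outcome must contain both classes")
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    n = X.shape[0]
    config.selector.prepare(X, y, _tree_rng(seed, 0))
    trees: list[Tree] = []
    for t in range(num_trees):
        rng = _tree_rng(seed, t + 1)
        if config.resample_mode == "bootstrap":
            inbag = rng.integers(0, n, size=n)
        else:
            size = max(1, int(round(config.sample_fraction * n)))
            inbag = rng.choice(n, size=size, replace=False)
        trees.append(grow_tree(NodeData(X, y, inbag), config, rng))
    return Forest(trees=trees, config=config, n_features=X.shape[1], n_train=n, seed=seed)


def predict_forest(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Class-1 probabilities: the mean of the per-tree leaf probabilities."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != forest.n_features:
        raise ValueError(f"X must have {forest.n_features} columns")
    acc = np.zeros(X.shape[0])
    for tree in forest.trees:
        acc += predict_tree(tree, X)
    return acc / forest.num_trees


def oob_estimate(forest: Forest, X: np.ndarray, y: np.ndarray) -> OobEstimate:
    """Out-of-bag estimate on the forest's own training data.

    Each row's probability is averaged over the trees whose resample did not
    contain it.  Rows never out-of-bag are excluded from the error.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = X.shape[0]
    if n != forest.n_train or X.shape[1] != forest.n_features:
        raise ValueError("data shape does not match the forest's training schema")
    prob_sum = np.zeros(n)
    coverage = np.zeros(n, dtype=np.intp)
    for tree in forest.trees:
        oob = np.ones(n, dtype=bool)
        oob[tree.inbag] = False
        if not oob.any():
            continue
        prob_sum[oob] += predict_tree(tree, X[oob])
        coverage[oob] += 1
    covered = coverage > 0
    prob = np.full(n, np.nan)
    prob[covered] = prob_sum[covered] / coverage[covered]
    if covered.any():
        pred = (prob[covered] > 0.5).astype(np.int8)
        error = float((pred != y[covered]).mean())
        brier = float(((prob[covered] - y[covered]) ** 2).mean())
    else:
        error = float("nan")
        brier = float("nan")
    return OobEstimate(prob, coverage, error, brier)


def oob_error(
    forest: Forest, X: np.ndarray, y: np.ndarray, measure: str = "misclassification"
) -> float:
    """OOB prediction error under the chosen measure (used for tuning)."""
    est = oob_estimate(forest, X, y)
    if measure == "misclassification":
        return est.error
    if measure == "brier":
        return est.brier
    raise ValueError("measure must be 'misclassification' or 'brier'")
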