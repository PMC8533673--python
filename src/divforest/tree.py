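"""Single decision trees grown with a pluggable split selector."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairsplits import PairSplit, route_pair_split
from .selectors import Selector
from .splitcore import NodeData, Split


@dataclass
class GrowConfig:
    """Tree-growth configuration.

    ``resample_mode`` controls the per-tree resample drawn by the forest:
    ``"bootstrap"`` draws n observations with replacement, ``"subsample"``
    draws ``round(sample_fraction * n)`` without replacement.  Trees are
    grown to purity by default (``min_node_size = 1``, no depth cap); growth
    is additionally bounded by empty candidate sets and, for the df
    selector, the proptry small-node rule.
    """

    selector: Selector
    min_node_size: int = 1
    resample_mode: str = "bootstrap"
    sample_fraction: float = 0.632
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.resample_mode not in ("bootstrap", "subsample"):
            raise ValueError("resample_mode must be 'bootstrap' or 'subsample'")
        if not (0.0 < self.sample_fraction <= 1.0):
            raise ValueError("sample_fraction must lie in (0, 1]")


@dataclass
class TreeNode:
    """Internal node (split rule + two children) or leaf (class-1 fraction)."""

    prob: float
    n_node: int
    split: Split | PairSplit | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split is None


@dataclass
class Tree:
    """A grown tree plus the in-bag index multiset it was trained on."""

    root: TreeNode
    inbag: np.ndarray
    n_features: int

    def node_count(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += 1
            if not node.is_leaf:
                stack.append(node.left)
                stack.append(node.right)
        return count


def _left_mask(split: Split | PairSplit, values: np.ndarray) -> np.ndarray:
    if isinstance(split, PairSplit):
        return route_pair_split(split, values)
    return values[:, split.feature] <= split.threshold


def grow_tree(sample: NodeData, config: GrowConfig, rng: np.random.Generator) -> Tree:
    """Grow one tree on the given (already resampled) node data.

    Recursion stops at pure nodes, nodes below ``min_node_size`` (or of a
    single row), and nodes for which the selector yields no usable split.
    """
    selector = config.selector
    root_holder: list[TreeNode] = [None]  # type: ignore[list-item]
    # explicit stack instead of recursion: fully grown trees can be deep
    stack: list[tuple[NodeData, TreeNode | None, bool]] = [(sample, None, False)]
    while stack:
        node_data, parent, is_left = stack.pop()
        labels = node_data.labels
        m = labels.size
        n1 = int((labels == 1).sum())
        node = TreeNode(prob=n1 / m, n_node=m)
        if parent is None:
            root_holder[0] = node
        elif is_left:
            parent.left = node
        else:
            parent.right = node
        if m < 2 or m < config.min_node_size or n1 == 0 or n1 == m:
            continue
        split = selector.best_split(node_data, rng)
        if split is None:
            continue
        mask = _left_mask(split, node_data.values)
        if not mask.any() or mask.all():  # degenerate; selector should prevent this
            continue
        node.split = split
        # push right first so the left child is processed first (defined order)
        stack.append((node_data.child(~mask), node, False))
        stack.append((node_data.child(mask), node, True))
    return Tree(root=root_holder[0], inbag=np.asarray(sample.rows), n_features=sample.p)


def predict_tree(tree: Tree, x: np.ndarray) -> np.ndarray | float:
    """Class-1 probability for one point (1-D) or a matrix of points."""
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != tree.n_features:
        raise ValueError(
            f"expected {tree.n_features} features, got {X.shape[1]}"
        )
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature value in prediction input")
    out = np.empty(X.shape[0], dtype=np.float64)
    stack: list[tuple[TreeNode, np.ndarray]] = [(tree.root, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node.is_leaf:
            out[idx] = node.prob
            continue
        mask = _left_mask(node.split, X[idx])
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return float(out[0]) if single else out


def leaf_row_sets(tree: Tree, sample: NodeData) -> list[np.ndarray]:
    """Row-index sets of the in-bag sample falling into each leaf (used by
    invariant checks)."""
    out: list[np.ndarray] = []
    stack: list[tuple[TreeNode, NodeData]] = [(tree.root, sample)]
    while stack:
        node, data = stack.pop()
        if node.is_leaf:
            out.append(np.asarray(data.rows))
            continue
        mask = _left_mask(node.split, data.values)
        stack.append((node.left, data.child(mask)))
        stack.append((node.right, data.child(~mask)))
    return out
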