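"""Core split machinery: enumeration, counting, sampling and the Gini criterion.

A *split problem* is the set of all binary splits available in one feature at
the current node.  Diversity forests build their candidate split set by
repeatedly (i) sampling a split problem uniformly with replacement and
(ii) sampling one split uniformly from that problem.  The number of draws is
``nsplits``, reduced for small nodes by the ``proptry`` rule: when
``nsplits > proptry * total`` (``total`` being the number of all splits in
all features at the node), only ``floor(proptry * total)`` draws are made;
a reduction to zero makes the node terminal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Criterion value assigned to degenerate splits (an empty child); guarantees
#: such a split is never selected.
SENTINEL = -np.inf

# floating-point guard for proptry * total comparisons; proptry is a short
# decimal and total an integer, so the true product is rational and any
# representation error is far below this.
_EPS = 1e-9


class NodeData:
    """The rows of a tree's training sample that reach one node.

    Holds a reference to the full sample matrix plus an index vector, and
    caches the per-node derived quantities (column-sorted values, distinct
    counts, midpoint thresholds) that all selectors need.
    """

    __slots__ = ("X", "y", "rows", "_values", "_sorted", "_n_distinct", "_thr")

    def __init__(self, X: np.ndarray, y: np.ndarray, rows: np.ndarray | None = None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if rows is None:
            rows = np.arange(X.shape[0], dtype=np.intp)
        else:
            rows = np.asarray(rows, dtype=np.intp)
        if rows.size == 0:
            raise ValueError("a node must contain at least one row")
        self.X = X
        self.y = y
        self.rows = rows
        self._values: np.ndarray | None = None
        self._sorted: np.ndarray | None = None
        self._n_distinct: np.ndarray | None = None
        self._thr: dict[int, np.ndarray] = {}

    @property
    def n_rows(self) -> int:
        return self.rows.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Feature matrix restricted to the node's rows, shape (m, p)."""
        if self._values is None:
            self._values = self.X[self.rows]
        return self._values

    @property
    def labels(self) -> np.ndarray:
        return self.y[self.rows]

    @property
    def sorted_values(self) -> np.ndarray:
        if self._sorted is None:
            self._sorted = np.sort(self.values, axis=0)
        return self._sorted

    @property
    def distinct_counts(self) -> np.ndarray:
        """Number of distinct values of each feature within the node."""
        if self._n_distinct is None:
            s = self.sorted_values
            if s.shape[0] == 1:
                self._n_distinct = np.ones(self.p, dtype=np.intp)
            else:
                self._n_distinct = 1 + (np.diff(s, axis=0) != 0).sum(axis=0)
        return self._n_distinct

    def thresholds(self, feature: int) -> np.ndarray:
        """Node-local split points of one feature (cached)."""
        thr = self._thr.get(feature)
        if thr is None:
            thr = enumerate_thresholds(self.sorted_values[:, feature], assume_sorted=True)
            self._thr[feature] = thr
        return thr

    def child(self, mask: np.ndarray) -> "NodeData":
        """Sub-node containing the rows where ``mask`` is True."""
        return NodeData(self.X, self.y, self.rows[mask])


@dataclass(frozen=True)
class SplitProblem:
    """All binary splits in one feature at the current node."""

    feature: int


@dataclass
class Split:
    """A univariable binary split rule: ``value <= threshold`` goes left."""

    feature: int
    threshold: float
    criterion: float = math.nan


@dataclass(frozen=True)
class SamplingParams:
    """Diversity-forest candidate-sampling parameters."""

    nsplits: int = 30
    proptry: float = 1.0

    def __post_init__(self) -> None:
        if self.nsplits < 1:
            raise ValueError("nsplits must be >= 1")
        if not (0.0 < self.proptry <= 1.0):
            raise ValueError("proptry must lie in (0, 1]")


@dataclass
class CandidateSet:
    """An ordered collection of drawn candidate splits (duplicates allowed).

    Stored column-wise for vectorised evaluation; ``criteria`` is filled in
    lazily by :func:`select_best`.
    """

    features: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    thresholds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))
    criteria: np.ndarray | None = None

    def __len__(self) -> int:
        return self.features.size

    def to_splits(self) -> list[Split]:
        crit = self.criteria
        if crit is None:
            crit = np.full(len(self), math.nan)
        return [
            Split(int(f), float(t), float(c))
            for f, t, c in zip(self.features, self.thresholds, crit)
        ]


def enumerate_thresholds(values: np.ndarray, *, assume_sorted: bool = False) -> np.ndarray:
    """All split points of one feature: midpoints between consecutive
    distinct sorted values.  A constant vector yields an empty array."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if not assume_sorted:
        v = np.sort(v)
    distinct = v[np.r_[True, v[1:] != v[:-1]]]
    return (distinct[:-1] + distinct[1:]) / 2.0


def count_all_splits(node: NodeData) -> int:
    """Cardinality of ``allsplits`` at the node: the total number of distinct
    univariable binary splits over all features."""
    return int((node.distinct_counts - 1).sum())


def effective_nsplits(params: SamplingParams, total: int) -> int:
    """Number of candidate draws after the ``proptry`` reduction.

    Returns ``nsplits`` unless it exceeds ``proptry * total``, in which case
    ``floor(proptry * total)`` is returned; zero signals a terminal node.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    cap = params.proptry * total
    if params.nsplits <= cap + _EPS:
        return params.nsplits
    return int(math.floor(cap + _EPS))


def evaluate_candidates(
    node: NodeData, features: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Gini impurity decrease of each (feature, threshold) candidate at the
    node, vectorised.  Degenerate candidates (an empty child) get SENTINEL."""
    features = np.asarray(features, dtype=np.intp)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    m = node.n_rows
    left = node.values[:, features] <= thresholds
    y1 = node.labels == 1
    nl = left.sum(axis=0).astype(np.float64)
    n1l = left[y1].sum(axis=0).astype(np.float64) if y1.any() else np.zeros_like(nl)
    n1 = float(y1.sum())
    nr = m - nl
    n1r = n1 - n1l
    crit = np.full(features.size, SENTINEL)
    ok = (nl > 0) & (nr > 0)
    if ok.any():
        p1 = n1 / m
        g_parent = 2.0 * p1 * (1.0 - p1)
        with np.errstate(divide="ignore", invalid="ignore"):
            gl = 2.0 * (n1l / nl) * (1.0 - n1l / nl)
            gr = 2.0 * (n1r / nr) * (1.0 - n1r / nr)
            dec = g_parent - (nl / m) * gl - (nr / m) * gr
        # clip the tiny negatives that finite precision can produce
        crit[ok] = np.maximum(dec[ok], 0.0)
    return crit


def gini_decrease(split: Split, node: NodeData) -> float:
    """Gini impurity decrease of one split at the node (SENTINEL when a
    child is empty)."""
    return float(
        evaluate_candidates(
            node, np.array([split.feature]), np.array([split.threshold])
        )[0]
    )


def draw_candidates(
    node: NodeData, params: SamplingParams, rng: np.random.Generator
) -> CandidateSet:
    """Diversity-forest candidate drawing.

    Performs ``effective_nsplits`` draws; each samples a split problem
    (feature) uniformly with replacement over *all* features, then one split
    point uniformly from that feature's node-local thresholds.  Draws landing
    on a feature with no available split are re-drawn, with total attempts
    bounded by ten times the number of required draws.
    """
    total = count_all_splits(node)
    k = effective_nsplits(params, total)
    if k == 0 or total == 0:
        return CandidateSet()
    n_thr = node.distinct_counts - 1
    feats = np.empty(k, dtype=np.intp)
    filled = 0
    attempts = 0
    cap = 10 * k
    while filled < k and attempts < cap:
        draw = rng.integers(0, node.p, size=k - filled)
        attempts += draw.size
        ok = draw[n_thr[draw] > 0]
        take = min(ok.size, k - filled)
        feats[filled : filled + take] = ok[:take]
        filled += take
    feats = feats[:filled]
    if feats.size == 0:
        return CandidateSet()
    u = rng.random(feats.size)
    counts = n_thr[feats]
    idx = np.minimum((u * counts).astype(np.intp), counts - 1)
    thr = np.empty(feats.size, dtype=np.float64)
    for i, (f, j) in enumerate(zip(feats, idx)):
        thr[i] = node.thresholds(int(f))[j]
    return CandidateSet(features=feats, thresholds=thr)


def select_best(
    cand: CandidateSet, node: NodeData, rng: np.random.Generator
) -> Split | None:
    """Best candidate by Gini decrease; ties broken uniformly at random.

    Returns ``None`` for an empty set or when every candidate is degenerate.
    """
    if len(cand) == 0:
        return None
    if cand.criteria is None:
        cand.criteria = evaluate_candidates(node, cand.features, cand.thresholds)
    best = cand.criteria.max()
    if best == SENTINEL:
        return None
    ties = np.flatnonzero(cand.criteria == best)
    i = ties[0] if ties.size == 1 else ties[int(rng.integers(ties.size))]
    return Split(int(cand.features[i]), float(cand.thresholds[i]), float(best))
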