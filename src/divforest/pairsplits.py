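"""Bivariable splitting for interaction forests.

Each split problem is a feature pair (j1, j2) offering seven split types:
two univariable splits (one per member) and five bivariable splits that all
share one split-point pair (pb1, pb2).  Four bivariable types partition the
plane into one quadrant versus the rest ("quantitative" interactions); the
fifth separates the two diagonal quadrants from the two off-diagonal ones
("qualitative" interactions, e.g. XOR-type signal).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .splitcore import SENTINEL, NodeData

#: Split-type tags.  QUANT_xy: left child is the quadrant where j1 is on
#: side x and j2 on side y (L = "<= point", U = "> point").
UNIV_J1 = "UNIV_J1"
UNIV_J2 = "UNIV_J2"
QUANT_LL = "QUANT_LL"
QUANT_LU = "QUANT_LU"
QUANT_UL = "QUANT_UL"
QUANT_UU = "QUANT_UU"
QUAL = "QUAL"

PAIR_SPLIT_TYPES = (UNIV_J1, UNIV_J2, QUANT_LL, QUANT_LU, QUANT_UL, QUANT_UU, QUAL)
_BIVARIABLE = frozenset({QUANT_LL, QUANT_LU, QUANT_UL, QUANT_UU, QUAL})


@dataclass(frozen=True)
class PairSplitProblem:
    """All univariable and bivariable splits of the seven types in one
    feature pair."""

    j1: int
    j2: int

    def __post_init__(self) -> None:
        if self.j1 == self.j2:
            raise ValueError("a pair split problem needs two distinct features")


@dataclass
class PairSplit:
    """One drawn split of a pair split problem.

    ``point1``/``point2`` are the split points on j1/j2: for UNIV_J1 only
    ``point1`` is meaningful, for UNIV_J2 only ``point2``; every bivariable
    type uses both (the shared pair (pb1, pb2)).
    """

    type: str
    j1: int
    j2: int
    point1: float = math.nan
    point2: float = math.nan
    criterion: float = math.nan

    def __post_init__(self) -> None:
        if self.type not in PAIR_SPLIT_TYPES:
            raise ValueError(f"unknown pair split type: {self.type}")


@dataclass(frozen=True)
class PairCaps:
    """Caps bounding the interaction-forest candidate sets.

    With the defaults, at most 10 split problems are sampled per node and 7
    splits drawn per problem, so at most 70 candidate splits are evaluated
    at any node.  For data with more than ``screening_threshold_p`` features,
    only ``max_screened_pairs`` pre-screened pairs are eligible.
    """

    max_problems_per_node: int = 10
    splits_per_problem: int = 7
    max_screened_pairs: int = 5000
    screening_threshold_p: int = 100

    def __post_init__(self) -> None:
        if self.max_problems_per_node < 1 or self.max_screened_pairs < 1:
            raise ValueError("caps must be positive")


def draw_pair_splits(
    node: NodeData, pair: PairSplitProblem, rng: np.random.Generator
) -> list[PairSplit]:
    """Sample one split of each feasible type from the pair split problem.

    When both features are splittable this yields exactly seven splits, the
    five bivariable ones sharing a single (pb1, pb2) drawn uniformly from
    the node-local thresholds of each member.  A constant member removes the
    bivariable types and its own univariable type.
    """
    thr1 = node.thresholds(pair.j1)
    thr2 = node.thresholds(pair.j2)
    j1, j2 = pair.j1, pair.j2
    if thr1.size == 0 and thr2.size == 0:
        return []
    if thr1.size == 0:
        pu2 = float(thr2[rng.integers(thr2.size)])
        return [PairSplit(UNIV_J2, j1, j2, point2=pu2)]
    if thr2.size == 0:
        pu1 = float(thr1[rng.integers(thr1.size)])
        return [PairSplit(UNIV_J1, j1, j2, point1=pu1)]
    pu1 = float(thr1[rng.integers(thr1.size)])
    pu2 = float(thr2[rng.integers(thr2.size)])
    pb1 = float(thr1[rng.integers(thr1.size)])
    pb2 = float(thr2[rng.integers(thr2.size)])
    out = [
        PairSplit(UNIV_J1, j1, j2, point1=pu1),
        PairSplit(UNIV_J2, j1, j2, point2=pu2),
    ]
    for t in (QUANT_LL, QUANT_LU, QUANT_UL, QUANT_UU, QUAL):
        out.append(PairSplit(t, j1, j2, point1=pb1, point2=pb2))
    return out


def route_pair_split(split: PairSplit, x: np.ndarray) -> np.ndarray | bool:
    """Left-child membership for one point (1-D x) or a matrix of points.

    Left regions: UNIV_* — the named coordinate <= its point; QUANT_xy — the
    single quadrant; QUAL — the union of the lower-left and upper-right
    quadrants (the diagonal).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = x[None, :] if single else x
    a = X[:, split.j1] <= split.point1
    b = X[:, split.j2] <= split.point2
    t = split.type
    if t == UNIV_J1:
        left = a
    elif t == UNIV_J2:
        left = b
    elif t == QUANT_LL:
        left = a & b
    elif t == QUANT_LU:
        left = a & ~b
    elif t == QUANT_UL:
        left = ~a & b
    elif t == QUANT_UU:
        left = ~a & ~b
    else:  # QUAL
        left = a == b
    return bool(left[0]) if single else left


def evaluate_pair_splits(node: NodeData, splits: list[PairSplit]) -> np.ndarray:
    """Gini decrease of each pair split at the node; degenerate splits get
    SENTINEL.  Criteria are also written back onto the split objects."""
    m = node.n_rows
    y1 = node.labels == 1
    n1 = float(y1.sum())
    p1 = n1 / m
    g_parent = 2.0 * p1 * (1.0 - p1)
    crit = np.empty(len(splits))
    V = node.values
    for i, s in enumerate(splits):
        left = route_pair_split(s, V)
        nl = int(left.sum())
        nr = m - nl
        if nl == 0 or nr == 0:
            crit[i] = SENTINEL
        else:
            n1l = float((left & y1).sum())
            n1r = n1 - n1l
            gl = 2.0 * (n1l / nl) * (1.0 - n1l / nl)
            gr = 2.0 * (n1r / nr) * (1.0 - n1r / nr)
            crit[i] = max(g_parent - (nl / m) * gl - (nr / m) * gr, 0.0)
        s.criterion = float(crit[i])
    return crit


def pair_node_candidates(
    node: NodeData,
    eligible_pairs: list[PairSplitProblem],
    caps: PairCaps,
    rng: np.random.Generator,
) -> list[PairSplit]:
    """Candidate splits for one node of an interaction forest.

    Samples ``min(max_problems_per_node, #eligible)`` split problems with
    replacement and concatenates their drawn splits; the result never
    exceeds ``max_problems_per_node * splits_per_problem`` candidates.
    """
    if not eligible_pairs:
        raise ValueError("eligible_pairs must be non-empty")
    n_problems = min(caps.max_problems_per_node, len(eligible_pairs))
    idx = rng.integers(0, len(eligible_pairs), size=n_problems)
    out: list[PairSplit] = []
    for i in idx:
        out.extend(draw_pair_splits(node, eligible_pairs[int(i)], rng))
    return out


def interaction_scores(
    X: np.ndarray, y: np.ndarray, n_grid: int = 3
) -> np.ndarray:
    """Screening score for every feature pair: interaction-specific signal.

    For each pair, the best Gini decrease of a QUAL (diagonal) split over a
    coarse ``n_grid`` x ``n_grid`` quantile grid, minus the best univariable
    Gini decrease of either member on its grid points.  Computed for all
    pairs at once via indicator-matrix products.  Returns a (p, p) symmetric
    matrix (diagonal = -inf).
    """
    X = np.asarray(X, dtype=np.float64)
    y1 = np.asarray(y) == 1
    n, p = X.shape
    qs = (np.arange(n_grid) + 1.0) / (n_grid + 1.0)
    cuts = np.quantile(X, qs, axis=0)  # (g, p)
    # indicator matrix: column (j, g) is 1[x_j <= cut_{g, j}]
    B = (X[:, :, None] <= cuts.T[None, :, :]).reshape(n, p * n_grid).astype(np.float64)
    s = B.sum(axis=0)  # <= counts per column
    s1 = B[y1].sum(axis=0)
    n1 = float(y1.sum())
    g_parent = 2.0 * (n1 / n) * (1.0 - n1 / n)

    def _dec(nl, n1l):
        nl = np.asarray(nl, dtype=np.float64)
        n1l = np.asarray(n1l, dtype=np.float64)
        nr = n - nl
        n1r = n1 - n1l
        with np.errstate(divide="ignore", invalid="ignore"):
            gl = 2.0 * (n1l / nl) * (1.0 - n1l / nl)
            gr = 2.0 * (n1r / nr) * (1.0 - n1r / nr)
            dec = g_parent - (nl / n) * gl - (nr / n) * gr
        dec = np.where((nl > 0) & (nr > 0), dec, -np.inf)
        return dec

    # best univariable decrease per feature over its grid cuts
    univ = _dec(s, s1).reshape(p, n_grid).max(axis=1)

    # QUAL left count for column pair (a, b): #\{B_a == B_b\} = n - s_a - s_b + 2 E_ab
    E = B.T @ B
    E1 = (B * y1[:, None]).T @ B
    nl = n - s[:, None] - s[None, :] + 2.0 * E
    n1l = n1 - s1[:, None] - s1[None, :] + 2.0 * E1
    qual = _dec(nl, n1l)  # (p*g, p*g)
    qual_pair = qual.reshape(p, n_grid, p, n_grid).max(axis=(1, 3))
    score = qual_pair - np.maximum(univ[:, None], univ[None, :])
    np.fill_diagonal(score, -np.inf)
    return score


def screen_pairs(
    X: np.ndarray,
    y: np.ndarray,
    caps: PairCaps = PairCaps(),
    rng: np.random.Generator | None = None,
) -> list[PairSplitProblem]:
    """Eligible feature pairs for an interaction forest.

    All pairs when ``p <= screening_threshold_p``; otherwise the
    ``max_screened_pairs`` pairs with the strongest interaction-screening
    score (deterministic; ties resolved by pair order).
    """
    X = np.asarray(X, dtype=np.float64)
    p = X.shape[1]
    if p < 2:
        raise ValueError("pair splitting needs at least two features")
    all_pairs = [PairSplitProblem(a, b) for a, b in itertools.combinations(range(p), 2)]
    if p <= caps.screening_threshold_p or len(all_pairs) <= caps.max_screened_pairs:
        return all_pairs
    score = interaction_scores(X, y)
    iu = np.triu_indices(p, k=1)
    vals = score[iu]
    # stable top-k: sort by (-score, pair order)
    order = np.lexsort((np.arange(vals.size), -vals))[: caps.max_screened_pairs]
    order.sort()  # keep deterministic pair ordering in the output
    return [PairSplitProblem(int(iu[0][i]), int(iu[1][i])) for i in order]
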