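"""Interchangeable node-splitting policies.

Four selectors are provided:

* ``df``   — diversity-forest split sampling (split problems drawn with
  replacement, one split per draw, ``nsplits``/``proptry`` control);
* ``rf``   — conventional random-forest selection (``mtry`` features without
  replacement, every threshold of each considered);
* ``extr`` — extremely-randomized-trees selection (``mtry`` features without
  replacement, ``k`` continuous-uniform cut-points per feature);
* ``pair`` — the interaction-forest bivariable procedure (seven splits per
  sampled feature pair).

``extr`` with ``k=1`` is the classical extra-trees rule; ``k=5`` is the
five-cut-point variant.  DF cut-points are uniform over the node-local
midpoint thresholds, while ``extr`` cut-points are continuous-uniform on the
node-local (min, max) range — the two sampling laws are deliberately kept
distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pairsplits as ps
from . import splitcore as sc
from .splitcore import CandidateSet, NodeData, SamplingParams, Split


def rf_candidates(node: NodeData, mtry: int, rng: np.random.Generator) -> CandidateSet:
    """Conventional RF candidate set: sample ``mtry`` features without
    replacement and take every node-local threshold of each."""
    if not 1 <= mtry <= node.p:
        raise ValueError("mtry must lie in [1, p]")
    feats = rng.choice(node.p, size=mtry, replace=False)
    f_out: list[np.ndarray] = []
    t_out: list[np.ndarray] = []
    for f in feats:
        thr = node.thresholds(int(f))
        if thr.size:
            f_out.append(np.full(thr.size, f, dtype=np.intp))
            t_out.append(thr)
    if not f_out:
        return CandidateSet()
    return CandidateSet(np.concatenate(f_out), np.concatenate(t_out))


def extr_candidates(
    node: NodeData, mtry: int, k: int, rng: np.random.Generator
) -> CandidateSet:
    """Extra-trees candidate set: ``mtry`` features without replacement,
    ``k`` cut-points per feature drawn uniformly from the node-local
    (min, max) range; constant features contribute nothing."""
    if not 1 <= mtry <= node.p:
        raise ValueError("mtry must lie in [1, p]")
    if k < 1:
        raise ValueError("k must be >= 1")
    feats = rng.choice(node.p, size=mtry, replace=False)
    s = node.sorted_values
    lo = s[0, feats]
    hi = s[-1, feats]
    ok = hi > lo
    u = rng.random((mtry, k))
    if not ok.any():
        return CandidateSet()
    cuts = lo[ok, None] + u[ok] * (hi[ok] - lo[ok])[:, None]
    f_rep = np.repeat(feats[ok].astype(np.intp), k)
    return CandidateSet(f_rep, cuts.ravel())


class Selector:
    """Base class: a node-splitting policy usable by the tree grower."""

    kind: str = "?"

    def prepare(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> None:
        """Hook run once per forest fit, before any tree is grown."""

    def best_split(self, node: NodeData, rng: np.random.Generator):
        raise NotImplementedError

    def to_config(self) -> dict:
        raise NotImplementedError


@dataclass
class DFSelector(Selector):
    """Diversity-forest split sampling."""

    params: SamplingParams = field(default_factory=SamplingParams)
    kind = "df"

    def best_split(self, node: NodeData, rng: np.random.Generator) -> Split | None:
        cand = sc.draw_candidates(node, self.params, rng)
        return sc.select_best(cand, node, rng)

    def to_config(self) -> dict:
        return {
            "kind": "df",
            "nsplits": self.params.nsplits,
            "proptry": self.params.proptry,
        }


@dataclass
class RFSelector(Selector):
    """Conventional random-forest split selection."""

    mtry: int
    kind = "rf"

    def best_split(self, node: NodeData, rng: np.random.Generator) -> Split | None:
        cand = rf_candidates(node, min(self.mtry, node.p), rng)
        return sc.select_best(cand, node, rng)

    def to_config(self) -> dict:
        return {"kind": "rf", "mtry": self.mtry}


@dataclass
class ExtrSelector(Selector):
    """Extremely-randomized-trees split selection with ``k`` cut-points."""

    mtry: int
    k: int = 1
    kind = "extr"

    def best_split(self, node: NodeData, rng: np.random.Generator) -> Split | None:
        cand = extr_candidates(node, min(self.mtry, node.p), self.k, rng)
        return sc.select_best(cand, node, rng)

    def to_config(self) -> dict:
        return {"kind": "extr", "mtry": self.mtry, "k": self.k}


@dataclass
class PairSelector(Selector):
    """Interaction-forest bivariable split selection.

    Eligible pairs are determined once per fit by :func:`pairsplits
    .screen_pairs` (all pairs for small p, screened top pairs otherwise)
    unless an explicit pair list is supplied.
    """

    caps: ps.PairCaps = field(default_factory=ps.PairCaps)
    pairs: list[ps.PairSplitProblem] | None = None
    kind = "pair"

    def prepare(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> None:
        if self.pairs is None:
            self.pairs = ps.screen_pairs(X, y, self.caps, rng)

    def best_split(self, node: NodeData, rng: np.random.Generator) -> ps.PairSplit | None:
        if self.pairs is None:
            raise RuntimeError("PairSelector.prepare was never called")
        cand = ps.pair_node_candidates(node, self.pairs, self.caps, rng)
        if not cand:
            return None
        crit = ps.evaluate_pair_splits(node, cand)
        best = crit.max()
        if best == sc.SENTINEL:
            return None
        ties = np.flatnonzero(crit == best)
        i = ties[0] if ties.size == 1 else ties[int(rng.integers(ties.size))]
        return cand[int(i)]

    def to_config(self) -> dict:
        cfg = {
            "kind": "pair",
            "max_problems_per_node": self.caps.max_problems_per_node,
            "max_screened_pairs": self.caps.max_screened_pairs,
            "screening_threshold_p": self.caps.screening_threshold_p,
        }
        if self.pairs is not None:
            cfg["pairs"] = [[p.j1, p.j2] for p in self.pairs]
        return cfg


def selector_from_config(cfg: dict) -> Selector:
    """Rebuild a selector from its ``to_config`` dictionary."""
    kind = cfg["kind"]
    if kind == "df":
        return DFSelector(SamplingParams(cfg["nsplits"], cfg["proptry"]))
    if kind == "rf":
        return RFSelector(cfg["mtry"])
    if kind == "extr":
        return ExtrSelector(cfg["mtry"], cfg.get("k", 1))
    if kind == "pair":
        caps = ps.PairCaps(
            max_problems_per_node=cfg.get("max_problems_per_node", 10),
            max_screened_pairs=cfg.get("max_screened_pairs", 5000),
            screening_threshold_p=cfg.get("screening_threshold_p", 100),
        )
        pairs = cfg.get("pairs")
        sel = PairSelector(caps)
        if pairs is not None:
            sel.pairs = [ps.PairSplitProblem(int(a), int(b)) for a, b in pairs]
        return sel
    raise ValueError(f"unknown selector kind: {kind}")
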