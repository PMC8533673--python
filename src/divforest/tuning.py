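"""Out-of-bag hyperparameter tuning.

Each candidate setting gets its own forest of ``trees_per_candidate`` trees;
the setting with the smallest OOB prediction error wins (ties resolved in
grid order) and a final forest of ``final_trees`` trees is refit at the
winner.  The recommended diversity-forest protocol fixes ``nsplits = 30``
and chooses ``proptry`` from {0.05, 1} by OOB error; for conventional RF
and extra-trees variants, ``mtry`` is tuned on a grid of at most 20 values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import Forest, fit_forest, oob_error
from .selectors import DFSelector, ExtrSelector, PairSelector, RFSelector, Selector
from .splitcore import SamplingParams
from .tree import GrowConfig

#: The dense pre-study grids for nsplits and proptry (sensitivity studies).
PRESTUDY_NSPLITS = (2, 5, 10, 30, 50, 100, 200)
PRESTUDY_PROPTRY = (0.01, 0.05, 0.1, 0.3, 0.5, 0.8, 1)


@dataclass
class TuningPlan:
    """A tuning protocol: method, candidate grid and tree counts."""

    method: str  # df | rf | extr | pair
    grid: list[dict]
    trees_per_candidate: int = 1000
    final_trees: int = 2000
    oob_measure: str = "misclassification"
    min_node_size: int = 1
    resample_mode: str = "bootstrap"
    sample_fraction: float = 0.632

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("the tuning grid must be non-empty")
        if self.method not in ("df", "rf", "extr", "pair"):
            raise ValueError(f"unknown method: {self.method}")


@dataclass
class TuningResult:
    best_setting: dict
    forest: Forest
    table: pd.DataFrame  # columns: setting index, parameters, oob_error, selected


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_mtry_grid(p: int) -> list[int]:
    """mtry tuning grid: every value 1..p when p <= 20, otherwise the
    rounded geometric-like ladder ``{[i^(log p / log 20)] : i = 1..20}``
    (deduplicated, ascending; first element 1, last element p)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if p <= 20:
        return list(range(1, p + 1))
    expo = math.log(p) / math.log(20)
    vals = sorted({_round_half_away(i**expo) for i in range(1, 21)})
    return [min(max(v, 1), p) for v in vals]


def default_df_grid(
    trees_per_candidate: int = 1000, final_trees: int = 2000
) -> TuningPlan:
    """The recommended diversity-forest plan: nsplits fixed at 30, proptry
    chosen from {0.05, 1} by OOB error."""
    return TuningPlan(
        method="df",
        grid=[{"nsplits": 30, "proptry": 0.05}, {"nsplits": 30, "proptry": 1.0}],
        trees_per_candidate=trees_per_candidate,
        final_trees=final_trees,
    )


def prestudy_df_grid() -> list[dict]:
    """The dense 7 x 7 (nsplits, proptry) grid used for sensitivity studies."""
    return [
        {"nsplits": ns, "proptry": float(pt)}
        for ns in PRESTUDY_NSPLITS
        for pt in PRESTUDY_PROPTRY
    ]


def default_mtry_plan(
    method: str,
    p: int,
    k: int = 1,
    trees_per_candidate: int = 1000,
    final_trees: int = 2000,
) -> TuningPlan:
    """mtry tuning plan for ``rf`` or ``extr`` on ``p`` features."""
    if method == "rf":
        grid = [{"mtry": m} for m in build_mtry_grid(p)]
    elif method == "extr":
        grid = [{"mtry": m, "k": k} for m in build_mtry_grid(p)]
    else:
        raise ValueError("default_mtry_plan supports methods 'rf' and 'extr'")
    return TuningPlan(method, grid, trees_per_candidate, final_trees)


def selector_for_setting(method: str, setting: dict) -> Selector:
    if method == "df":
        return DFSelector(SamplingParams(setting["nsplits"], setting["proptry"]))
    if method == "rf":
        return RFSelector(setting["mtry"])
    if method == "extr":
        return ExtrSelector(setting["mtry"], setting.get("k", 1))
    if method == "pair":
        return PairSelector()
    raise ValueError(f"unknown method: {method}")


def tune_by_oob(
    X: np.ndarray, y: np.ndarray, plan: TuningPlan, seed: int = 0
) -> TuningResult:
    """Fit one candidate forest per grid setting, pick the OOB-best setting
    and refit the final forest there.

    Candidate forests are independent (no tree reuse); reproducible given
    ``seed``, including tie resolution (first setting in grid order wins).
    """
    errors: list[float] = []
    for i, setting in enumerate(plan.grid):
        cfg = GrowConfig(
            selector=selector_for_setting(plan.method, setting),
            min_node_size=plan.min_node_size,
            resample_mode=plan.resample_mode,
            sample_fraction=plan.sample_fraction,
        )
        forest = fit_forest(X, y, cfg, plan.trees_per_candidate, seed=_setting_seed(seed, i))
        errors.append(oob_error(forest, X, y, plan.oob_measure))
    best_i = int(np.nanargmin(errors))  # ties: first occurrence in grid order
    best = plan.grid[best_i]
    final_cfg = GrowConfig(
        selector=selector_for_setting(plan.method, best),
        min_node_size=plan.min_node_size,
        resample_mode=plan.resample_mode,
        sample_fraction=plan.sample_fraction,
    )
    final = fit_forest(X, y, final_cfg, plan.final_trees, seed=seed)
    table = pd.DataFrame(
        {
            "setting": [repr(s) for s in plan.grid],
            "oob_error": errors,
            "selected": [i == best_i for i in range(len(plan.grid))],
        }
    )
    return TuningResult(best_setting=dict(best), forest=final, table=table)


def _setting_seed(seed: int, index: int) -> int:
    # distinct, reproducible stream per candidate setting
    return int(
        np.random.SeedSequence(seed, spawn_key=(1000 + index,)).generate_state(1)[0]
        % (2**31)
    )
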