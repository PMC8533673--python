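"""Evaluation protocol: repeated stratified cross-validation, the three
performance measures (ACC, AUC, Brier), cross-dataset quartile summaries and
paired Wilcoxon signed-rank comparisons.

Per dataset and method, each CV repetition pools the held-out predictions of
its folds and computes each measure once; per-dataset values are the mean
over repetitions; quartiles are then taken across datasets (type-7, linear
interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, brier_score_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .data import Dataset
from .forest import predict_forest
from .tuning import TuningPlan, tune_by_oob

MEASURES = ("acc", "auc", "brier")


@dataclass
class CvPlan:
    """Stratified k-fold cross-validation repeated ``repetitions`` times."""

    folds: int = 5
    repetitions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class BenchmarkResult:
    """Long-format per-(dataset, method, repetition, measure) values."""

    table: pd.DataFrame

    def per_dataset(self) -> pd.DataFrame:
        """Mean over CV repetitions: one value per dataset/method/measure."""
        return (
            self.table.groupby(["dataset", "method", "measure"], sort=False)["value"]
            .mean()
            .reset_index()
        )

    def summarize_quartiles(self) -> pd.DataFrame:
        return summarize_quartiles(self)

    def paired_tests(self, baseline: str) -> pd.DataFrame:
        """Wilcoxon signed-rank of every method against ``baseline``, per
        measure, over per-dataset values."""
        per = self.per_dataset()
        rows = []
        for method in per["method"].unique():
            if method == baseline:
                continue
            for measure in per["measure"].unique():
                a = per.query("method == @method and measure == @measure")
                b = per.query("method == @baseline and measure == @measure")
                merged = a.merge(b, on="dataset", suffixes=("_a", "_b"))
                p, r = paired_compare(
                    merged["value_a"].to_numpy(), merged["value_b"].to_numpy()
                )
                rows.append(
                    {
                        "method": method,
                        "baseline": baseline,
                        "measure": measure,
                        "p_value": p,
                        "effect_size_r": r,
                    }
                )
        return pd.DataFrame(rows)


def stratified_folds(labels: np.ndarray, plan: CvPlan) -> list[np.ndarray]:
    """Fold assignments (one integer array per repetition).

    Each repetition partitions the rows into ``plan.folds`` groups whose
    class counts deviate from perfect proportionality by less than one
    observation; repetitions use fresh shuffles derived from the seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < plan.folds:
        raise ValueError(
            f"the smaller class has {counts.min()} members; needs >= {plan.folds}"
        )
    out = []
    for rep in range(plan.repetitions):
        state = int(
            np.random.SeedSequence(plan.seed, spawn_key=(rep,)).generate_state(1)[0]
            % (2**31)
        )
        skf = StratifiedKFold(n_splits=plan.folds, shuffle=True, random_state=state)
        assign = np.empty(labels.size, dtype=np.intp)
        for k, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
            assign[test_idx] = k
        out.append(assign)
    return out


def metric_acc(labels: np.ndarray, probabilities: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of correct class assignments at the probability threshold."""
    pred = (np.asarray(probabilities) > threshold).astype(int)
    return float(accuracy_score(labels, pred))


def metric_auc(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC is undefined for single-class labels")
    return float(roc_auc_score(labels, probabilities))


def metric_brier(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean squared difference between probability and the 0/1 label."""
    return float(brier_score_loss(labels, probabilities))


def paired_compare(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-dataset values.

    Zero differences are dropped and ties mid-ranked; the null is exact for
    up to 25 non-zero pairs and a continuity-corrected normal approximation
    beyond.  Returns (p-value, effect size r = |Z| / sqrt(N)) with N the
    number of non-zero pairs.  All-zero differences give (1, 0).
    """
    d = np.asarray(values_a, dtype=np.float64) - np.asarray(values_b, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0, 0.0
    method = "exact" if n <= 25 else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, method=method)
    p = float(res.pvalue)
    # effect size from the normal approximation of the signed-rank statistic
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = 0.0 if var == 0 else (w_plus - mu) / np.sqrt(var)
    r = abs(z) / np.sqrt(n)
    return p, float(r)


def summarize_quartiles(results: BenchmarkResult) -> pd.DataFrame:
    """Q1/median/Q3 per method and measure across datasets (repetition
    means first, then type-7 quantiles)."""
    per = results.per_dataset()
    rows = []
    for (method, measure), grp in per.groupby(["method", "measure"], sort=False):
        q1, med, q3 = np.quantile(grp["value"].to_numpy(), [0.25, 0.5, 0.75])
        rows.append(
            {"method": method, "measure": measure, "q1": q1, "median": med, "q3": q3}
        )
    return pd.DataFrame(rows)


def run_benchmark(
    datasets: dict[str, Dataset],
    methods: dict[str, TuningPlan],
    cv: CvPlan,
) -> BenchmarkResult:
    """Run the full protocol: per dataset, method and CV repetition, tune on
    each training split by OOB error, predict the held-out fold, pool the
    predictions of the repetition and compute ACC, AUC and Brier."""
    rows = []
    for ds_name, ds in datasets.items():
        fold_sets = stratified_folds(ds.y, cv)
        for method_name, plan in methods.items():
            for rep, assign in enumerate(fold_sets):
                probs = np.empty(ds.n)
                for k in range(cv.folds):
                    test = assign == k
                    train = ~test
                    res = tune_by_oob(
                        ds.X[train],
                        ds.y[train],
                        plan,
                        seed=_fold_seed(cv.seed, ds_name, method_name, rep, k),
                    )
                    probs[test] = predict_forest(res.forest, ds.X[test])
                values = {
                    "acc": metric_acc(ds.y, probs),
                    "auc": metric_auc(ds.y, probs),
                    "brier": metric_brier(ds.y, probs),
                }
                for measure, value in values.items():
                    rows.append(
                        {
                            "dataset": ds_name,
                            "method": method_name,
                            "repetition": rep,
                            "measure": measure,
                            "value": value,
                        }
                    )
    return BenchmarkResult(table=pd.DataFrame(rows))


def _fold_seed(seed: int, dataset: str, method: str, rep: int, fold: int) -> int:
    key = f"{dataset}|{method}|{rep}|{fold}".encode()
    ent = int.from_bytes(key.ljust(16, b"\0")[:16], "little")
    return int(
        np.random.SeedSequence([seed, ent]).generate_state(1)[0] % (2**31)
    )
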