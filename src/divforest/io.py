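"""Dataset loading (CSV / OpenML-dialect ARFF) and model persistence.

Loading rules: numeric columns pass through; categorical columns are
integer-encoded by ascending class-1 frequency of their categories (so the
univariable ordered-split machinery remains meaningful); the binary label is
mapped to {0, 1} by the configured positive class; missing values are
rejected with the offending column and row named.

Models are persisted as a versioned JSON document with a bit-exact
round-trip: probabilities, thresholds and in-bag records are preserved
exactly (Python's JSON float encoding round-trips IEEE doubles).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

from .data import Dataset
from .forest import Forest
from .pairsplits import PairSplit
from .selectors import selector_from_config
from .splitcore import Split
from .tree import GrowConfig, Tree, TreeNode

MODEL_FORMAT = "divforest-model"
MODEL_VERSION = 1


@dataclass
class DatasetOnDisk:
    """Where and how a dataset is stored."""

    path: str | Path
    format: str | None = None  # csv | arff; inferred from the suffix if None
    label_column: str = "label"
    positive_class: object | None = None


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".arff":
        return "arff"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def _read_frame(spec: DatasetOnDisk) -> pd.DataFrame:
    path = Path(spec.path)
    fmt = _infer_format(path, spec.format)
    if fmt == "csv":
        return pd.read_csv(path)
    if fmt == "arff":
        data, _meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:  # nominal attributes arrive as bytes
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
        return df
    raise ValueError(f"unknown format: {fmt}")


def _check_missing(df: pd.DataFrame) -> None:
    mask = df.isna()
    if df.select_dtypes(include=object).size:
        mask |= df.apply(lambda c: c == "?" if c.dtype == object else np.zeros(len(c), bool))
    if mask.to_numpy().any():
        col = mask.any(axis=0).idxmax()
        row = int(mask[col].idxmax())
        raise ValueError(f"missing value in column {col!r}, row {row}")


def encode_categorical(values: pd.Series, y: np.ndarray) -> np.ndarray:
    """Integer-encode a categorical column by ascending class-1 frequency of
    its categories (ties broken by category value)."""
    frame = pd.DataFrame({"v": values.astype(str), "y": y})
    freq = frame.groupby("v")["y"].mean().sort_values(kind="stable")
    order = sorted(freq.index, key=lambda c: (freq[c], c))
    mapping = {c: i for i, c in enumerate(order)}
    return frame["v"].map(mapping).to_numpy(dtype=np.float64)


def load_dataset(spec: DatasetOnDisk | str | Path) -> Dataset:
    """Load a delimited-text or ARFF dataset into the in-memory form."""
    if not isinstance(spec, DatasetOnDisk):
        spec = DatasetOnDisk(path=spec)
    df = _read_frame(spec)
    if spec.label_column not in df.columns:
        raise ValueError(
            f"label column {spec.label_column!r} not found; columns: {list(df.columns)}"
        )
    _check_missing(df)
    raw_labels = df[spec.label_column]
    observed = sorted(raw_labels.astype(str).unique())
    if len(observed) != 2:
        raise ValueError(f"label column must be binary; observed values: {observed}")
    pos = str(spec.positive_class) if spec.positive_class is not None else observed[-1]
    if pos not in observed:
        raise ValueError(f"positive_class {pos!r} not among observed labels {observed}")
    y = (raw_labels.astype(str) == pos).to_numpy().astype(np.int8)
    features = df.drop(columns=[spec.label_column])
    cols = []
    for name in features.columns:
        col = features[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            cols.append(encode_categorical(col, y))
        else:
            cols.append(col.to_numpy(dtype=np.float64))
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return Dataset(
        X, y, [str(c) for c in features.columns],
        meta={"source": str(spec.path), "positive_class": pos},
    )


# --- model persistence -----------------------------------------------------


def _split_to_doc(split: Split | PairSplit) -> dict:
    if isinstance(split, PairSplit):
        return {
            "kind": "pair",
            "type": split.type,
            "j1": split.j1,
            "j2": split.j2,
            "point1": split.point1,
            "point2": split.point2,
            "criterion": split.criterion,
        }
    return {
        "kind": "univ",
        "feature": split.feature,
        "threshold": split.threshold,
        "criterion": split.criterion,
    }


def _split_from_doc(doc: dict) -> Split | PairSplit:
    if doc["kind"] == "pair":
        return PairSplit(
            doc["type"], doc["j1"], doc["j2"], doc["point1"], doc["point2"],
            doc.get("criterion", math.nan),
        )
    return Split(doc["feature"], doc["threshold"], doc.get("criterion", math.nan))


def _tree_to_doc(tree: Tree) -> dict:
    # flat node table (iterative: fully grown trees can be deep)
    nodes: list[dict] = []
    order: list[TreeNode] = []
    index: dict[int, int] = {}
    work = [tree.root]
    while work:
        node = work.pop()
        index[id(node)] = len(order)
        order.append(node)
        if not node.is_leaf:
            work.append(node.right)
            work.append(node.left)
    for node in order:
        doc = {"prob": node.prob, "n": node.n_node}
        if not node.is_leaf:
            doc["split"] = _split_to_doc(node.split)
            doc["left"] = index[id(node.left)]
            doc["right"] = index[id(node.right)]
        nodes.append(doc)
    return {"nodes": nodes, "inbag": [int(i) for i in tree.inbag]}


def _tree_from_doc(doc: dict, n_features: int) -> Tree:
    raw = doc["nodes"]
    nodes = [TreeNode(prob=d["prob"], n_node=d["n"]) for d in raw]
    for node, d in zip(nodes, raw):
        if "split" in d:
            node.split = _split_from_doc(d["split"])
            node.left = nodes[d["left"]]
            node.right = nodes[d["right"]]
    return Tree(root=nodes[0], inbag=np.asarray(doc["inbag"], dtype=np.intp),
                n_features=n_features)


def save_model(forest: Forest) -> dict:
    """Serialize a fitted forest to a versioned JSON-ready document."""
    cfg = forest.config
    return {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "n_features": forest.n_features,
        "n_train": forest.n_train,
        "seed": forest.seed,
        "config": {
            "selector": cfg.selector.to_config(),
            "min_node_size": cfg.min_node_size,
            "resample_mode": cfg.resample_mode,
            "sample_fraction": cfg.sample_fraction,
        },
        "trees": [_tree_to_doc(t) for t in forest.trees],
    }


def load_model(document: dict) -> Forest:
    """Rebuild a forest from a ``save_model`` document (version-checked)."""
    if not isinstance(document, dict) or document.get("format") != MODEL_FORMAT:
        raise ValueError("not a divforest model document")
    if document.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version {document.get('version')!r} not supported "
            f"(expected {MODEL_VERSION})"
        )
    cfg_doc = document["config"]
    config = GrowConfig(
        selector=selector_from_config(cfg_doc["selector"]),
        min_node_size=cfg_doc["min_node_size"],
        resample_mode=cfg_doc["resample_mode"],
        sample_fraction=cfg_doc["sample_fraction"],
    )
    n_features = document["n_features"]
    trees = [_tree_from_doc(d, n_features) for d in document["trees"]]
    return Forest(
        trees=trees,
        config=config,
        n_features=n_features,
        n_train=document["n_train"],
        seed=document["seed"],
    )


def write_model(forest: Forest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(save_model(forest)))


def read_model(path: str | Path) -> Forest:
    try:
        document = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    return load_model(document)
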