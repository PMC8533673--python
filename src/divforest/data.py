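"""In-memory dataset container shared by the generators, loaders and fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Dataset:
    """A complete tabular binary-classification dataset.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Feature matrix, float64.  Categorical features are integer codes
        (see :func:`divforest.io.load_dataset` for the encoding rule).
    y : ndarray of shape (n,)
        Binary labels, values 0/1 (int8).
    feature_names : list of str
        Column names, length p.
    meta : dict
        Free-form provenance (generator spec, source path, ...).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length must match the number of rows of X")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be coded 0/1")
        if not self.feature_names:
            self.feature_names = [f"x{j + 1}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must match the number of columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[label_column] = self.y
        return df
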