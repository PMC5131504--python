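"""Loading and saving labelled tabular datasets.

CSV is the primary dialect: a header row, numeric feature columns and one
label column (default ``label``).  ARFF files are also read (via
scipy.io.arff) since the classic imbalanced benchmark sets ship in that
format.  Rows with missing entries are dropped at load time with a logged
count — downstream operations require complete numeric features.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.io import arff

from .rebalance import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = ["load_csv", "load_arff", "load_dataset", "save_csv"]


def _from_frame(df: pd.DataFrame, label_col: str, minority_label) -> LabeledDataset:
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found; columns: {list(df.columns)}")
    n_before = len(df)
    df = df.dropna()
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing values", dropped)
    if df.empty:
        raise ValueError("no complete rows left after dropping missing values")
    labels = df[label_col].to_numpy()
    features = df.drop(columns=[label_col]).to_numpy(dtype=float)
    if minority_label is None:
        values, counts = np.unique(labels, return_counts=True)
        if len(values) != 2:
            raise ValueError(f"expected two classes, found {len(values)}")
        minority_label = values[counts.argmin()]
        logger.info("minority label inferred as %r (%d of %d rows)", minority_label,
                    counts.min(), len(labels))
    elif minority_label not in labels:
        raise ValueError(f"minority_label {minority_label!r} not present in the data")
    return LabeledDataset(features=features, labels=labels, minority_label=minority_label)


def load_csv(path, label_col: str = "label", minority_label=None) -> LabeledDataset:
    """Load a CSV with a header row; the rarer class is the minority unless
    ``minority_label`` is given explicitly."""
    df = pd.read_csv(path)
    if "subcluster" in df.columns and label_col != "subcluster":
        df = df.drop(columns=["subcluster"])  # ground-truth column from the generator
    return _from_frame(df, label_col, minority_label)


def load_arff(path, label_col: Optional[str] = None, minority_label=None) -> LabeledDataset:
    """Load an ARFF file; the label column defaults to the last attribute."""
    data, meta = arff.loadarff(path)
    df = pd.DataFrame(data)
    # byte-string nominal attributes -> str
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.decode("utf-8")
    if label_col is None:
        label_col = df.columns[-1]
    return _from_frame(df, label_col, minority_label)


def load_dataset(path, label_col: str = "label", minority_label=None) -> LabeledDataset:
    path = Path(path)
    if path.suffix.lower() == ".arff":
        return load_arff(path, label_col=label_col if label_col != "label" else None,
                         minority_label=minority_label)
    return load_csv(path, label_col=label_col, minority_label=minority_label)


def save_csv(
    dataset: LabeledDataset,
    path,
    label_col: str = "label",
    include_synthetic_flag: bool = False,
    subcluster: Optional[np.ndarray] = None,
) -> None:
    """Write a dataset as CSV (features f1..fd, then the label column).

    ``include_synthetic_flag`` adds a ``synthetic`` 0/1 provenance column
    (suppressed by default); ``subcluster`` optionally appends ground-truth
    majority sub-cluster assignments (minority rows get -1).
    """
    d = dataset.features.shape[1]
    df = pd.DataFrame(dataset.features, columns=[f"f{i + 1}" for i in range(d)])
    df[label_col] = dataset.labels
    if include_synthetic_flag:
        df["synthetic"] = dataset.synthetic.astype(int)
    if subcluster is not None:
        col = np.full(len(df), -1, dtype=int)
        maj_idx = np.flatnonzero(~dataset.minority_mask)
        col[maj_idx] = subcluster
        df["subcluster"] = col
    df.to_csv(path, index=False)
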