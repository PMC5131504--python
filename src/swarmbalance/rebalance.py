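"""Dataset container and SMOTE-based oversampling.

SMOTE fabricates synthetic minority samples by linear interpolation: for a
minority sample x_i, one of its k nearest minority neighbours x_t is drawn
and a synthetic point

    x_new = x_i + (x_t - x_i) * v_rand,      v_rand ~ Uniform[0, 1]

is emitted.  The oversampling rate N is the number of synthetic samples
generated per minority sample, so augmentation multiplies the minority count
by (1 + N).  This module provides the interpolation core plus the two
non-swarm baselines: full-balance SMOTE (append exactly enough synthetic
rows for a 1:1 ratio) and Random-SMOTE (draw N and k uniformly at random
from bounds).  Features are used as-is — no standardisation — before the
Euclidean nearest-neighbour search; callers wanting z-scored distances
standardise first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDataset",
    "SmoteParams",
    "ParamBounds",
    "RebalanceError",
    "minority_knn",
    "smote",
    "apply_smote",
    "full_balance_smote",
    "random_smote",
]


class RebalanceError(ValueError):
    """An oversampling operation was asked to run on degenerate input."""


@dataclass(frozen=True)
class LabeledDataset:
    """Numeric feature matrix with binary labels.

    ``minority_label`` names the positive/target class.  ``synthetic`` marks
    rows fabricated by an oversampler (all-False for loaded data); it is
    carried so that leakage checks can tell original rows from synthetic
    ones.  After oversampling the minority may outnumber the majority; the
    container allows that, only the rebalancing entry points check the
    imbalance direction.
    """

    features: np.ndarray
    labels: np.ndarray
    minority_label: object
    synthetic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if feats.ndim != 2:
            raise ValueError(f"features must be 2-D, got shape {feats.shape}")
        if labels.shape != (feats.shape[0],):
            raise ValueError("labels must be a 1-D array with one entry per feature row")
        if np.isnan(feats).any():
            raise ValueError("features contain missing values; filter rows at load time")
        uniq = set(np.unique(labels).tolist())
        if len(uniq) > 2:
            raise ValueError(f"expected binary labels, found {len(uniq)} distinct values")
        # single-class views (e.g. one side of a class split) are permitted;
        # operations that need both classes check at their own entry points
        synth = self.synthetic
        if synth is None:
            synth = np.zeros(feats.shape[0], dtype=bool)
        else:
            synth = np.asarray(synth, dtype=bool)
            if synth.shape != (feats.shape[0],):
                raise ValueError("synthetic mask must have one entry per row")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "synthetic", synth)

    # --- class views -----------------------------------------------------
    @property
    def minority_mask(self) -> np.ndarray:
        return self.labels == self.minority_label

    @property
    def minority_features(self) -> np.ndarray:
        return self.features[self.minority_mask]

    @property
    def majority_features(self) -> np.ndarray:
        return self.features[~self.minority_mask]

    @property
    def minority_count(self) -> int:
        return int(self.minority_mask.sum())

    @property
    def majority_count(self) -> int:
        return len(self.labels) - self.minority_count

    @property
    def majority_label(self) -> object:
        other = [v for v in np.unique(self.labels) if v != self.minority_label]
        return other[0] if other else self.minority_label

    @property
    def imbalance_ratio(self) -> float:
        """majority : minority ratio as a float (e.g. 15.0 for 15:1)."""
        return self.majority_count / max(self.minority_count, 1)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def append_synthetic_minority(self, rows: np.ndarray) -> "LabeledDataset":
        """Return a copy with ``rows`` appended as synthetic minority samples."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        labels = np.concatenate([self.labels, np.full(len(rows), self.minority_label, dtype=self.labels.dtype)])
        return LabeledDataset(
            features=np.vstack([self.features, rows]),
            labels=labels,
            minority_label=self.minority_label,
            synthetic=np.concatenate([self.synthetic, np.ones(len(rows), dtype=bool)]),
        )

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            minority_label=self.minority_label,
            synthetic=self.synthetic[idx],
        )


@dataclass(frozen=True)
class SmoteParams:
    """The (N, k) SMOTE parameter pair.

    ``n_rate`` — synthetic samples generated per minority sample (N);
    ``k_neighbors`` — size of the minority neighbourhood x_t is drawn from.
    """

    n_rate: int
    k_neighbors: int

    def __post_init__(self) -> None:
        if self.n_rate < 1 or self.n_rate != int(self.n_rate):
            raise ValueError(f"n_rate must be a positive integer, got {self.n_rate!r}")
        if self.k_neighbors < 1 or self.k_neighbors != int(self.k_neighbors):
            raise ValueError(f"k_neighbors must be a positive integer, got {self.k_neighbors!r}")


@dataclass(frozen=True)
class ParamBounds:
    """Inclusive integer bounds for the SMOTE parameter search space."""

    n_min: int = 1
    n_max: int = 10
    k_min: int = 1
    k_max: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.n_min <= self.n_max and 1 <= self.k_min <= self.k_max):
            raise ValueError(f"invalid bounds {self}")

    @classmethod
    def default_for(cls, dataset: LabeledDataset) -> "ParamBounds":
        """Bounds scaled to the dataset: N up to twice the (rounded-up)
        imbalance ratio — deliberately allowing the minority to overshoot the
        majority, since exact 1:1 balance is not where the best classifiers
        live — and k up to min(10, minority_count - 1)."""
        ir = math.ceil(dataset.imbalance_ratio)
        return cls(
            n_min=1,
            n_max=max(1, 2 * ir),
            k_min=1,
            k_max=max(1, min(10, dataset.minority_count - 1)),
        )

    def clamp_k(self, minority_count: int) -> "ParamBounds":
        hi = max(1, min(self.k_max, minority_count - 1))
        return replace(self, k_min=min(self.k_min, hi), k_max=hi)


def minority_knn(minority_features: np.ndarray, k: int) -> np.ndarray:
    """Indices of each minority row's k nearest *other* minority rows.

    Euclidean distances, ascending; exact distance ties broken by the lower
    row index.  Returns an (m, k) integer array.
    """
    x = np.asarray(minority_features, dtype=float)
    m = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= m:
        raise ValueError(f"k={k} must be < minority_count={m}; clamp before calling")
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)  # a sample is never its own neighbour
    # lexsort: primary key distance, secondary key column index -> stable tie-break
    cols = np.broadcast_to(np.arange(m), (m, m))
    order = np.lexsort((cols, d), axis=1)
    return order[:, :k]


def smote(
    minority_features: np.ndarray,
    params: SmoteParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate ``n_rate x m`` synthetic minority rows by interpolation.

    For each minority row x_i and each of its n_rate synthesis rounds, a
    neighbour x_t is drawn uniformly from x_i's k nearest minority
    neighbours and the synthetic row is x_i + (x_t - x_i) * v_rand with
    v_rand ~ Uniform[0, 1].  Deterministic given the generator state.
    """
    x = np.asarray(minority_features, dtype=float)
    m = len(x)
    if m < 2:
        raise RebalanceError("SMOTE needs at least two minority samples to interpolate between")
    k = params.k_neighbors
    if k >= m:
        raise ValueError(f"k_neighbors={k} must be < minority_count={m}; clamp before calling")
    nn = minority_knn(x, k)
    base = np.repeat(np.arange(m), params.n_rate)
    picked = nn[base, rng.integers(0, k, size=len(base))]
    v = rng.random((len(base), 1))
    return x[base] + (x[picked] - x[base]) * v


def apply_smote(dataset: LabeledDataset, params: SmoteParams, rng: np.random.Generator) -> LabeledDataset:
    """Augment ``dataset`` with SMOTE at the given (N, k); k is clamped to
    minority_count - 1."""
    k = max(1, min(params.k_neighbors, dataset.minority_count - 1))
    eff = SmoteParams(n_rate=params.n_rate, k_neighbors=k)
    return dataset.append_synthetic_minority(smote(dataset.minority_features, eff, rng))


def full_balance_smote(dataset: LabeledDataset, k: int, rng: np.random.Generator) -> LabeledDataset:
    """SMOTE to an exact 1:1 ratio.

    Appends exactly (majority - minority) synthetic rows.  An integer
    per-sample rate generally cannot land on 1:1, so base samples are cycled
    round-robin: per-sample synthesis counts differ by at most one.  An
    already balanced (or minority-heavy) dataset is returned unchanged.
    """
    deficit = dataset.majority_count - dataset.minority_count
    if deficit <= 0:
        logger.info("dataset already balanced (%d:%d); full_balance_smote is a no-op",
                    dataset.majority_count, dataset.minority_count)
        return dataset
    minority = dataset.minority_features
    m = len(minority)
    if m < 2:
        raise RebalanceError("cannot SMOTE a single-sample minority class")
    k_eff = max(1, min(k, m - 1))
    nn = minority_knn(minority, k_eff)
    base = np.arange(deficit) % m  # round-robin: counts differ by <= 1
    picked = nn[base, rng.integers(0, k_eff, size=deficit)]
    v = rng.random((deficit, 1))
    rows = minority[base] + (minority[picked] - minority[base]) * v
    return dataset.append_synthetic_minority(rows)


def random_smote(
    dataset: LabeledDataset,
    bounds: ParamBounds,
    rng: np.random.Generator,
) -> tuple[LabeledDataset, SmoteParams]:
    """Draw (N, k) uniformly from ``bounds`` and apply SMOTE once.

    Returns the augmented dataset and the drawn parameters; the benchmark
    harness is responsible for averaging over repeated draws.
    """
    if dataset.minority_count < 2:
        raise RebalanceError("cannot SMOTE a single-sample minority class")
    b = bounds.clamp_k(dataset.minority_count)
    n = int(rng.integers(b.n_min, b.n_max + 1))
    k = int(rng.integers(b.k_min, b.k_max + 1))
    params = SmoteParams(n_rate=n, k_neighbors=k)
    return apply_smote(dataset, params, rng), params
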