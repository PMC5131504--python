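"""Seeded generator of imbalanced tabular datasets with planted structure.

The generator emulates the regime of small biomedical benchmark sets:
imbalance ratios from roughly 5:1 to 42:1, a few hundred to a few thousand
samples, and — crucially — a majority class that is itself a mixture of
several latent sub-populations (the situation that motivates clustering the
majority before oversampling).

Model: the majority class is drawn from ``majority_subclusters`` spherical
unit-variance Gaussians whose means sit at the vertices of a regular
simplex with edge length ``cluster_separation`` (in units of the
within-cluster standard deviation).  The minority class has its own
spherical component placed at exactly ``cluster_separation`` from the
nearest majority mean; a ``minority_overlap`` fraction of minority points
is then *relocated* into randomly chosen majority components — relocation
rather than variance widening, so the class counts and the clean part of
the minority geometry stay interpretable.  Ground-truth sub-cluster
assignments for the majority rows are returned for clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .rebalance import LabeledDataset

__all__ = ["SyntheticSpec", "generate", "standard_fixtures", "FIXTURE_SPECS"]

MAJORITY_LABEL = 0
MINORITY_LABEL = 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic imbalanced dataset.

    ``cluster_separation`` is the distance between sub-cluster means in
    units of the within-cluster standard deviation (sigma = 1), so e.g. 8
    means essentially disjoint blobs and 4 means visibly touching tails.
    ``minority_overlap`` in [0, 1] is the fraction of minority points
    relocated into majority components.
    """

    n_majority: int
    n_minority: int
    majority_subclusters: int = 3
    dims: int = 2
    cluster_separation: float = 8.0
    minority_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_majority < 1 or self.n_minority < 1:
            raise ValueError("class counts must be positive")
        if self.n_majority < self.n_minority:
            raise ValueError("n_majority must be >= n_minority (imbalance by construction)")
        if self.majority_subclusters < 1 or self.majority_subclusters > self.n_majority:
            raise ValueError("majority_subclusters must be in 1..n_majority")
        if self.dims < max(1, self.majority_subclusters - 1):
            raise ValueError("dims must be >= majority_subclusters - 1 to place a regular simplex")
        if not 0.0 <= self.minority_overlap <= 1.0:
            raise ValueError("minority_overlap must be in [0, 1]")
        if self.cluster_separation <= 0:
            raise ValueError("cluster_separation must be positive")

    @property
    def imbalance_ratio(self) -> float:
        return self.n_majority / self.n_minority


def _majority_means(k: int, dims: int, edge: float) -> np.ndarray:
    """Vertices of a regular (k-1)-simplex with edge length ``edge``,
    centred at the origin and embedded in the first k-1 of ``dims`` axes."""
    if k == 1:
        return np.zeros((1, dims))
    v = np.eye(k)
    v = (v - v.mean(axis=0)) * (edge / np.sqrt(2.0))
    # drop the constant direction: the k centred vertices span k-1 dims
    u, s, _ = np.linalg.svd(v, full_matrices=False)
    coords = u[:, : k - 1] * s[: k - 1]
    means = np.zeros((k, dims))
    means[:, : k - 1] = coords
    return means


def generate(spec: SyntheticSpec) -> Tuple[LabeledDataset, np.ndarray]:
    """Draw one dataset; returns (dataset, majority ground-truth assignments).

    Exact class counts, exact imbalance ratio, fully seed-deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.majority_subclusters
    means = _majority_means(k, spec.dims, spec.cluster_separation)

    # majority: balanced round-robin assignment to sub-clusters, then shuffle
    truth = np.arange(spec.n_majority) % k
    rng.shuffle(truth)
    majority = means[truth] + rng.standard_normal((spec.n_majority, spec.dims))

    # minority mean: along the first-vertex direction, at exactly
    # `cluster_separation` beyond the nearest majority mean
    v0 = means[0]
    norm = np.linalg.norm(v0)
    direction = v0 / norm if norm > 0 else np.eye(spec.dims)[0]
    minority_mean = v0 + direction * spec.cluster_separation
    minority = minority_mean + rng.standard_normal((spec.n_minority, spec.dims))

    n_overlap = int(round(spec.minority_overlap * spec.n_minority))
    if n_overlap > 0:
        which = rng.choice(spec.n_minority, size=n_overlap, replace=False)
        host = rng.integers(0, k, size=n_overlap)
        minority[which] = means[host] + rng.standard_normal((n_overlap, spec.dims))

    features = np.vstack([majority, minority])
    labels = np.concatenate(
        [np.full(spec.n_majority, MAJORITY_LABEL), np.full(spec.n_minority, MINORITY_LABEL)]
    )
    dataset = LabeledDataset(features=features, labels=labels, minority_label=MINORITY_LABEL)
    return dataset, truth


# Frozen fixture suite: three difficulty levels spanning the benchmark
# regime (15:1 and 42:1 ratios).  Seeds are fixed so every run regenerates
# bit-identical matrices.
FIXTURE_SPECS: Dict[str, SyntheticSpec] = {
    "easy": SyntheticSpec(
        n_majority=450, n_minority=30, majority_subclusters=3,
        cluster_separation=8.0, minority_overlap=0.0, seed=11,
    ),
    "hard": SyntheticSpec(
        n_majority=450, n_minority=30, majority_subclusters=3,
        cluster_separation=4.0, minority_overlap=0.3, seed=23,
    ),
    "extreme": SyntheticSpec(
        n_majority=420, n_minority=10, majority_subclusters=3,
        cluster_separation=6.0, minority_overlap=0.1, seed=37,
    ),
}


def standard_fixtures() -> Dict[str, Tuple[LabeledDataset, np.ndarray, SyntheticSpec]]:
    """The named fixture suite: ``easy`` (well-separated, 15:1), ``hard``
    (tighter separation, 30% minority overlap, 15:1) and ``extreme``
    (42:1 with only ten minority samples)."""
    return {name: (*generate(spec), spec) for name, spec in FIXTURE_SPECS.items()}
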