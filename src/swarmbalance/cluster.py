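"""PSO-assisted k-means decomposition of the majority class.

The majority class of an imbalanced biomedical dataset typically mixes
several latent sub-populations (e.g. the many non-disease conditions lumped
into a single "control" label).  Splitting it into k clusters and pairing
each sub-majority with the full minority class yields sub-datasets with a
much milder imbalance, each of which is rebalanced independently.

k-means is sensitive to its random initial centres; here a particle swarm
searches over centre configurations (each particle encodes k centres as a
flattened k x d position, fitness = within-cluster sum of squared errors
after a short Lloyd refinement) so the decomposition does not fall into a
poor local optimum.  The cluster count itself is chosen adaptively: k is
accepted only if (1) k > 1 and (2) the minimum screening kappa across the
resulting sub-datasets exceeds 0.2 — i.e. every sub-problem is at least
"fair agreement" learnable.  When no k qualifies, the k with the best
minimum kappa is returned and flagged as a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .rebalance import LabeledDataset
from .swarm_mo import SwarmConfig, pso_minimize

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "SubDataset",
    "DecompositionResult",
    "kmeans_refine",
    "pso_kmeans",
    "build_subdatasets",
    "adaptive_decompose",
    "default_k_max",
]

MIN_KAPPA_SCREEN = 0.2  # second termination condition of the k search
MIN_CLUSTER_SIZE = 5  # clusters smaller than this invalidate a k


@dataclass
class ClusterModel:
    centers: np.ndarray  # (k, d)
    assignments: np.ndarray  # (n,) int, nearest-centre index per sample
    k: int
    sse: float


@dataclass
class SubDataset:
    """One majority cluster paired with the entire minority class."""

    sub_majority: np.ndarray
    minority: np.ndarray
    cluster_index: int

    def to_dataset(self, majority_label=0, minority_label=1) -> LabeledDataset:
        n_maj, n_min = len(self.sub_majority), len(self.minority)
        return LabeledDataset(
            features=np.vstack([self.sub_majority, self.minority]),
            labels=np.concatenate([np.full(n_maj, majority_label), np.full(n_min, minority_label)]),
            minority_label=minority_label,
        )


def _assign(data: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, float]:
    d2 = cdist(data, centers, metric="sqeuclidean")
    assign = d2.argmin(axis=1)
    sse = float(d2[np.arange(len(data)), assign].sum())
    return assign, sse


def kmeans_refine(
    data: np.ndarray,
    initial_centers: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> ClusterModel:
    """Lloyd iterations from given centres until the SSE change drops below
    ``tol`` or ``max_iter`` passes.

    SSE is non-increasing across iterations.  A cluster that empties during
    refinement is re-seeded at the sample farthest from its assigned centre
    (logged), which strictly decreases SSE.
    """
    data = np.asarray(data, dtype=float)
    centers = np.array(initial_centers, dtype=float, copy=True)
    k = len(centers)
    if k > len(data):
        raise ValueError(f"k={k} exceeds sample count {len(data)}")
    if len(np.unique(centers, axis=0)) != k:
        raise ValueError("initial centers must be distinct")
    assign, sse = _assign(data, centers)
    for _ in range(max_iter):
        for j in range(k):
            mask = assign == j
            if mask.any():
                centers[j] = data[mask].mean(axis=0)
            else:
                # farthest sample from its current centre becomes the new seed
                d2 = ((data - centers[assign]) ** 2).sum(axis=1)
                far = int(d2.argmax())
                logger.debug("empty cluster %d re-seeded at sample %d", j, far)
                centers[j] = data[far]
        new_assign, new_sse = _assign(data, centers)
        done = abs(sse - new_sse) < tol
        assign, sse = new_assign, new_sse
        if done:
            break
    return ClusterModel(centers=centers, assignments=assign, k=k, sse=sse)


def pso_kmeans(
    data: np.ndarray,
    k: int,
    config: SwarmConfig,
    rng: np.random.Generator,
    refine_steps: int = 5,
    patience: Optional[int] = 20,
) -> ClusterModel:
    """k-means with PSO-searched centres.

    Each particle's position is a flattened (k, d) centre set constrained to
    the data's bounding box; its fitness is the SSE after ``refine_steps``
    Lloyd iterations of the decoded centres.  The best refined model found
    anywhere in the run is returned (and given a final full refinement), so
    the result is never worse than the best particle's fitness.  Seeded-
    deterministic.  ``patience`` stops the swarm early after that many
    iterations without improvement.
    """
    data = np.asarray(data, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(data):
        raise ValueError(f"k={k} exceeds sample count {len(data)}")
    d = data.shape[1]
    if k == 1:
        center = data.mean(axis=0, keepdims=True)
        assign, sse = _assign(data, center)
        return ClusterModel(centers=center, assignments=assign, k=1, sse=sse)
    lo = np.tile(data.min(axis=0), k)
    hi = np.tile(data.max(axis=0), k)
    span = hi - lo
    span[span == 0] = 1.0  # constant feature: keep the box non-degenerate
    hi = lo + span

    best: dict = {"model": None, "sse": np.inf}

    def fitness(position: np.ndarray) -> float:
        centers = position.reshape(k, d)
        if len(np.unique(centers, axis=0)) != k:
            # coincident decoded centres: tiny deterministic jitter so Lloyd
            # starts from distinct seeds
            centers = centers + np.linspace(0, 1e-9, k)[:, None]
        model = kmeans_refine(data, centers, max_iter=refine_steps)
        if model.sse < best["sse"]:
            best["sse"] = model.sse
            best["model"] = model
        return model.sse

    pso_minimize(fitness, lo, hi, config, rng, patience=patience)
    # refine the winning centres to full convergence
    final = kmeans_refine(data, best["model"].centers)
    return final if final.sse <= best["model"].sse else best["model"]


def build_subdatasets(dataset: LabeledDataset, assignments: np.ndarray) -> list[SubDataset]:
    """Pair every majority cluster with the full minority class.

    The sub-majority sets partition the majority rows; the minority rows are
    shared verbatim by every sub-dataset.
    """
    majority = dataset.majority_features
    minority = dataset.minority_features
    subs = []
    for j in sorted(np.unique(assignments).tolist()):
        subs.append(SubDataset(sub_majority=majority[assignments == j], minority=minority, cluster_index=int(j)))
    return subs


def default_k_max(dataset: LabeledDataset) -> int:
    """Cap on the cluster-count search: keeps every sub-dataset big enough to
    train on."""
    maj, mino = dataset.majority_count, dataset.minority_count
    return max(2, min(8, maj // (2 * max(mino, 1)) + 2, maj // 10))


@dataclass
class DecompositionResult:
    subdatasets: list[SubDataset]
    k: int
    sub_kappas: list[float]
    fallback: bool
    model: ClusterModel
    cluster_sizes: list[int] = field(default_factory=list)
    candidates: dict[int, float] = field(default_factory=dict)  # k -> min screening kappa

    def to_report(self) -> dict:
        return {
            "k": self.k,
            "cluster_sizes": self.cluster_sizes,
            "sub_kappas": self.sub_kappas,
            "fallback": self.fallback,
        }


def adaptive_decompose(
    dataset: LabeledDataset,
    screen: Callable[[LabeledDataset], float],
    config: SwarmConfig,
    rng: Optional[np.random.Generator] = None,
    k_max: Optional[int] = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> DecompositionResult:
    """Choose the cluster count adaptively and decompose the majority class.

    ``screen`` maps a sub-dataset to a screening kappa (the pipeline supplies
    a seeded stratified-holdout classifier evaluation).  k is searched
    ascending from 2; the first k whose clusters all reach
    ``min_cluster_size`` and whose minimum sub-dataset kappa exceeds 0.2 is
    accepted.  If none qualifies, the candidate k with the largest minimum
    kappa is returned with ``fallback=True``.  The returned k is always > 1.
    """
    if dataset.minority_count < 2:
        raise ValueError("minority class must have at least two samples")
    if dataset.majority_count < 4:
        raise ValueError("majority class too small to decompose")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k_hi = k_max if k_max is not None else default_k_max(dataset)
    k_hi = max(2, min(k_hi, dataset.majority_count // 2))
    majority = dataset.majority_features

    candidates: dict[int, float] = {}
    stash: dict[int, tuple[ClusterModel, list[SubDataset], list[float]]] = {}
    for k in range(2, k_hi + 1):
        model = pso_kmeans(majority, k, config, rng)
        sizes = np.bincount(model.assignments, minlength=k)
        if sizes.min() < min_cluster_size:
            logger.info("k=%d rejected: smallest cluster has %d < %d samples", k, sizes.min(), min_cluster_size)
            continue
        subs = build_subdatasets(dataset, model.assignments)
        kappas = [screen(s.to_dataset()) for s in subs]
        candidates[k] = min(kappas)
        stash[k] = (model, subs, kappas)
        if min(kappas) > MIN_KAPPA_SCREEN:
            return DecompositionResult(
                subdatasets=subs,
                k=k,
                sub_kappas=kappas,
                fallback=False,
                model=model,
                cluster_sizes=sizes.tolist(),
                candidates=candidates,
            )
    if not stash:
        raise ValueError(
            f"no cluster count in 2..{k_hi} produced clusters of >= {min_cluster_size} samples"
        )
    k_best = max(candidates, key=candidates.get)
    model, subs, kappas = stash[k_best]
    logger.warning(
        "no k in 2..%d reached min sub-dataset kappa > %.1f; falling back to k=%d (min kappa %.3f)",
        k_hi, MIN_KAPPA_SCREEN, k_best, candidates[k_best],
    )
    return DecompositionResult(
        subdatasets=subs,
        k=k_best,
        sub_kappas=kappas,
        fallback=True,
        model=model,
        cluster_sizes=np.bincount(model.assignments, minlength=k_best).tolist(),
        candidates=candidates,
    )
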