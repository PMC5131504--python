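"""Particle swarm search over SMOTE parameters.

The oversampling rate N and neighbourhood size k are tuned per sub-dataset
by particle swarm optimisation (PSO).  Each particle carries a continuous
2-D position (n_raw, k_raw) that decodes to integer SMOTE parameters by
rounding and clamping; velocities follow the canonical update

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),    x <- x + v

with fresh r1, r2 ~ Uniform[0,1] per particle per dimension, and positions
and velocities clamped to bounds.

Two fitness objectives are tracked simultaneously: Cohen's kappa
(credibility) and accuracy.  Evaluations that no other evaluation dominates
are kept in a non-inferior (Pareto) archive; the global best fed back into
the velocity update is drawn uniformly at random from that archive each
iteration.  A particle's personal best is replaced by its new evaluation
when any of three criteria holds:

  (i)   the new evaluation is better on both objectives;
  (ii)  it is strictly better on one objective and within a tolerance on the
        other;
  (iii) the old personal best's kappa sits below the current credibility
        threshold (the threshold escalates through 0.2, 0.4, 0.6, 0.8 and
        never descends).

Otherwise the particle is "randomly removed": its position and velocity are
re-drawn uniformly within bounds and its personal best reset, keeping the
population size constant.  At termination the archive member with the best
reliable accuracy (kappa x accuracy) wins.

The single-objective predecessor (SRA) is also provided: plain PSO on
accuracy where bests only update when kappa exceeds a fixed 0.4 threshold
and accuracy strictly improves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

from .metrics import MetricsReport
from .rebalance import LabeledDataset, ParamBounds, SmoteParams

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectivePair",
    "Particle",
    "SwarmConfig",
    "ArchiveMember",
    "NonInferiorSet",
    "dominates",
    "update_archive",
    "select_global_best",
    "replacement_decision",
    "pso_step",
    "pso_minimize",
    "dmsmote_optimize",
    "sra_optimize",
    "DmsmoteResult",
    "SraResult",
]

# Evaluator contract: maps decoded SMOTE parameters for a fixed sub-dataset
# to a full metrics report (rebalance -> train classifier -> score).  Must be
# deterministic in its argument; see pipeline.make_evaluator.
Evaluator = Callable[[SmoteParams], MetricsReport]


class ObjectivePair(NamedTuple):
    """The two optimisation targets of one evaluation."""

    kappa: float
    accuracy: float


@dataclass
class Particle:
    """One swarm member: continuous position/velocity plus personal best."""

    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_eval: Optional[ObjectivePair] = None
    best_report: Optional[MetricsReport] = None
    best_value: float = float("inf")  # single-objective slot (pso_minimize)


@dataclass(frozen=True)
class SwarmConfig:
    """PSO settings.

    Defaults follow the benchmark protocol (population 20, 100 iterations)
    with standard constriction-equivalent constants w = 0.7298,
    c1 = c2 = 1.49618.  ``kappa_thresholds`` is the escalating credibility
    ladder; ``tolerance`` is the near-tie band of replacement criterion (ii).
    ``velocity_clamp`` caps |v| per dimension at that fraction of the bound
    range.  ``early_stop`` terminates once an archive member is essentially
    perfect on both objectives (disable for protocol-faithful full runs).
    """

    population: int = 20
    max_iterations: int = 100
    inertia: float = 0.7298
    c1: float = 1.49618
    c2: float = 1.49618
    tolerance: float = 0.05
    kappa_thresholds: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    bounds: Optional[ParamBounds] = None
    seed: int = 0
    velocity_clamp: float = 0.2
    early_stop: bool = True
    keep_old_on_fail: bool = False
    check_archive_invariant: bool = False

    def __post_init__(self) -> None:
        if self.population < 1 or self.max_iterations < 1:
            raise ValueError("population and max_iterations must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        th = tuple(self.kappa_thresholds)
        if any(not -1.0 < t < 1.0 for t in th) or any(a >= b for a, b in zip(th, th[1:])):
            raise ValueError("kappa_thresholds must be strictly ascending within (-1, 1)")


# --------------------------------------------------------------------------
# Pareto machinery
# --------------------------------------------------------------------------

def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """True iff ``a`` is at least as good on both objectives and strictly
    better on at least one."""
    return (
        a.kappa >= b.kappa
        and a.accuracy >= b.accuracy
        and (a.kappa > b.kappa or a.accuracy > b.accuracy)
    )


class ArchiveMember(NamedTuple):
    params: SmoteParams
    objectives: ObjectivePair
    report: Optional[MetricsReport] = None


class NonInferiorSet:
    """Archive of mutually non-dominated evaluations (the Pareto front
    approximation).  Small by construction; no crowding pruning."""

    def __init__(self, members: Sequence[ArchiveMember] = ()) -> None:
        self.members: list[ArchiveMember] = []
        for m in members:
            self.add(m)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def add(self, candidate: ArchiveMember) -> bool:
        """Insert ``candidate`` unless a member dominates it; evict members it
        dominates.  Returns True iff inserted.  Duplicate objective pairs are
        kept (they do not dominate each other) unless params also match."""
        for m in self.members:
            if dominates(m.objectives, candidate.objectives):
                return False
            if m.params == candidate.params and m.objectives == candidate.objectives:
                return False
        self.members = [m for m in self.members if not dominates(candidate.objectives, m.objectives)]
        self.members.append(candidate)
        return True

    def check_invariant(self) -> None:
        for i, a in enumerate(self.members):
            for j, b in enumerate(self.members):
                if i != j and dominates(a.objectives, b.objectives):
                    raise AssertionError(f"archive invariant violated: {a} dominates {b}")

    def best_by_reliable_accuracy(self) -> ArchiveMember:
        if not self.members:
            raise RuntimeError("empty non-inferior set")
        return max(self.members, key=lambda m: m.objectives.kappa * m.objectives.accuracy)


def update_archive(archive: NonInferiorSet, candidate: ArchiveMember) -> NonInferiorSet:
    """Functional wrapper over :meth:`NonInferiorSet.add` (mutates and
    returns ``archive``)."""
    archive.add(candidate)
    return archive


def select_global_best(archive: NonInferiorSet, rng: np.random.Generator) -> ArchiveMember:
    """Uniform random draw from the archive — the global best used for the
    next swarm renewal."""
    if len(archive) == 0:
        raise RuntimeError("cannot select a global best from an empty non-inferior set")
    return archive.members[int(rng.integers(0, len(archive)))]


def replacement_decision(
    old: ObjectivePair,
    new: ObjectivePair,
    threshold: float,
    tolerance: float,
) -> str:
    """Decide whether a particle's new evaluation replaces its old one.

    Returns ``"replace"`` iff any criterion holds:
      (i)   new is better on both objectives;
      (ii)  new is strictly better on one objective and the absolute
            difference on the other is below ``tolerance``;
      (iii) the old evaluation's kappa is below ``threshold`` (a stagnant
            low-credibility personal best is always worth displacing);
    else ``"reinitialize"``.
    """
    if new.kappa > old.kappa and new.accuracy > old.accuracy:
        return "replace"
    if new.kappa > old.kappa and abs(new.accuracy - old.accuracy) < tolerance:
        return "replace"
    if new.accuracy > old.accuracy and abs(new.kappa - old.kappa) < tolerance:
        return "replace"
    if old.kappa < threshold:
        return "replace"
    return "reinitialize"


# --------------------------------------------------------------------------
# PSO core
# --------------------------------------------------------------------------

def _clamp(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lo), hi)


def pso_step(
    particles: Sequence[Particle],
    global_best_position: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
    lo: np.ndarray,
    hi: np.ndarray,
) -> None:
    """One velocity/position update for every particle (in place).

    ``lo``/``hi`` are per-dimension position bounds; velocities are clamped
    to ``config.velocity_clamp`` times the bound range.
    """
    gbest = np.asarray(global_best_position, dtype=float)
    vmax = config.velocity_clamp * (hi - lo)
    for p in particles:
        r1 = rng.random(p.position.shape)
        r2 = rng.random(p.position.shape)
        p.velocity = (
            config.inertia * p.velocity
            + config.c1 * r1 * (p.best_position - p.position)
            + config.c2 * r2 * (gbest - p.position)
        )
        p.velocity = _clamp(p.velocity, -vmax, vmax)
        p.position = _clamp(p.position + p.velocity, lo, hi)


def pso_minimize(
    f: Callable[[np.ndarray], float],
    lo: Sequence[float],
    hi: Sequence[float],
    config: SwarmConfig,
    rng: np.random.Generator,
    patience: Optional[int] = None,
) -> tuple[np.ndarray, float]:
    """Plain single-objective PSO minimisation of ``f`` over a box.

    Used directly for the PSO-assisted k-means centre search and as the
    reference sanity check of the swarm core (e.g. the 2-D sphere function).
    ``patience``: stop early after that many iterations without improvement
    of the global best (None = run all iterations).
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    particles = []
    gbest_pos, gbest_val = None, np.inf
    for _ in range(config.population):
        pos = rng.uniform(lo, hi)
        vmax = config.velocity_clamp * (hi - lo)
        vel = rng.uniform(-vmax, vmax)
        val = f(pos)
        p = Particle(position=pos, velocity=vel, best_position=pos.copy(), best_value=val)
        particles.append(p)
        if val < gbest_val:
            gbest_pos, gbest_val = pos.copy(), val
    stale = 0
    for _ in range(config.max_iterations):
        pso_step(particles, gbest_pos, config, rng, lo, hi)
        improved = False
        for p in particles:
            val = f(p.position)
            if val < p.best_value:
                p.best_value = val
                p.best_position = p.position.copy()
            if val < gbest_val:
                gbest_pos, gbest_val = p.position.copy(), val
                improved = True
        stale = 0 if improved else stale + 1
        if patience is not None and stale >= patience:
            break
    return gbest_pos, gbest_val


# --------------------------------------------------------------------------
# Parameter encoding
# --------------------------------------------------------------------------

def _decode(position: np.ndarray, bounds: ParamBounds) -> SmoteParams:
    n = int(np.clip(round(float(position[0])), bounds.n_min, bounds.n_max))
    k = int(np.clip(round(float(position[1])), bounds.k_min, bounds.k_max))
    return SmoteParams(n_rate=n, k_neighbors=k)


def _encode(params: SmoteParams) -> np.ndarray:
    return np.array([params.n_rate, params.k_neighbors], dtype=float)


def _resolve_bounds(config: SwarmConfig, dataset: LabeledDataset) -> ParamBounds:
    bounds = config.bounds if config.bounds is not None else ParamBounds.default_for(dataset)
    return bounds.clamp_k(dataset.minority_count)


# --------------------------------------------------------------------------
# Dynamic multi-objective search (DMSMOTE / SDMRA)
# --------------------------------------------------------------------------

@dataclass
class DmsmoteResult:
    params: SmoteParams
    report: MetricsReport
    archive: NonInferiorSet
    thresholds_visited: list[float]
    iterations_run: int
    evaluations: int
    trace: list[dict] = field(default_factory=list)


def dmsmote_optimize(
    subdataset: LabeledDataset,
    config: SwarmConfig,
    evaluator: Evaluator,
    rng: Optional[np.random.Generator] = None,
    collect_trace: bool = False,
) -> DmsmoteResult:
    """Dynamic multi-objective PSO search for the best (N, k).

    Runs the archive-driven swarm described in the module docstring on one
    sub-dataset and returns the archive member with the highest reliable
    accuracy, its full metrics report, and the final non-inferior set.

    ``evaluator`` must map SmoteParams deterministically to a MetricsReport;
    because decoded parameters are integers on a small grid, evaluations are
    cached, which leaves the search trajectory unchanged while avoiding
    re-training the classifier on revisited parameter pairs.
    """
    if subdataset.minority_count < 2:
        raise ValueError("sub-dataset minority class must have at least two samples")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bounds = _resolve_bounds(config, subdataset)
    lo = np.array([bounds.n_min, bounds.k_min], dtype=float)
    hi = np.array([bounds.n_max, bounds.k_max], dtype=float)
    vmax = config.velocity_clamp * (hi - lo)

    cache: dict[SmoteParams, MetricsReport] = {}
    n_evals = 0

    def evaluate(params: SmoteParams) -> MetricsReport:
        nonlocal n_evals
        if params not in cache:
            cache[params] = evaluator(params)
            n_evals += 1
        return cache[params]

    def fresh_particle() -> tuple[Particle, SmoteParams, MetricsReport]:
        pos = rng.uniform(lo, hi)
        vel = rng.uniform(-vmax, vmax)
        params = _decode(pos, bounds)
        report = evaluate(params)
        p = Particle(
            position=pos,
            velocity=vel,
            best_position=pos.copy(),
            best_eval=ObjectivePair(report.kappa, report.accuracy),
            best_report=report,
        )
        return p, params, report

    archive = NonInferiorSet()
    particles: list[Particle] = []
    for _ in range(config.population):
        p, params, report = fresh_particle()
        particles.append(p)
        archive.add(ArchiveMember(params, p.best_eval, report))

    thresholds = list(config.kappa_thresholds)
    t_idx = 0
    visited = [thresholds[t_idx]]
    trace: list[dict] = []
    iterations_run = 0

    for it in range(config.max_iterations):
        iterations_run = it + 1
        gbest = select_global_best(archive, rng)
        pso_step(particles, _encode(gbest.params), config, rng, lo, hi)
        for pid, p in enumerate(particles):
            params = _decode(p.position, bounds)
            report = evaluate(params)
            new_eval = ObjectivePair(report.kappa, report.accuracy)
            archive.add(ArchiveMember(params, new_eval, report))
            decision = replacement_decision(p.best_eval, new_eval, thresholds[t_idx], config.tolerance)
            if decision == "replace":
                p.best_position = p.position.copy()
                p.best_eval = new_eval
                p.best_report = report
            elif not config.keep_old_on_fail:
                # "randomly removed": re-seed this swarm slot uniformly
                newp, nparams, nreport = fresh_particle()
                particles[pid] = newp
                archive.add(ArchiveMember(nparams, newp.best_eval, nreport))
            if collect_trace:
                trace.append(
                    {
                        "iteration": it,
                        "particle": pid,
                        "n_rate": params.n_rate,
                        "k_neighbors": params.k_neighbors,
                        "kappa": new_eval.kappa,
                        "accuracy": new_eval.accuracy,
                        "event": decision,
                        "threshold": thresholds[t_idx],
                    }
                )
        if config.check_archive_invariant:
            archive.check_invariant()
        if t_idx < len(thresholds) - 1 and all(
            p.best_eval.kappa > thresholds[t_idx] for p in particles
        ):
            t_idx += 1
            visited.append(thresholds[t_idx])
        if config.early_stop and any(
            m.objectives.kappa >= 0.999 and m.objectives.accuracy >= 0.999 for m in archive
        ):
            break

    winner = archive.best_by_reliable_accuracy()
    return DmsmoteResult(
        params=winner.params,
        report=winner.report,
        archive=archive,
        thresholds_visited=visited,
        iterations_run=iterations_run,
        evaluations=n_evals,
        trace=trace,
    )


# --------------------------------------------------------------------------
# Single-objective baseline (SRA)
# --------------------------------------------------------------------------

SRA_KAPPA_THRESHOLD = 0.4


@dataclass
class SraResult:
    params: SmoteParams
    report: MetricsReport
    feasible: bool  # False -> no evaluation cleared the kappa threshold; best-kappa fallback
    evaluations: int = 0


def sra_optimize(
    dataset: LabeledDataset,
    config: SwarmConfig,
    evaluator: Evaluator,
    rng: Optional[np.random.Generator] = None,
) -> SraResult:
    """Single-objective swarm rebalancing (the PSO-SMOTE predecessor).

    Maximises accuracy subject to the fixed credibility condition
    kappa > 0.4: a personal or global best only updates when the candidate
    both clears the kappa threshold and strictly improves accuracy.  If no
    evaluation is ever feasible the best-kappa evaluation is returned with
    ``feasible=False``.
    """
    if dataset.minority_count < 2:
        raise ValueError("minority class must have at least two samples")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bounds = _resolve_bounds(config, dataset)
    lo = np.array([bounds.n_min, bounds.k_min], dtype=float)
    hi = np.array([bounds.n_max, bounds.k_max], dtype=float)
    vmax = config.velocity_clamp * (hi - lo)

    cache: dict[SmoteParams, MetricsReport] = {}
    n_evals = 0

    def evaluate(params: SmoteParams) -> MetricsReport:
        nonlocal n_evals
        if params not in cache:
            cache[params] = evaluator(params)
            n_evals += 1
        return cache[params]

    best_feasible: Optional[tuple[SmoteParams, MetricsReport]] = None
    best_any: Optional[tuple[SmoteParams, MetricsReport]] = None  # highest kappa, fallback

    def consider(params: SmoteParams, report: MetricsReport) -> None:
        nonlocal best_feasible, best_any
        if best_any is None or report.kappa > best_any[1].kappa:
            best_any = (params, report)
        if report.kappa > SRA_KAPPA_THRESHOLD and (
            best_feasible is None or report.accuracy > best_feasible[1].accuracy
        ):
            best_feasible = (params, report)

    particles: list[Particle] = []
    for _ in range(config.population):
        pos = rng.uniform(lo, hi)
        vel = rng.uniform(-vmax, vmax)
        params = _decode(pos, bounds)
        report = evaluate(params)
        p = Particle(
            position=pos,
            velocity=vel,
            best_position=pos.copy(),
            best_eval=ObjectivePair(report.kappa, report.accuracy),
            best_report=report,
        )
        particles.append(p)
        consider(params, report)

    for _ in range(config.max_iterations):
        gbest_pair = best_feasible if best_feasible is not None else best_any
        pso_step(particles, _encode(gbest_pair[0]), config, rng, lo, hi)
        for p in particles:
            params = _decode(p.position, bounds)
            report = evaluate(params)
            consider(params, report)
            if report.kappa > SRA_KAPPA_THRESHOLD and report.accuracy > p.best_eval.accuracy:
                p.best_position = p.position.copy()
                p.best_eval = ObjectivePair(report.kappa, report.accuracy)
                p.best_report = report
        if config.early_stop and best_feasible is not None and (
            best_feasible[1].kappa >= 0.999 and best_feasible[1].accuracy >= 0.999
        ):
            break

    if best_feasible is not None:
        params, report = best_feasible
        return SraResult(params=params, report=report, feasible=True, evaluations=n_evals)
    params, report = best_any
    logger.warning("SRA: no evaluation cleared kappa > %.1f; returning best-kappa fallback", SRA_KAPPA_THRESHOLD)
    return SraResult(params=params, report=report, feasible=False, evaluations=n_evals)
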