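"""PSO mechanics, Pareto archive, replacement rules and the two searches."""

import numpy as np
import pytest

from swarmbalance.metrics import MetricsReport
from swarmbalance.pipeline import ClassifierConfig, make_evaluator
from swarmbalance.rebalance import ParamBounds, SmoteParams
from swarmbalance.swarm_mo import (
    ArchiveMember,
    NonInferiorSet,
    ObjectivePair,
    Particle,
    SwarmConfig,
    dmsmote_optimize,
    dominates,
    pso_minimize,
    pso_step,
    replacement_decision,
    select_global_best,
    sra_optimize,
    update_archive,
)

from conftest import two_blob_dataset


def _report(kappa, accuracy):
    return MetricsReport(
        kappa=kappa, accuracy=accuracy, g_mean=accuracy, f_measure=accuracy,
        reliable_accuracy=kappa * accuracy, majority_count=10, minority_count=5,
    )


def synthetic_evaluator(params: SmoteParams) -> MetricsReport:
    """Deterministic toy landscape peaking at N=6, k=4."""
    kappa = max(0.0, 1 - 0.08 * abs(params.n_rate - 6) - 0.05 * abs(params.k_neighbors - 4))
    accuracy = 0.5 + 0.5 * kappa
    return _report(kappa, accuracy)


class TestPsoStep:
    def test_pure_inertia_translates(self):
        cfg = SwarmConfig(inertia=1.0, c1=0.0, c2=0.0, velocity_clamp=1.0)
        p = Particle(position=np.zeros(2), velocity=np.array([1.0, 0.0]),
                     best_position=np.zeros(2))
        lo, hi = np.array([-10.0, -10.0]), np.array([10.0, 10.0])
        for i in range(1, 4):
            pso_step([p], np.zeros(2), cfg, np.random.default_rng(0), lo, hi)
            assert np.allclose(p.position, [i, 0.0])

    def test_stationary_at_joint_best(self):
        cfg = SwarmConfig()
        pos = np.array([2.0, 3.0])
        p = Particle(position=pos.copy(), velocity=np.zeros(2), best_position=pos.copy())
        pso_step([p], pos, cfg, np.random.default_rng(0), np.array([0.0, 0.0]), np.array([5.0, 5.0]))
        assert np.allclose(p.position, pos)

    def test_positions_respect_bounds(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            lo = rng.uniform(-5, 0, 2)
            hi = lo + rng.uniform(0.5, 5, 2)
            cfg = SwarmConfig(inertia=rng.uniform(0.2, 1.2), c1=rng.uniform(0, 2.5), c2=rng.uniform(0, 2.5))
            ps = [Particle(position=rng.uniform(lo, hi), velocity=rng.uniform(-2, 2, 2),
                           best_position=rng.uniform(lo, hi)) for _ in range(5)]
            for _ in range(10):
                pso_step(ps, rng.uniform(lo, hi), cfg, rng, lo, hi)
                for p in ps:
                    assert (p.position >= lo).all() and (p.position <= hi).all()

    def test_sphere_minimum_found(self):
        rng = np.random.default_rng(5)
        pos, val = pso_minimize(lambda x: float(x @ x), [-5, -5], [5, 5], SwarmConfig(seed=5), rng)
        assert np.linalg.norm(pos) < 1e-3


class TestDominance:
    def test_clear_dominance(self):
        assert dominates(ObjectivePair(0.9, 0.9), ObjectivePair(0.5, 0.8))

    def test_incomparable_pair(self):
        a, b = ObjectivePair(0.9, 0.5), ObjectivePair(0.5, 0.9)
        assert not dominates(a, b) and not dominates(b, a)

    def test_equal_pairs_do_not_dominate(self):
        a = ObjectivePair(0.7, 0.7)
        assert not dominates(a, a)


class TestArchive:
    def test_empty_plus_candidate_is_singleton(self):
        arc = NonInferiorSet()
        update_archive(arc, ArchiveMember(SmoteParams(1, 1), ObjectivePair(0.5, 0.5)))
        assert len(arc) == 1

    def test_dominated_member_evicted(self):
        arc = NonInferiorSet([ArchiveMember(SmoteParams(1, 1), ObjectivePair(0.8, 0.9))])
        update_archive(arc, ArchiveMember(SmoteParams(2, 2), ObjectivePair(0.9, 0.95)))
        assert [m.objectives for m in arc] == [ObjectivePair(0.9, 0.95)]

    def test_streaming_equals_brute_force_pareto_filter(self):
        rng = np.random.default_rng(42)
        cands = [
            ArchiveMember(SmoteParams(int(i % 20 + 1), int(i % 7 + 1)),
                          ObjectivePair(float(rng.uniform(-1, 1)), float(rng.uniform(0, 1))))
            for i in range(200)
        ]
        arc = NonInferiorSet()
        for c in cands:
            update_archive(arc, c)
        brute = [
            c for c in cands
            if not any(dominates(o.objectives, c.objectives) for o in cands if o is not c)
        ]
        assert sorted(m.objectives for m in arc) == sorted(b.objectives for b in brute)
        arc.check_invariant()
        winner = arc.best_by_reliable_accuracy()
        assert all(
            winner.objectives.kappa * winner.objectives.accuracy
            >= m.objectives.kappa * m.objectives.accuracy
            for m in arc
        )


class TestSelectGlobalBest:
    def test_singleton(self):
        m = ArchiveMember(SmoteParams(1, 1), ObjectivePair(0.5, 0.5))
        assert select_global_best(NonInferiorSet([m]), np.random.default_rng(0)) == m

    def test_uniformity_two_members(self):
        arc = NonInferiorSet([
            ArchiveMember(SmoteParams(1, 1), ObjectivePair(0.9, 0.5)),
            ArchiveMember(SmoteParams(2, 2), ObjectivePair(0.5, 0.9)),
        ])
        rng = np.random.default_rng(123)
        n = 10_000
        hits = sum(select_global_best(arc, rng).params.n_rate == 1 for _ in range(n))
        sigma = (n * 0.25) ** 0.5
        assert abs(hits - n / 2) < 3 * sigma

    def test_seeded_repeatability(self):
        arc = NonInferiorSet([
            ArchiveMember(SmoteParams(i, 1), ObjectivePair(0.5 + i / 100, 0.9 - i / 100))
            for i in range(1, 6)
        ])
        a = [select_global_best(arc, np.random.default_rng(7)).params.n_rate for _ in range(5)]
        b = [select_global_best(arc, np.random.default_rng(7)).params.n_rate for _ in range(5)]
        assert a == b

    def test_empty_archive_raises(self):
        with pytest.raises(RuntimeError):
            select_global_best(NonInferiorSet(), np.random.default_rng(0))


class TestReplacementDecision:
    def test_better_on_both(self):
        assert replacement_decision(ObjectivePair(0.3, 0.8), ObjectivePair(0.5, 0.9), 0.2, 0.05) == "replace"

    def test_one_better_other_within_tolerance(self):
        assert replacement_decision(ObjectivePair(0.5, 0.90), ObjectivePair(0.8, 0.87), 0.2, 0.05) == "replace"

    def test_old_below_threshold_is_displaced(self):
        assert replacement_decision(ObjectivePair(0.1, 0.99), ObjectivePair(0.05, 0.5), 0.2, 0.05) == "replace"

    def test_otherwise_reinitialize(self):
        assert replacement_decision(ObjectivePair(0.6, 0.9), ObjectivePair(0.5, 0.8), 0.2, 0.05) == "reinitialize"


class TestDmsmote:
    def _dataset(self):
        return two_blob_dataset(n_majority=60, n_minority=8, seed=1)

    def test_smoke_population_one(self):
        ds = self._dataset()
        cfg = SwarmConfig(population=1, max_iterations=1, seed=0,
                          bounds=ParamBounds(n_max=4, k_max=4))
        res = dmsmote_optimize(ds, cfg, synthetic_evaluator)
        assert len(res.archive) >= 1
        assert res.report.kappa == synthetic_evaluator(res.params).kappa

    def test_winner_maximizes_reliable_accuracy(self):
        ds = self._dataset()
        cfg = SwarmConfig(population=6, max_iterations=10, seed=2,
                          bounds=ParamBounds(n_max=12, k_max=7),
                          check_archive_invariant=True)
        res = dmsmote_optimize(ds, cfg, synthetic_evaluator)
        best = max(m.objectives.kappa * m.objectives.accuracy for m in res.archive)
        assert res.report.kappa * res.report.accuracy == pytest.approx(best)
        # the toy landscape's optimum is reachable
        assert res.params == SmoteParams(6, 4)

    def test_threshold_sequence_non_decreasing(self):
        ds = self._dataset()
        cfg = SwarmConfig(population=6, max_iterations=15, seed=3,
                          bounds=ParamBounds(n_max=12, k_max=7), early_stop=False)
        res = dmsmote_optimize(ds, cfg, synthetic_evaluator)
        assert res.thresholds_visited == sorted(res.thresholds_visited)

    def test_seeded_determinism(self):
        ds = self._dataset()
        cfg = SwarmConfig(population=5, max_iterations=8, seed=11,
                          bounds=ParamBounds(n_max=12, k_max=7))
        r1 = dmsmote_optimize(ds, cfg, synthetic_evaluator)
        r2 = dmsmote_optimize(ds, cfg, synthetic_evaluator)
        assert r1.params == r2.params
        assert [m.objectives for m in r1.archive] == [m.objectives for m in r2.archive]

    def test_separable_blobs_reach_perfect_kappa(self, clf_config):
        ds = two_blob_dataset(n_majority=80, n_minority=8, separation=14.0, seed=5)
        cfg = SwarmConfig(population=5, max_iterations=6, seed=4)
        res = dmsmote_optimize(ds, cfg, make_evaluator(ds, clf_config, base_seed=9))
        assert res.report.kappa == 1.0
        assert res.report.accuracy == 1.0

    def test_trace_collection(self):
        ds = self._dataset()
        cfg = SwarmConfig(population=3, max_iterations=2, seed=0,
                          bounds=ParamBounds(n_max=6, k_max=5))
        res = dmsmote_optimize(ds, cfg, synthetic_evaluator, collect_trace=True)
        assert res.trace and {"iteration", "particle", "event", "threshold"} <= set(res.trace[0])


class TestSra:
    def test_all_infeasible_flags_fallback(self):
        ds = two_blob_dataset(n_majority=40, n_minority=6, seed=2)
        cfg = SwarmConfig(population=4, max_iterations=3, seed=0,
                          bounds=ParamBounds(n_max=5, k_max=5))
        res = sra_optimize(ds, cfg, lambda p: _report(0.1, 0.9))
        assert not res.feasible

    def test_best_feasible_by_accuracy(self):
        ds = two_blob_dataset(n_majority=40, n_minority=6, seed=2)

        def landscape(p):
            if p.n_rate <= 2:
                return _report(0.45, 0.8)
            return _report(0.6, 0.9)

        cfg = SwarmConfig(population=6, max_iterations=6, seed=1,
                          bounds=ParamBounds(n_max=6, k_max=5), early_stop=False)
        res = sra_optimize(ds, cfg, landscape)
        assert res.feasible
        assert (res.report.kappa, res.report.accuracy) == (0.6, 0.9)

    def test_separable_blobs_reach_perfect_scores(self, clf_config):
        ds = two_blob_dataset(n_majority=80, n_minority=8, separation=14.0, seed=5)
        cfg = SwarmConfig(population=5, max_iterations=6, seed=4)
        res = sra_optimize(ds, cfg, make_evaluator(ds, clf_config, base_seed=9))
        assert res.feasible
        assert res.report.kappa == 1.0
        assert res.report.accuracy == 1.0
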