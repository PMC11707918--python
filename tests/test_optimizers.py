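"""Unit and property tests for the metaheuristic module."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcdnet.optimizers import (
    OptimizerConfig,
    SearchSpace,
    aosma_update,
    compute_rr,
    esoa_update,
    init_population,
    multi_run_stats,
    opposition_of,
    optimize,
    select_update_branch,
)
from tests.conftest import sphere


class TestSearchSpace:
    def test_validates_bounds(self):
        with pytest.raises(ValueError):
            SearchSpace(lower=np.array([0.0, np.inf]), upper=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            SearchSpace(lower=np.array([2.0]), upper=np.array([1.0]))

    def test_integer_rounding_stays_in_bounds(self):
        space = SearchSpace(
            lower=np.array([5.0]), upper=np.array([255.0]),
            integer_mask=np.array([True]),
        )
        assert space.round_integers(np.array([4.9]))[0] == 5
        assert space.round_integers(np.array([254.7]))[0] == 255
        assert space.round_integers(np.array([10.4]))[0] == 10


class TestRRSchedule:
    def test_rr_values(self):
        assert compute_rr(50, 50) == 1.0
        assert compute_rr(25, 50) == 0.5
        assert compute_rr(1, 50) == 0.02

    def test_rr_strictly_increasing(self):
        values = [compute_rr(u, 50) for u in range(1, 51)]
        assert all(b > a for a, b in zip(values, values[1:]))
        assert values == [u / 50 for u in range(1, 51)]

    def test_rr_zero_max_iter_raises(self):
        with pytest.raises(ZeroDivisionError):
            compute_rr(0, 0)

    def test_branch_rule_examples(self):
        assert select_update_branch(1, 50) == "AOSMA"
        assert select_update_branch(1, 100) == "ESOA"

    def test_degenerate_aosma_only_schedule_at_50(self):
        # with the default budget every iteration's RR is a multiple of 0.02
        assert [select_update_branch(u, 50) for u in range(1, 51)] == ["AOSMA"] * 50

    def test_alternating_schedule_at_100(self):
        branches = [select_update_branch(u, 100) for u in range(1, 101)]
        assert branches == ["ESOA" if u % 2 else "AOSMA" for u in range(1, 101)]

    def test_invalid_divisor(self):
        with pytest.raises(ValueError):
            select_update_branch(1, 50, switch_divisor=0.0)


class TestOpposition:
    def test_midpoint_is_fixed(self, sphere_space):
        mid = (sphere_space.lower + sphere_space.upper) / 2
        assert np.allclose(opposition_of(mid, sphere_space), mid)

    def test_unit_box_example(self):
        space = SearchSpace(lower=np.zeros(1), upper=np.ones(1))
        assert opposition_of(np.array([0.2]), space)[0] == pytest.approx(0.8)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    def test_involution(self, xs):
        space = SearchSpace(lower=-5.0 * np.ones(6), upper=5.0 * np.ones(6))
        x = np.array(xs)
        assert np.allclose(opposition_of(opposition_of(x, space), space), x)


class TestInitPopulation:
    def test_deterministic(self, sphere_space):
        cfg = OptimizerConfig(seed=7)
        s1 = init_population(sphere, sphere_space, cfg)
        s2 = init_population(sphere, sphere_space, cfg)
        assert all(
            np.array_equal(a.position, b.position) and a.fitness == b.fitness
            for a, b in zip(s1.population, s2.population)
        )

    def test_degenerate_interval(self):
        space = SearchSpace(lower=np.full(3, 2.0), upper=np.full(3, 2.0))
        state = init_population(sphere, space, OptimizerConfig(seed=0))
        for cand in state.population:
            assert np.array_equal(cand.position, np.full(3, 2.0))

    def test_in_bounds_and_finite(self, sphere_space):
        state = init_population(sphere, sphere_space, OptimizerConfig(seed=3))
        assert len(state.population) == 10
        for cand in state.population:
            assert np.all(cand.position >= sphere_space.lower)
            assert np.all(cand.position <= sphere_space.upper)
            assert math.isfinite(cand.fitness)

    def test_matches_uniform_sampling_oracle(self, sphere_space):
        cfg = OptimizerConfig(seed=42)
        state = init_population(sphere, sphere_space, cfg)
        oracle = np.random.default_rng(42).uniform(
            sphere_space.lower, sphere_space.upper, size=(10, 6)
        )
        got = np.array([c.position for c in state.population])
        assert np.array_equal(got, oracle)

    def test_all_nonfinite_objective_raises(self, sphere_space):
        with pytest.raises(RuntimeError):
            init_population(lambda x: float("nan"), sphere_space, OptimizerConfig(seed=0))


@pytest.mark.parametrize("update", [aosma_update, esoa_update])
class TestSingleSteps:
    def test_best_cannot_worsen(self, update, sphere_space):
        state = init_population(sphere, sphere_space, OptimizerConfig(seed=1))
        before = state.best.fitness
        update(state, sphere)
        assert state.best.fitness <= before

    def test_positions_stay_in_bounds(self, update, sphere_space):
        state = init_population(sphere, sphere_space, OptimizerConfig(seed=2))
        for _ in range(5):
            update(state, sphere)
            for cand in state.population:
                assert np.all(cand.position >= sphere_space.lower - 1e-12)
                assert np.all(cand.position <= sphere_space.upper + 1e-12)

    def test_objective_error_is_tolerated(self, update, sphere_space):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 7 == 0:
                raise RuntimeError("transient")
            return sphere(x)

        state = init_population(flaky, sphere_space, OptimizerConfig(seed=3))
        update(state, flaky)   # must not raise
        assert state.n_errors >= 0


class TestOptimize:
    def test_constant_objective_flat_trace(self, sphere_space):
        res = optimize(lambda x: 4.25, sphere_space, OptimizerConfig(seed=0, max_iter=10))
        assert res.best_fitness == 4.25
        assert np.all(res.trace == 4.25)

    def test_same_seed_identical(self, sphere_space):
        cfg = OptimizerConfig(seed=9, max_iter=15)
        r1 = optimize(sphere, sphere_space, cfg)
        r2 = optimize(sphere, sphere_space, cfg)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert np.array_equal(r1.trace, r2.trace)

    @pytest.mark.parametrize("method", ["aosma", "esoa", "rpaosm-eso"])
    def test_trace_non_increasing(self, method, sphere_space):
        for seed in range(3):
            res = optimize(
                sphere, sphere_space, OptimizerConfig(seed=seed, max_iter=20), method
            )
            assert res.trace.size == 20
            assert np.all(np.diff(res.trace) <= 0)

    def test_hybrid_schedule_recorded(self, sphere_space):
        res = optimize(sphere, sphere_space, OptimizerConfig(seed=0, max_iter=50))
        assert set(res.branch_schedule) == {"AOSMA"}
        res100 = optimize(sphere, sphere_space, OptimizerConfig(seed=0, max_iter=100))
        assert set(res100.branch_schedule) == {"AOSMA", "ESOA"}

    def test_unknown_method(self, sphere_space):
        with pytest.raises(ValueError):
            optimize(sphere, sphere_space, OptimizerConfig(), method="genetic")

    def test_non_callable_objective(self, sphere_space):
        with pytest.raises(TypeError):
            optimize(3.0, sphere_space, OptimizerConfig())

    def test_integer_mask_rounds_before_call(self):
        seen = []
        space = SearchSpace(
            lower=np.array([0.0, 5.0]), upper=np.array([1.0, 50.0]),
            integer_mask=np.array([False, True]),
        )

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        optimize(probe, space, OptimizerConfig(seed=0, max_iter=3))
        assert all(float(x[1]).is_integer() for x in seen)

    def test_run_record_serializes(self, sphere_space):
        import json

        res = optimize(sphere, sphere_space, OptimizerConfig(seed=0, max_iter=5))
        record = json.loads(res.to_json())
        assert record["config"]["seed"] == 0
        assert len(record["trace"]) == 5


class TestMultiRunStats:
    def test_constant_objective(self, sphere_space):
        stats = multi_run_stats(
            lambda x: 2.5, sphere_space, OptimizerConfig(seed=0, max_iter=3), n_runs=4
        )
        assert stats.best == stats.worst == stats.mean == stats.median == 2.5
        assert stats.std == 0.0

    def test_single_run(self, sphere_space):
        stats = multi_run_stats(
            sphere, sphere_space, OptimizerConfig(seed=0, max_iter=5), n_runs=1
        )
        assert stats.best == stats.worst == stats.mean == stats.median
        assert stats.std == 0.0

    def test_matches_recomputation_from_finals(self, sphere_space):
        stats = multi_run_stats(
            sphere, sphere_space, OptimizerConfig(seed=0, max_iter=5), n_runs=5
        )
        arr = np.array(stats.finals)
        assert stats.best == arr.min() and stats.worst == arr.max()
        assert stats.mean == pytest.approx(arr.mean())
        assert stats.median == pytest.approx(np.median(arr))
        assert stats.std == pytest.approx(arr.std())
        assert stats.best <= stats.median <= stats.worst

    def test_rejects_zero_runs(self, sphere_space):
        with pytest.raises(ValueError):
            multi_run_stats(sphere, sphere_space, OptimizerConfig(), n_runs=0)
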