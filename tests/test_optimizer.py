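import math

import numpy as np
import pytest

from drrpose.optimizer import (
    DEConfig,
    Population,
    crossover,
    initialize_population,
    mutate,
    optimize,
    phase_controls,
    select,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class ScriptedRNG:
    """Replays a fixed integer/uniform draw script (for hand-built examples)."""

    def __init__(self, integers=(), uniforms=()):
        self._ints = list(integers)
        self._floats = list(uniforms)

    def integers(self, low, high):
        return self._ints.pop(0)

    def random(self, n=None):
        if n is None:
            return self._floats.pop(0)
        return np.array([self._floats.pop(0) for _ in range(n)])


def replay_pde(objective, config):
    """Straight-line reimplementation of the optimizer's documented draw order."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    x = lo + rng.random((config.np_size, config.dim)) * (hi - lo)
    if config.initial is not None:
        x[0] = config.initial
    fit = np.array([objective(v) for v in x])
    for g in range(1, config.gmax + 1):
        first = g <= math.ceil(config.gmax / 2)
        f = (config.f_schedule[0] if first else config.f_schedule[1]) * np.asarray(config.f_dim_scale)
        cr = config.cr_schedule[0] if first else config.cr_schedule[1]
        trials = np.empty_like(x)
        for i in range(config.np_size):
            idx = []
            while len(idx) < 5:
                r = int(rng.integers(0, config.np_size))
                if r != i and r not in idx:
                    idx.append(r)
            r1, r2, r3, r4, r5 = idx
            v = np.clip(x[r1] + f * (x[r2] - x[r3]) + f * (x[r4] - x[r5]), lo, hi)
            j_rand = int(rng.integers(0, config.dim))
            take = rng.random(config.dim) < cr
            take[j_rand] = True
            trials[i] = np.where(take, v, x[i])
        tfit = np.array([objective(t) for t in trials])
        for i in range(config.np_size):
            if tfit[i] < fit[i]:
                x[i] = trials[i]
                fit[i] = tfit[i]
    return x, fit


class TestDEConfig:
    def test_np_below_six_rejected(self):
        with pytest.raises(ValueError):
            DEConfig(np_size=5, dim=2, bounds=((0, 1),) * 2)

    def test_cr_schedule_must_straddle_half(self):
        with pytest.raises(ValueError):
            DEConfig(np_size=6, dim=1, bounds=((0, 1),), cr_schedule=(0.4, 0.3))
        with pytest.raises(ValueError):
            DEConfig(np_size=6, dim=1, bounds=((0, 1),), cr_schedule=(0.9, 0.6))

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            DEConfig(np_size=6, dim=2, bounds=((0, 1), (1, 1)))

    def test_initial_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            DEConfig(np_size=6, dim=1, bounds=((0, 1),), initial=(2.0,))


class TestInitializePopulation:
    def test_shape_and_containment(self):
        cfg = DEConfig(np_size=10, dim=6, bounds=((0.0, 1.0),) * 6, seed=3)
        pop = initialize_population(cfg, sphere)
        assert pop.vectors.shape == (10, 6)
        assert np.all(pop.vectors >= 0.0) and np.all(pop.vectors < 1.0)
        assert pop.fitnesses.shape == (10,)

    def test_seed_reproducibility(self):
        cfg = DEConfig(np_size=8, dim=3, bounds=((-2.0, 5.0),) * 3, seed=11)
        a = initialize_population(cfg, sphere)
        b = initialize_population(cfg, sphere)
        assert np.array_equal(a.vectors, b.vectors)

    def test_initial_injection(self):
        cfg = DEConfig(np_size=6, dim=2, bounds=((-1.0, 1.0),) * 2, initial=(0.5, -0.5))
        pop = initialize_population(cfg, sphere)
        assert np.array_equal(pop.vectors[0], [0.5, -0.5])


class TestPhaseControls:
    @pytest.mark.parametrize(
        "g,gmax,f_expected,cr_expected",
        [
            (1, 50, 0.5, 0.9),
            (25, 50, 0.5, 0.9),
            (26, 50, 0.8, 0.3),
            (50, 50, 0.8, 0.3),
            (26, 51, 0.5, 0.9),  # odd Gmax: first stage runs through ceil(51/2) = 26
            (27, 51, 0.8, 0.3),
        ],
    )
    def test_stage_switch(self, g, gmax, f_expected, cr_expected):
        cfg = DEConfig(np_size=6, dim=3, gmax=gmax, bounds=((0, 1),) * 3)
        f_vec, cr = phase_controls(g, gmax, cfg)
        np.testing.assert_allclose(f_vec, f_expected)
        assert cr == cr_expected

    def test_per_dimension_scale(self):
        cfg = DEConfig(
            np_size=6, dim=6, gmax=50, bounds=((0, 1),) * 6, f_dim_scale=(1, 1, 0.8, 1, 1, 1)
        )
        f_vec, _ = phase_controls(26, 50, cfg)
        assert f_vec[2] == pytest.approx(0.8 * 0.8)
        assert f_vec[0] == pytest.approx(0.8)

    def test_out_of_range_generation(self):
        cfg = DEConfig(np_size=6, dim=1, gmax=10, bounds=((0, 1),))
        with pytest.raises(ValueError):
            phase_controls(0, 10, cfg)


class TestMutate:
    def test_uniform_population_returns_base_vector(self):
        cfg = DEConfig(np_size=6, dim=3, bounds=((-5.0, 5.0),) * 3, seed=0)
        vecs = np.tile([1.0, 2.0, 3.0], (6, 1))
        pop = Population(vectors=vecs, fitnesses=np.zeros(6))
        v = mutate(pop, 0, np.full(3, 0.5), np.random.default_rng(0), cfg)
        np.testing.assert_array_equal(v, [1.0, 2.0, 3.0])

    def test_hand_arithmetic_example(self):
        cfg = DEConfig(np_size=6, dim=2, bounds=((-10.0, 10.0),) * 2)
        vecs = np.array([[9, 9], [1, 2], [0.5, 0], [0, 0.5], [1, 1], [1, 0]], dtype=float)
        pop = Population(vectors=vecs, fitnesses=np.zeros(6))
        rng = ScriptedRNG(integers=[1, 2, 3, 4, 5])  # donors r1..r5 = rows 1..5
        v = mutate(pop, 0, np.full(2, 0.5), rng, cfg)
        np.testing.assert_allclose(v, [1.25, 2.25])

    def test_zero_f_returns_base(self):
        cfg = DEConfig(np_size=6, dim=2, bounds=((-10.0, 10.0),) * 2)
        vecs = np.arange(12, dtype=float).reshape(6, 2)
        pop = Population(vectors=vecs, fitnesses=np.zeros(6))
        rng = ScriptedRNG(integers=[3, 0, 1, 4, 5])
        v = mutate(pop, 2, np.zeros(2), rng, cfg)
        np.testing.assert_array_equal(v, vecs[3])

    def test_mutant_clipped_to_bounds(self):
        cfg = DEConfig(np_size=6, dim=1, bounds=((0.0, 1.0),))
        vecs = np.array([[1.0], [1.0], [0.0], [1.0], [1.0], [0.0]])
        pop = Population(vectors=vecs, fitnesses=np.zeros(6))
        rng = ScriptedRNG(integers=[1, 3, 2, 4, 5])  # 1 + 2*(1-0) + 2*(1-0) would leave the box
        v = mutate(pop, 0, np.array([2.0]), rng, cfg)
        assert v[0] == 1.0

    def test_donor_indices_mutually_distinct(self):
        cfg = DEConfig(np_size=6, dim=1, bounds=((0.0, 1.0),), seed=0)
        rng = np.random.default_rng(99)
        base = np.zeros((6, 1))
        # vectors encode their own index so the drawn donors can be decoded
        base[:, 0] = np.arange(6)
        pop = Population(vectors=base, fitnesses=np.zeros(6))
        from drrpose.optimizer import _distinct_indices

        for _ in range(10_000):
            i = int(rng.integers(0, 6))
            idx = _distinct_indices(rng, 6, i)
            assert len(set(idx)) == 5
            assert i not in idx


class TestCrossover:
    def test_cr_zero_changes_only_jrand(self):
        target = np.zeros(6)
        mutant = np.ones(6)
        rng = np.random.default_rng(5)
        trial = crossover(target, mutant, cr=0.0, rng=rng)
        assert trial.sum() == 1.0  # exactly one mutant coordinate survives

    def test_cr_near_one_takes_mutant(self):
        target = np.zeros(8)
        mutant = np.ones(8)
        trial = crossover(target, mutant, cr=1.0 - 1e-12, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(trial, mutant)

    def test_scripted_replay(self):
        target = np.array([0.0, 0.0, 0.0, 0.0])
        mutant = np.array([1.0, 2.0, 3.0, 4.0])
        rng = ScriptedRNG(integers=[2], uniforms=[0.6, 0.3, 0.9, 0.49])
        trial = crossover(target, mutant, cr=0.5, rng=rng)
        # rand_j < 0.5 at j = 1, 3; j_rand = 2 forced
        np.testing.assert_array_equal(trial, [0.0, 2.0, 3.0, 4.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover(np.zeros(3), np.zeros(4), 0.5, np.random.default_rng(0))


class TestSelect:
    def test_strictly_better_trial_survives(self):
        vec, fit, replaced = select(np.array([2.0]), 4.0, np.array([1.0]), sphere)
        assert replaced and fit == 1.0 and vec[0] == 1.0

    def test_tie_keeps_target(self):
        vec, fit, replaced = select(np.array([2.0]), 4.0, np.array([-2.0]), sphere)
        assert not replaced and vec[0] == 2.0

    def test_worse_trial_rejected(self):
        vec, fit, replaced = select(np.array([1.0]), 1.0, np.array([3.0]), sphere)
        assert not replaced and fit == 1.0

    def test_non_finite_objective_reported(self):
        with pytest.raises(ValueError, match="non-finite"):
            select(np.array([1.0]), 1.0, np.array([2.0]), lambda x: np.nan)


class TestOptimize:
    def test_quadratic_minimum_found(self):
        cfg = DEConfig(np_size=10, dim=1, gmax=100, bounds=((-5.0, 5.0),), seed=4)
        res = optimize(lambda x: (x[0] - 2.0) ** 2, cfg)
        assert abs(res.best_vector[0] - 2.0) < 1e-3

    def test_constant_objective_flat_trace(self):
        cfg = DEConfig(np_size=6, dim=2, gmax=10, bounds=((0, 1),) * 2, seed=1)
        res = optimize(lambda x: 7.5, cfg)
        assert res.best_fitness == 7.5
        assert np.all(res.trace == 7.5)

    def test_trace_monotone_non_increasing(self):
        cfg = DEConfig(np_size=8, dim=4, gmax=60, bounds=((-3.0, 3.0),) * 4, seed=9)
        res = optimize(sphere, cfg)
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_fitness == res.trace[-1]

    def test_exact_evaluation_count(self):
        calls = {"n": 0}

        def counting(x):
            calls["n"] += 1
            return sphere(x)

        cfg = DEConfig(np_size=7, dim=2, gmax=13, bounds=((-1.0, 1.0),) * 2, seed=2)
        res = optimize(counting, cfg)
        assert calls["n"] == 7 * (13 + 1)
        assert res.evaluations == calls["n"]

    def test_vectors_stay_in_bounds(self):
        cfg = DEConfig(np_size=6, dim=3, gmax=40, bounds=((-0.5, 0.25),) * 3, seed=8)
        res = optimize(sphere, cfg)
        assert np.all(res.population.vectors >= -0.5)
        assert np.all(res.population.vectors <= 0.25)

    def test_full_run_reproducible(self):
        cfg = DEConfig(np_size=6, dim=2, gmax=20, bounds=((-2.0, 2.0),) * 2, seed=123)
        a = optimize(sphere, cfg)
        b = optimize(sphere, cfg)
        assert np.array_equal(a.best_vector, b.best_vector)
        assert np.array_equal(a.trace, b.trace)

    def test_step_level_replay_oracle(self):
        """Three generations at NP=6, D=2 reproduce an independent
        straight-line reimplementation fed the same generator draws."""
        cfg = DEConfig(np_size=6, dim=2, gmax=3, bounds=((-4.0, 4.0),) * 2, seed=2024)
        res = optimize(sphere, cfg)
        x, fit = replay_pde(sphere, cfg)
        assert np.array_equal(res.population.vectors, x)
        assert np.array_equal(res.population.fitnesses, fit)

    def test_batch_objective_equivalent_to_scalar(self):
        cfg = DEConfig(np_size=6, dim=3, gmax=15, bounds=((-1.0, 2.0),) * 3, seed=77)
        a = optimize(sphere, cfg)
        b = optimize(sphere, cfg, batch_objective=lambda vs: [sphere(v) for v in vs])
        assert np.array_equal(a.best_vector, b.best_vector)
        assert np.array_equal(a.trace, b.trace)

    def test_objective_errors_propagate(self):
        cfg = DEConfig(np_size=6, dim=1, gmax=5, bounds=((0.0, 1.0),), seed=0)
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: np.inf, cfg)
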