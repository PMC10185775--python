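"""Unit and property tests for the Equilibrium Optimizer core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svmeo.eo import (
    Bounds,
    EOConfig,
    Particle,
    exponential_term,
    generation_rate,
    initialize_population,
    memory_save,
    run_eo,
    time_coefficient,
    update_concentration,
    update_equilibrium_pool,
)


def unit_bounds(dim):
    return Bounds(lower=np.zeros(dim), upper=np.ones(dim))


class TestConfigAndBounds:
    def test_pool_needs_five_particles(self):
        with pytest.raises(ValueError, match="population_size"):
            EOConfig(population_size=4)

    @pytest.mark.parametrize("gp", [-0.1, 1.1])
    def test_generation_probability_range(self, gp):
        with pytest.raises(ValueError):
            EOConfig(generation_probability=gp)

    def test_bounds_must_be_finite_and_ordered(self):
        with pytest.raises(ValueError):
            Bounds(lower=np.array([0.0]), upper=np.array([np.inf]))
        with pytest.raises(ValueError):
            Bounds(lower=np.array([1.0]), upper=np.array([0.0]))


class TestInitialization:
    def test_all_positions_inside_box(self, rng):
        bounds = unit_bounds(5)
        pop = initialize_population(bounds, EOConfig(population_size=10), rng)
        assert len(pop) == 10
        for p in pop:
            assert p.position.size == 5
            assert (p.position >= 0).all() and (p.position <= 1).all()
            assert p.fitness is None

    def test_hyperparameter_scale_box(self, rng):
        bounds = Bounds(lower=np.array([0.001]), upper=np.array([1000.0]))
        pop = initialize_population(bounds, EOConfig(population_size=20), rng)
        vals = np.array([p.position[0] for p in pop])
        assert (vals >= 0.001).all() and (vals <= 1000.0).all()

    def test_same_seed_gives_identical_population(self):
        bounds = unit_bounds(3)
        cfg = EOConfig(population_size=8)
        a = initialize_population(bounds, cfg, np.random.default_rng(5))
        b = initialize_population(bounds, cfg, np.random.default_rng(5))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.position, pb.position)


class TestEquilibriumPool:
    def _pop(self, fitnesses):
        return [
            Particle(position=np.array([float(i)]), fitness=f)
            for i, f in enumerate(fitnesses)
        ]

    def test_pool_matches_brute_force_sort(self):
        pop = self._pop([3, 1, 2, 5, 4, 0.5])
        pool = update_equilibrium_pool(pop)
        assert list(pool.fitnesses[:4]) == [0.5, 1, 2, 3]
        expected_mean = np.mean([[5.0], [1.0], [2.0], [0.0]], axis=0)
        np.testing.assert_allclose(pool.candidates[4], expected_mean)
        assert np.isnan(pool.fitnesses[4])

    def test_degenerate_identical_population(self):
        pop = self._pop([1.0] * 6)
        for p in pop:
            p.position = np.array([7.0])
        pool = update_equilibrium_pool(pop)
        for cand in pool.candidates:
            np.testing.assert_array_equal(cand, np.array([7.0]))

    def test_tie_break_is_stable_by_index(self):
        pop = self._pop([2.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        pool = update_equilibrium_pool(pop)
        # the four best are particles 1..4 in index order
        np.testing.assert_array_equal(
            np.concatenate(pool.candidates[:4]), np.array([1.0, 2.0, 3.0, 4.0])
        )

    def test_unevaluated_population_rejected(self):
        pop = self._pop([1, 2, 3, 4, 5])
        pop[2].fitness = None
        with pytest.raises(RuntimeError, match="fitness"):
            update_equilibrium_pool(pop)

    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_pool_bests_equal_sorted_four_lowest(self, fits):
        pop = self._pop(fits)
        pool = update_equilibrium_pool(pop)
        assert list(pool.fitnesses[:4]) == sorted(fits)[:4]


class TestDynamics:
    def test_time_coefficient_boundary_values(self):
        cfg = EOConfig(max_iterations=100)
        assert time_coefficient(0, cfg) == 1.0
        assert time_coefficient(100, cfg) == 0.0

    def test_time_coefficient_midpoint(self):
        cfg = EOConfig(max_iterations=100, a2=1.0)
        assert time_coefficient(50, cfg) == pytest.approx(0.70710678, abs=1e-8)

    def test_exponential_term_vanishes_at_t_zero(self, rng):
        f = exponential_term(0.0, 6, EOConfig(), rng)
        np.testing.assert_array_equal(f, np.zeros(6))

    def test_exponential_term_value_and_sign(self):
        # a1=2, t=1, lam=1, r=0.9 -> F = 2*(e^-1 - 1)
        cfg = EOConfig(a1=2.0)

        class FixedRng:
            calls = 0

            def random(self, n=None):
                self.calls += 1
                return np.full(n, 1.0 if self.calls == 1 else 0.9)

        f = exponential_term(1.0, 1, cfg, FixedRng())
        assert f[0] == pytest.approx(2.0 * (np.exp(-1) - 1), abs=1e-5)
        assert f[0] == pytest.approx(-1.26424, abs=1e-5)

    def test_exponential_term_bounded_by_a1(self, rng):
        cfg = EOConfig(a1=2.0)
        for t in (0.1, 0.5, 1.0):
            f = exponential_term(t, 1000, cfg, rng)
            assert (np.abs(f) < cfg.a1).all()
            assert (np.abs(f) <= cfg.a1 * (1 - np.exp(-t)) + 1e-12).all()

    def test_generation_rate_suppressed_below_gp(self, rng):
        cfg = EOConfig(generation_probability=1.0)  # g2 < 1 always
        g, _ = generation_rate(np.ones(4), np.zeros(4), np.ones(4), cfg, rng)
        np.testing.assert_array_equal(g, np.zeros(4))

    def test_generation_rate_zero_when_f_zero(self, rng):
        cfg = EOConfig(generation_probability=0.0)  # never suppressed
        g, _ = generation_rate(np.ones(4), np.zeros(4), np.zeros(4), cfg, rng)
        np.testing.assert_array_equal(g, np.zeros(4))

    def test_generation_rate_direct_value(self):
        cfg = EOConfig(generation_probability=0.0)

        class FixedRng:
            def random(self, n=None):
                return np.ones(n) if n is not None else 1.0

        g, gam = generation_rate(
            np.array([2.0]), np.array([1.0]), np.array([0.5]), cfg, FixedRng()
        )
        assert g[0] == pytest.approx(0.25)  # 0.5*1*(2-1)*0.5
        assert gam[0] == 1.0

    def test_update_identity_and_equilibrium_limits(self):
        cfg = EOConfig()
        bounds = Bounds(lower=np.full(3, -10.0), upper=np.full(3, 10.0))
        c = np.array([1.0, 2.0, 3.0])
        c_eq = np.array([-1.0, 0.0, 1.0])
        gam = np.full(3, 0.5)
        # F=1, G=0 -> stays at C
        out = update_concentration(c, c_eq, np.ones(3), np.zeros(3), gam, cfg, bounds)
        np.testing.assert_array_equal(out, c)
        # F=0, G=0 -> jumps to Ceq
        out = update_concentration(c, c_eq, np.zeros(3), np.zeros(3), gam, cfg, bounds)
        np.testing.assert_array_equal(out, c_eq)

    def test_update_direct_value(self):
        cfg = EOConfig(volume=1.0)
        bounds = Bounds(lower=np.array([-10.0]), upper=np.array([10.0]))
        out = update_concentration(
            np.array([1.0]), np.array([0.0]), np.array([0.5]),
            np.array([0.1]), np.array([0.5]), cfg, bounds,
        )
        assert out[0] == pytest.approx(0.6)

    def test_update_clips_into_bounds(self):
        cfg = EOConfig()
        bounds = unit_bounds(1)
        out = update_concentration(
            np.array([1.0]), np.array([0.5]), np.array([5.0]),
            np.array([0.0]), np.array([0.5]), cfg, bounds,
        )
        assert 0.0 <= out[0] <= 1.0


class TestMemorySaving:
    def test_keeps_improvement(self):
        p = Particle(np.array([1.0]), fitness=0.3,
                     previous_position=np.array([0.0]), previous_fitness=0.5)
        memory_save(p)
        assert p.fitness == 0.3 and p.previous_fitness == 0.3

    def test_reverts_worsening(self):
        p = Particle(np.array([1.0]), fitness=0.5,
                     previous_position=np.array([0.0]), previous_fitness=0.3)
        memory_save(p)
        assert p.fitness == 0.3
        np.testing.assert_array_equal(p.position, np.array([0.0]))


class TestRunEO:
    def test_constant_objective(self):
        bounds = unit_bounds(3)
        res = run_eo(lambda x: 4.2, bounds, EOConfig(population_size=6, max_iterations=5, seed=1))
        assert res.best_fitness == 4.2
        assert res.fitness_trace.size == 5

    def test_trace_non_increasing_and_positions_bounded(self):
        bounds = Bounds(lower=np.full(5, -10.0), upper=np.full(5, 10.0))
        cfg = EOConfig(population_size=12, max_iterations=30, seed=3)
        res = run_eo(lambda x: float(np.sum(x**2)), bounds, cfg)
        assert (np.diff(res.fitness_trace) <= 0).all()
        assert (np.abs(res.best_position) <= 10.0).all()

    def test_same_seed_reproduces_run(self):
        bounds = Bounds(lower=np.full(4, -5.0), upper=np.full(4, 5.0))
        cfg = EOConfig(population_size=8, max_iterations=15, seed=9)
        obj = lambda x: float(np.sum(np.abs(x)))
        a = run_eo(obj, bounds, cfg)
        b = run_eo(obj, bounds, cfg)
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.fitness_trace, b.fitness_trace)

    def test_gp_one_yields_pure_relaxation_progress(self):
        # with GP=1 the generation term is always zero; EO still improves
        bounds = Bounds(lower=np.full(4, -5.0), upper=np.full(4, 5.0))
        cfg = EOConfig(population_size=10, max_iterations=40, seed=2,
                       generation_probability=1.0)
        res = run_eo(lambda x: float(np.sum(x**2)), bounds, cfg)
        assert res.best_fitness < res.fitness_trace[0] or res.fitness_trace[0] == res.best_fitness
        assert (np.diff(res.fitness_trace) <= 0).all()

    def test_objective_error_propagates(self):
        def bad(x):
            raise RuntimeError("objective exploded")

        with pytest.raises(RuntimeError, match="objective exploded"):
            run_eo(bad, unit_bounds(2), EOConfig(population_size=5, max_iterations=2, seed=0))
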