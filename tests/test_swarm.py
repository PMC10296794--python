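"""Swarm optimizers: velocity rule, inertia schedule, Levy mental search,
boundedness, monotonicity, determinism, and the PSO-reduction property."""

import math

import numpy as np
import pytest

from swarmlp import benchmarks as B
from swarmlp.swarm import (MentalSearchDraw, SwarmConfig, apply_mental_search,
                           draw_levy_candidate, inertia_at, initialize_swarm,
                           optimize, update_velocity)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


def cfg2d(**kw):
    kw.setdefault("dimension", 2)
    kw.setdefault("bounds", (-5.0, 5.0))
    return SwarmConfig(**kw)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SwarmConfig(dimension=2, population_size=1)
        with pytest.raises(ValueError):
            SwarmConfig(dimension=2, beta_low=0.0)
        with pytest.raises(ValueError):
            SwarmConfig(dimension=2, bounds=(1.0, -1.0))
        with pytest.raises(ValueError):
            SwarmConfig(dimension=2, bounds=(0.0, np.inf))
        with pytest.raises(ValueError):
            SwarmConfig(dimension=2, v_max=0.0)

    def test_default_vmax_is_fifth_of_box(self):
        c = SwarmConfig(dimension=3, bounds=(-10.0, 10.0))
        assert np.allclose(c.v_max, 4.0)


class TestInertia:
    def test_endpoints_and_midpoint(self):
        assert inertia_at(0, 100, 0.9, 0.4) == pytest.approx(0.9)
        assert inertia_at(100, 100, 0.9, 0.4) == pytest.approx(0.4)
        assert inertia_at(50, 100, 0.9, 0.4) == pytest.approx(0.65)

    def test_zero_horizon_rejected(self):
        with pytest.raises(ValueError):
            inertia_at(0, 0, 0.9, 0.4)


class TestVelocity:
    def test_hand_computed_update(self):
        v = update_velocity(np.array([1.0]), np.array([0.0]), np.array([1.0]),
                            np.array([2.0]), 0.729, 1.49, 1.49,
                            r1=0.5, r2=0.5)
        assert v[0] == pytest.approx(2.964)

    def test_stationary_at_consensus(self, rng):
        x = np.ones(4)
        v = update_velocity(np.zeros(4), x, x, x, 0.7, 1.49, 1.49, rng)
        assert np.all(v == 0.0)

    def test_clamped_to_vmax(self, rng):
        v = update_velocity(np.full(3, 10.0), np.zeros(3), np.full(3, 5.0),
                            np.full(3, 5.0), 0.9, 2.0, 2.0, rng, v_max=0.1)
        assert np.all(np.abs(v) <= 0.1)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            update_velocity(np.zeros(3), np.zeros(2), np.zeros(2),
                            np.zeros(2), 0.7, 1.0, 1.0, rng)


class TestInitialization:
    def test_positions_within_bounds_many_seeds(self):
        c = cfg2d(population_size=10)
        lo, hi = c.bounds
        for seed in range(50):
            st = initialize_swarm(c, sphere, np.random.default_rng(seed))
            assert np.all(st.positions >= lo) and np.all(st.positions <= hi)
            assert np.all(st.velocities == 0.0)

    def test_constant_objective(self):
        st = initialize_swarm(cfg2d(), lambda x: 7.0, np.random.default_rng(0))
        assert st.gbest_fitness == 7.0
        assert np.all(st.pbest_fitness == 7.0)

    def test_same_seed_identical_state(self):
        a = initialize_swarm(cfg2d(), sphere, np.random.default_rng(3))
        b = initialize_swarm(cfg2d(), sphere, np.random.default_rng(3))
        assert np.array_equal(a.positions, b.positions)
        assert a.gbest_fitness == b.gbest_fitness


class TestLevyDraw:
    def test_draw_invariants(self, rng):
        c = cfg2d()
        for _ in range(200):
            d = draw_levy_candidate(np.array([1.0, -2.0]), c, rng)
            assert 0.0 < d.d <= 1.0 / math.sqrt(2.0 * math.pi)
            assert c.beta_low <= d.beta <= c.beta_high
            assert 0.0 < d.sigma <= 1.0
            lo, hi = c.bounds
            assert np.all(d.S >= lo) and np.all(d.S <= hi)

    def test_density_at_zero(self):
        # the normal density at mc=0 is 1/sqrt(2*pi)
        assert math.exp(0.0) / math.sqrt(2 * math.pi) == pytest.approx(0.39894, abs=1e-5)

    def test_sigma_at_beta_one(self):
        assert math.sin(math.pi * 1.0 / 2.0) == 1.0

    def test_candidate_scales_with_position(self, rng):
        # zero position => zero candidate (multiplicative step)
        c = cfg2d()
        d = draw_levy_candidate(np.zeros(2), c, rng)
        assert np.all(d.S == 0.0)

    def test_tail_heaviness_grows_as_beta_falls(self):
        """The |v|^(-1/beta) divisor makes SMALL distribution indices produce
        the heavy-tailed jumps: the 99th percentile of the step size at beta
        near the lower bound dominates the one near the upper bound."""
        def steps(lo, hi, n=10_000):
            rng = np.random.default_rng(123)
            c = SwarmConfig(dimension=1, bounds=(-1e9, 1e9),
                            beta_low=lo, beta_high=hi)
            return np.array([abs(draw_levy_candidate(np.array([1.0]), c, rng).S[0])
                             for _ in range(n)])
        q_low = np.percentile(steps(0.3, 0.3001), 99)
        q_high = np.percentile(steps(1.989, 1.99), 99)
        assert q_low > q_high

    def test_mantegna_flag_changes_scale_only(self, rng):
        c = cfg2d(mantegna_sigma=True)
        d = draw_levy_candidate(np.array([1.0, 1.0]), c, rng)
        assert d.sigma > 0.0
        assert np.all(np.isfinite(d.S))


class TestMentalSearch:
    def _state(self):
        c = cfg2d(population_size=3, seed=0)
        return c, initialize_swarm(c, sphere, np.random.default_rng(0))

    def _draw(self, S):
        return MentalSearchDraw(mc=0.0, d=0.4, beta=1.0, sigma=1.0,
                                u=np.zeros(2), v=np.ones(2), S=np.asarray(S))

    def test_candidate_accepted_when_best(self):
        c, st = self._state()
        st.fitness[0] = st.pbest_fitness[0] + 1.0  # current position is worse
        apply_mental_search(st, 0, self._draw([0.0, 0.0]), sphere)
        assert st.pbest_fitness[0] == 0.0
        assert np.all(st.pbest[0] == 0.0)

    def test_position_wins_over_candidate(self):
        c, st = self._state()
        st.positions[0] = np.array([0.1, 0.0])
        st.fitness[0] = sphere(st.positions[0])
        st.pbest_fitness[0] = 1.0
        apply_mental_search(st, 0, self._draw([0.0, 0.0]), sphere)
        # first branch: position replaces pbest even though S is fitter
        assert st.pbest_fitness[0] == pytest.approx(0.01)

    def test_no_improvement_keeps_incumbent(self):
        c, st = self._state()
        st.pbest_fitness[0] = -1.0  # unbeatable for the sphere
        pb = st.pbest[0].copy()
        apply_mental_search(st, 0, self._draw([0.0, 0.0]), sphere)
        assert st.pbest_fitness[0] == -1.0
        assert np.array_equal(st.pbest[0], pb)

    def test_nonfinite_candidate_rejected(self):
        c, st = self._state()
        st.fitness[0] = st.pbest_fitness[0] + 1.0
        before = st.pbest_fitness[0]
        apply_mental_search(st, 0, self._draw([0.0, 0.0]),
                            lambda x: float("inf"))
        assert st.pbest_fitness[0] == before


class TestOptimize:
    @pytest.mark.parametrize("algo", ["pso", "hms", "hms_pso"])
    def test_trace_monotone_and_bounded(self, algo):
        c = cfg2d(population_size=15, max_iterations=40, seed=7)
        r = optimize(sphere, c, algo)
        assert len(r.fitness_trace) == 40
        assert np.all(np.diff(r.fitness_trace) <= 0.0)
        lo, hi = c.bounds
        assert np.all(r.best_position >= lo) and np.all(r.best_position <= hi)

    @pytest.mark.parametrize("algo", ["pso", "hms", "hms_pso"])
    def test_same_seed_identical(self, algo):
        c = cfg2d(population_size=10, max_iterations=20, seed=11)
        a = optimize(sphere, c, algo)
        b = optimize(sphere, c, algo)
        assert np.array_equal(a.fitness_trace, b.fitness_trace)
        assert np.array_equal(a.best_position, b.best_position)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            optimize(sphere, cfg2d(), "genetic")

    @pytest.mark.parametrize("algo, cs, expected_factor", [
        ("pso", 1, 1), ("hms_pso", 1, 2), ("hms_pso", 2, 3),
    ])
    def test_evaluation_count(self, algo, cs, expected_factor):
        pop, iters = 8, 12
        c = cfg2d(population_size=pop, max_iterations=iters, seed=0,
                  candidates_per_particle=cs)
        r = optimize(sphere, c, algo)
        assert r.evaluation_count == pop * (1 + iters * expected_factor)

    @pytest.mark.parametrize("fid", ["branin", "six_hump", "matyas"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reduction_to_pso_without_mental_search(self, fid, seed):
        """Disabling the mental search makes the hybrid trajectory bitwise
        identical to plain PSO under a shared seed."""
        obj, lo, hi = B.make_objective(fid)
        kw = dict(dimension=2, bounds=(lo, hi), population_size=20,
                  max_iterations=30, seed=seed, mental_search_enabled=False)
        a = optimize(obj, SwarmConfig(**kw), "hms_pso")
        b = optimize(obj, SwarmConfig(**kw), "pso")
        assert np.array_equal(a.fitness_trace, b.fitness_trace)
        assert np.array_equal(a.best_position, b.best_position)
        assert a.evaluation_count == b.evaluation_count

    def test_hybrid_solves_2d_sphere(self):
        c = SwarmConfig(dimension=2, bounds=(-100.0, 100.0),
                        population_size=50, max_iterations=100, seed=5)
        r = optimize(sphere, c, "hms_pso")
        assert r.best_fitness < 1e-6

    def test_trace_csv_roundtrip(self, tmp_path):
        import pandas as pd
        r = optimize(sphere, cfg2d(population_size=10, max_iterations=10, seed=0))
        p = tmp_path / "trace.csv"
        r.trace_to_csv(p)
        df = pd.read_csv(p)
        assert list(df.columns) == ["iteration", "best_fitness", "mean_fitness"]
        assert np.allclose(df["best_fitness"], r.fitness_trace)

    def test_verified_2d_suite_reaches_oracle_minimum(self):
        """Best of a handful of seeded hybrid runs lands within 1e-3 of the
        grid-oracle minimum on every verified 2-D suite function."""
        for fid in B.list_suite():
            spec = B.get_spec(fid)
            if spec.dimension != 2 or not spec.verified:
                continue
            obj, lo, hi = B.make_objective(fid)
            oracle = B.locate_minimum_oracle(fid, 200, 2).value
            best = min(
                optimize(obj, SwarmConfig(dimension=2, bounds=(lo, hi),
                                          population_size=50,
                                          max_iterations=100, seed=s),
                         "hms_pso").best_fitness
                for s in (0, 1, 2, 3, 4))
            assert best <= oracle + 1e-3, fid
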