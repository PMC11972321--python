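"""PCSO operator contracts and optimizer invariants."""

import numpy as np
import pytest

from cardiopcso import benchmarks, pcso


def make_config(**kw):
    defaults = dict(dim=3, lower=-5.0, upper=5.0, pop_size=8, max_iters=30, seed=0)
    defaults.update(kw)
    return pcso.PCSOConfig(**defaults)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            make_config(pop_size=2)
        with pytest.raises(ValueError):
            make_config(max_iters=1)
        with pytest.raises(ValueError):
            make_config(lower=1.0, upper=-1.0)
        with pytest.raises(ValueError):
            make_config(lower=np.nan)


class TestAdaptiveM:
    @pytest.mark.parametrize("q,qmax,expected", [(0, 100, 1.0), (100, 100, 0.0), (50, 100, 0.5)])
    def test_endpoints_and_midpoint(self, q, qmax, expected):
        assert pcso.adaptive_M(q, qmax) == expected

    def test_closed_form_on_random_pairs(self, rng):
        for _ in range(100):
            qmax = int(rng.integers(1, 1000))
            q = int(rng.integers(0, qmax + 1))
            frac = q / qmax
            expected = 0.0 if frac == 1.0 else (1 - frac) ** (2 * frac)
            assert pcso.adaptive_M(q, qmax) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pcso.adaptive_M(-1, 10)
        with pytest.raises(ValueError):
            pcso.adaptive_M(11, 10)


class TestStepDistributions:
    def test_brownian_moments(self):
        rng = np.random.default_rng(0)
        draws = pcso.brownian_vector(100_000, rng)
        se = 1 / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se
        assert draws.var() == pytest.approx(1.0, abs=0.02)

    def test_levy_tail_index(self):
        # P(|step| > t) ~ t^(-alpha): log-log regression slope near -1.5
        rng = np.random.default_rng(1)
        draws = np.abs(pcso.levy_vector(100_000, 1.5, rng))
        ts = np.quantile(draws, [0.95, 0.97, 0.99, 0.995, 0.999])
        surv = np.array([(draws > t).mean() for t in ts])
        slope = np.polyfit(np.log(ts), np.log(surv), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.2)

    def test_fixed_state_reproducible(self):
        a = pcso.levy_vector(10, 1.5, np.random.default_rng(7))
        b = pcso.levy_vector(10, 1.5, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestInitPopulation:
    def test_zero_width_interval(self):
        cfg = make_config(lower=2.0, upper=2.0)
        swarm = pcso.init_population(cfg, benchmarks.sphere)
        np.testing.assert_array_equal(swarm.prey, np.full((8, 3), 2.0))

    def test_within_bounds_many_seeds(self):
        for seed in range(50):
            swarm = pcso.init_population(make_config(seed=seed), benchmarks.sphere)
            assert (swarm.prey >= -5).all() and (swarm.prey <= 5).all()

    def test_uniform_mean(self):
        cfg = make_config(dim=1, lower=0.0, upper=1.0, pop_size=10_000)
        swarm = pcso.init_population(cfg)
        se = np.sqrt(1 / 12 / 10_000)
        assert abs(swarm.prey.mean() - 0.5) < 3 * se


class TestPhaseDispatch:
    def test_thirds(self):
        qmax = 99
        phases = [pcso.phase_for(q, qmax) for q in range(1, qmax + 1)]
        assert phases[:32] == [1] * 32  # Q=1..32 < 33
        assert set(phases[33:65]) == {2}
        assert set(phases[66:]) == {3}

    def test_phase_steps_respect_bounds(self):
        cfg = make_config(seed=3)
        rng = np.random.default_rng(3)
        swarm = pcso.init_population(cfg, benchmarks.sphere)
        for q, step in [(1, pcso.phase1_step), (12, pcso.phase2_step), (25, pcso.phase3_step)]:
            swarm = step(swarm, q, cfg, rng)
            assert (swarm.prey >= cfg.lower).all() and (swarm.prey <= cfg.upper).all()

    def test_phase1_zero_constant_is_fixed_point(self):
        cfg = make_config(step_constant=0.0)
        rng = np.random.default_rng(0)
        swarm = pcso.init_population(cfg, benchmarks.sphere)
        before = swarm.prey.copy()
        pcso.phase1_step(swarm, 1, cfg, rng)
        np.testing.assert_array_equal(swarm.prey, before)

    def test_phase2_population_split(self):
        # tau=4: exactly 2 agents per branch; branch 2 frozen when M=0
        cfg = make_config(pop_size=4, max_iters=30)
        rng = np.random.default_rng(1)
        swarm = pcso.init_population(cfg, benchmarks.sphere)
        before = swarm.prey.copy()
        pcso.phase2_step(swarm, 30, cfg, rng)  # Q=Qmax -> M=0
        changed = np.any(swarm.prey != before, axis=1)
        assert not changed[2:].any()  # Brownian branch frozen by M=0


class TestRaidAndCrow:
    def test_raid_zero_mask_prob(self):
        cfg = make_config(mask_prob=0.0)
        pos = np.zeros(3)
        out = pcso.raid_jump(pos, cfg, 5, np.random.default_rng(0))
        np.testing.assert_array_equal(out, pos)

    def test_raid_M_zero(self):
        cfg = make_config(mask_prob=1.0)
        pos = np.ones(3)
        out = pcso.raid_jump(pos, cfg, cfg.max_iters, np.random.default_rng(0))
        np.testing.assert_array_equal(out, pos)

    def test_raid_perturbed_fraction(self):
        cfg = make_config(dim=10_000, mask_prob=0.2, pop_size=4)
        pos = np.zeros(10_000)
        out = pcso.raid_jump(pos, cfg, 1, np.random.default_rng(2))
        frac = (out != pos).mean()
        se = np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(frac - 0.2) < 3 * se

    def test_crow_fixed_points(self):
        rng = np.random.default_rng(0)
        pos = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(pcso.crow_step(pos, pos, 2.0, rng), pos)

    def test_crow_full_step_lands_on_memory(self):
        class OneRng:
            def random(self, *a):
                return 1.0

        pos = np.zeros(3)
        mem = np.array([1.0, -1.0, 2.0])
        out = pcso.crow_step(pos, mem, 1.0, OneRng())
        np.testing.assert_allclose(out, mem)

    def test_hybrid_midpoint_and_convexity(self):
        a, b = np.zeros(4), np.full(4, 2.0)
        np.testing.assert_array_equal(pcso.hybrid_update(a, b), np.ones(4))
        np.testing.assert_array_equal(pcso.hybrid_update(a, a), a)
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=6)
        h = pcso.hybrid_update(x, y)
        assert (h >= np.minimum(x, y) - 1e-12).all() and (h <= np.maximum(x, y) + 1e-12).all()
        with pytest.raises(ValueError):
            pcso.hybrid_update(np.zeros(2), np.zeros(3))


class TestOptimize:
    def test_constant_objective_flat_history(self):
        res = pcso.optimize(lambda x: 4.2, make_config())
        assert res.best_fitness == 4.2
        assert np.all(res.history == 4.2)

    def test_history_monotone_nonincreasing(self):
        res = pcso.optimize(benchmarks.rosenbrock, make_config(seed=5, max_iters=60))
        assert np.all(np.diff(res.history) <= 0)

    def test_bound_containment_at_every_evaluation(self):
        seen = []

        def obj(x):
            seen.append(x.copy())
            return benchmarks.sphere(x)

        cfg = make_config(lower=-1.0, upper=1.0, max_iters=20)
        pcso.optimize(obj, cfg)
        arr = np.array(seen)
        assert (arr >= -1.0).all() and (arr <= 1.0).all()

    def test_seeded_determinism(self):
        cfg = make_config(seed=11, max_iters=40)
        a = pcso.optimize(benchmarks.rastrigin, cfg)
        b = pcso.optimize(benchmarks.rastrigin, make_config(seed=11, max_iters=40))
        assert a.best_fitness == b.best_fitness
        np.testing.assert_array_equal(a.best_position, b.best_position)
        np.testing.assert_array_equal(a.history, b.history)

    def test_evaluation_count(self):
        cfg = make_config(max_iters=25)
        res = pcso.optimize(benchmarks.sphere, cfg)
        assert res.evaluations == cfg.pop_size * (cfg.max_iters + 1)
        assert res.n_iters == 25

    def test_nonfinite_objective_aborts_with_position(self):
        with pytest.raises(RuntimeError, match="non-finite"):
            pcso.optimize(lambda x: np.nan, make_config())

    def test_final_best_not_worse_than_initial(self):
        for seed in range(5):
            cfg = make_config(seed=seed, max_iters=30)
            swarm = pcso.init_population(cfg, benchmarks.sphere)
            res = pcso.optimize(benchmarks.sphere, cfg)
            assert res.best_fitness <= swarm.best_fitness

    def test_stagnation_early_stop(self):
        cfg = make_config(max_iters=500, stagnation_window=5)
        res = pcso.optimize(lambda x: 1.0, cfg)
        assert res.n_iters < 500
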