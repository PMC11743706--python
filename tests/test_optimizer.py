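"""The PSO-GA hybrid: component behaviour and hybrid-level invariants."""

import numpy as np
import pytest

from plantarstiff.network import NetworkArchitecture, forward
from plantarstiff.optimizer import (
    OptimizerConfig,
    _init_swarm,
    fitness_rmse,
    ga_run,
    optimize,
    optimize_network,
    pso_step,
)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestFitness:
    def test_perfect_predictor_zero(self, rng):
        arch = NetworkArchitecture(n_input=2, n_hidden=2, n_output=1)
        genome = rng.normal(size=arch.genome_length)
        X = rng.uniform(0, 1, (12, 2))
        y = forward(genome, arch, X)
        assert fitness_rmse(genome, arch, X, y) == 0.0

    def test_direct_rmse_evaluation(self):
        arch = NetworkArchitecture(n_input=1, n_hidden=1, n_output=1,
                                   hidden_activation="identity")
        # identity net predicting x itself: targets 0 at inputs 3 and 4
        genome = np.array([1.0, 0.0, 1.0, 0.0])
        X = np.array([[3.0], [4.0]])
        y = np.array([0.0, 0.0])
        assert fitness_rmse(genome, arch, X, y) == pytest.approx(np.sqrt(12.5))

    def test_invariant_to_sample_order(self, rng):
        arch = NetworkArchitecture(n_input=2, n_hidden=3, n_output=1)
        genome = rng.normal(size=arch.genome_length)
        X = rng.uniform(0, 1, (20, 2))
        y = rng.uniform(0, 1, 20)
        perm = rng.permutation(20)
        assert fitness_rmse(genome, arch, X, y) == pytest.approx(
            fitness_rmse(genome, arch, X[perm], y[perm]), rel=1e-12)

    def test_empty_training_set_rejected(self):
        arch = NetworkArchitecture(n_input=2, n_hidden=2, n_output=1)
        with pytest.raises(ValueError):
            fitness_rmse(np.zeros(arch.genome_length), arch,
                         np.empty((0, 2)), np.empty(0))


class TestPsoStep:
    def test_degenerate_coefficients_freeze_swarm(self, rng):
        cfg = OptimizerConfig(c1=0.0, c2=0.0, w_start=0.0, w_end=0.0, seed=0)
        state = _init_swarm(sphere, 5, cfg, rng)
        before = state.positions.copy()
        pso_step(state, cfg, 0, sphere, rng)
        assert np.max(np.abs(state.velocities)) == 0.0
        np.testing.assert_array_equal(state.positions, before)

    def test_particle_at_both_bests_is_stationary(self, rng):
        cfg = OptimizerConfig(pso_swarm_size=1, seed=0)
        state = _init_swarm(sphere, 4, cfg, rng)
        state.pbest_pos = state.positions.copy()
        state.gbest_pos = state.positions[0].copy()
        pso_step(state, cfg, 0, sphere, rng)
        np.testing.assert_array_equal(state.positions, state.pbest_pos)

    def test_velocities_respect_clamp(self, rng):
        cfg = OptimizerConfig(seed=1)
        state = _init_swarm(sphere, 8, cfg, rng)
        for it in range(10):
            pso_step(state, cfg, it, sphere, rng)
            assert np.max(np.abs(state.velocities)) <= cfg.velocity_max + 1e-12

    def test_positions_stay_in_box(self, rng):
        cfg = OptimizerConfig(seed=2)
        state = _init_swarm(sphere, 8, cfg, rng)
        for it in range(20):
            pso_step(state, cfg, it, sphere, rng)
            assert np.max(np.abs(state.positions)) <= cfg.position_bound

    def test_improves_sphere_in_most_seeds(self):
        """30 iterations of plain PSO beat the initial best on a 5-dim sphere."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cfg = OptimizerConfig(seed=seed)
            state = _init_swarm(sphere, 5, cfg, rng)
            initial_best = state.gbest_fit
            for it in range(cfg.pso_iterations):
                pso_step(state, cfg, it, sphere, rng)
            wins += state.gbest_fit < initial_best
        assert wins >= 95


class TestGaRun:
    def test_no_variation_operators_keep_population_static(self, rng):
        cfg = OptimizerConfig(crossover_rate=0.0, mutation_rate=0.0,
                              ga_generations=10)
        pop = rng.uniform(-1, 1, (5, 3))
        best, fit = ga_run(pop, cfg, sphere, rng)
        expected = pop[np.argmin([sphere(p) for p in pop])]
        np.testing.assert_array_equal(best, expected)

    def test_one_dim_quadratic_finds_optimum(self):
        """(x-0.3)^2 minimized within 0.1 in >=95/100 seeds (bounded box)."""
        target = 0.3

        def quad(x):
            return float((x[0] - target) ** 2)

        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cfg = OptimizerConfig(ga_generations=50, ga_accuracy=0.0, seed=seed)
            pop = rng.uniform(-1, 1, (5, 1))
            best, _ = ga_run(pop, cfg, quad, rng)
            hits += abs(best[0] - target) < 0.1
        assert hits >= 95

    def test_elitism_never_worsens_best(self, rng):
        cfg = OptimizerConfig(ga_generations=1, ga_accuracy=0.0)
        pop = rng.uniform(-1, 1, (5, 4))
        best_before = min(sphere(p) for p in pop)
        fits = []
        current = pop
        for _ in range(20):
            best, fit = ga_run(current, cfg, sphere, rng)
            fits.append(fit)
        assert all(f <= best_before + 1e-12 for f in fits)
        assert min(fits) <= fits[0]

    def test_empty_population_rejected(self, rng):
        with pytest.raises(ValueError):
            ga_run(np.empty((0, 3)), OptimizerConfig(), sphere, rng)


class TestOptimize:
    def test_trace_non_increasing_and_final_best(self):
        best, trace = optimize(sphere, 5, OptimizerConfig(seed=0))
        assert np.all(np.diff(trace) <= 0)
        assert trace[-1] <= trace[0]
        assert sphere(best) == pytest.approx(trace[-1])

    def test_same_seed_bit_identical(self):
        b1, t1 = optimize(sphere, 6, OptimizerConfig(seed=42))
        b2, t2 = optimize(sphere, 6, OptimizerConfig(seed=42))
        assert np.array_equal(b1, b2) and np.array_equal(t1, t2)

    def test_swarm_size_preserved_through_exchange(self, rng, monkeypatch):
        import plantarstiff.optimizer as opt

        sizes = []
        original = opt.pso_step

        def recording(state, *args, **kwargs):
            sizes.append(state.positions.shape[0])
            return original(state, *args, **kwargs)

        monkeypatch.setattr(opt, "pso_step", recording)
        opt.optimize(sphere, 4, OptimizerConfig(pso_iterations=10, seed=1))
        assert sizes == [5] * 10

    def test_trace_length_matches_iterations(self):
        _, trace = optimize(sphere, 3, OptimizerConfig(pso_iterations=7, seed=0))
        assert trace.size == 7

    def test_hybrid_beats_random_restart_median(self, linear_cohort):
        """PSO-GA init + training beats the median of random initializations."""
        from plantarstiff import network, preprocessing

        _, df = linear_cohort
        ds = preprocessing.dataset_from_frame(df)
        norm = preprocessing.fit_normalizer(ds)
        tr, _ = preprocessing.split(ds, preprocessing.SplitSpec(seed=0))
        X = preprocessing.normalize(tr.X, norm.x_min, norm.x_max)
        y = preprocessing.normalize(tr.y, norm.y_min, norm.y_max)
        arch = network.NetworkArchitecture()
        tcfg = network.TrainConfig(max_epochs=300)

        genome0, _ = optimize_network(
            arch, X, y, OptimizerConfig(pso_iterations=10, ga_generations=10, seed=5))
        _, hist = network.train(genome0, arch, X, y, tcfg)

        rng = np.random.default_rng(99)
        random_finals = []
        for _ in range(20):
            g0 = network.random_genome(arch, rng)
            _, h = network.train(g0, arch, X, y, tcfg)
            random_finals.append(h[-1])
        assert hist[-1] < np.median(random_finals)
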