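"""The 10-13-1 backpropagation network: sizing, forward, gradient, training."""

import numpy as np
import pytest

from plantarstiff.network import (
    NetworkArchitecture,
    TrainConfig,
    forward,
    gradient,
    hidden_node_count,
    mse_loss,
    pack_genome,
    random_genome,
    train,
    unpack_genome,
)


class TestHiddenNodeCount:
    def test_as_printed_default_gives_13(self):
        assert hidden_node_count(10, 1, a=2, form="as-printed") == 13

    def test_sqrt_variant(self):
        assert hidden_node_count(10, 1, a=9, form="sqrt") == 12

    def test_smallest_case(self):
        assert hidden_node_count(1, 1, a=1, form="as-printed") == 3

    @pytest.mark.parametrize("a", [0, 10])
    def test_constant_out_of_range(self, a):
        with pytest.raises(ValueError):
            hidden_node_count(10, 1, a=a)


def test_genome_length_for_10_13_1_is_157():
    assert NetworkArchitecture().genome_length == 157


def test_pack_unpack_round_trip(rng):
    arch = NetworkArchitecture(n_input=3, n_hidden=4, n_output=2)
    genome = rng.normal(size=arch.genome_length)
    assert np.array_equal(pack_genome(*unpack_genome(genome, arch)), genome)


class TestForward:
    def test_zero_genome_predicts_zero(self, rng):
        arch = NetworkArchitecture()
        x = rng.uniform(0, 1, 10)
        assert forward(np.zeros(157), arch, x)[0] == 0.0

    def test_identity_composition(self):
        arch = NetworkArchitecture(n_input=1, n_hidden=1, n_output=1,
                                   hidden_activation="identity")
        genome = np.array([1.0, 0.0, 1.0, 0.0])  # W1=1, b1=0, W2=1, b2=0
        x = np.array([[0.37]])
        assert forward(genome, arch, x)[0] == pytest.approx(0.37)

    def test_matches_scalar_per_neuron_oracle(self, rng):
        """Vectorized forward pass equals a per-neuron python-loop oracle."""
        for _ in range(20):
            arch = NetworkArchitecture(
                n_input=int(rng.integers(1, 6)), n_hidden=int(rng.integers(1, 7)),
                n_output=1)
            genome = rng.normal(size=arch.genome_length)
            W1, b1, W2, b2 = unpack_genome(genome, arch)
            x = rng.normal(size=arch.n_input)
            hidden = []
            for j in range(arch.n_hidden):
                z = b1[j]
                for i in range(arch.n_input):
                    z += W1[j, i] * x[i]
                hidden.append(np.tanh(z))
            out = b2[0]
            for j in range(arch.n_hidden):
                out += W2[0, j] * hidden[j]
            assert forward(genome, arch, x)[0] == pytest.approx(out, abs=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        arch = NetworkArchitecture()
        with pytest.raises(ValueError):
            forward(np.zeros(157), arch, rng.normal(size=(3, 9)))
        with pytest.raises(ValueError):
            forward(np.zeros(100), arch, rng.normal(size=10))


class TestGradient:
    def test_zero_at_perfect_fit(self, rng):
        arch = NetworkArchitecture(n_input=2, n_hidden=3, n_output=1)
        genome = rng.normal(size=arch.genome_length)
        X = rng.uniform(-1, 1, (15, 2))
        y = forward(genome, arch, X)
        assert np.max(np.abs(gradient(genome, arch, X, y))) < 1e-14

    def test_matches_central_finite_differences(self, rng):
        """Backprop vs central differences on random 3-4-1 nets."""
        arch = NetworkArchitecture(n_input=3, n_hidden=4, n_output=1)
        h = 1e-6
        for _ in range(20):
            genome = rng.normal(scale=0.5, size=arch.genome_length)
            X = rng.uniform(-1, 1, (8, 3))
            y = rng.uniform(-1, 1, 8)
            g = gradient(genome, arch, X, y)
            fd = np.empty_like(g)
            for k in range(genome.size):
                gp, gm = genome.copy(), genome.copy()
                gp[k] += h
                gm[k] -= h
                fd[k] = (mse_loss(gp, arch, X, y) - mse_loss(gm, arch, X, y)) / (2 * h)
            denom = max(np.linalg.norm(fd), 1e-12)
            assert np.linalg.norm(g - fd) / denom <= 1e-6

    def test_mean_normalization_invariant_to_duplication(self, rng):
        arch = NetworkArchitecture(n_input=2, n_hidden=2, n_output=1)
        genome = rng.normal(size=arch.genome_length)
        X = rng.uniform(-1, 1, (6, 2))
        y = rng.uniform(-1, 1, 6)
        g1 = gradient(genome, arch, X, y)
        g2 = gradient(genome, arch, np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(g1, g2, atol=1e-14)


class TestTrain:
    def test_already_optimal_start_stops_immediately(self, rng):
        arch = NetworkArchitecture(n_input=2, n_hidden=2, n_output=1)
        genome = rng.normal(size=arch.genome_length)
        X = rng.uniform(-1, 1, (10, 2))
        y = forward(genome, arch, X)
        final, history = train(genome, arch, X, y, TrainConfig(max_epochs=100))
        assert history[0] <= 1e-20
        assert len(history) == 1
        assert np.array_equal(final, genome)

    def test_linear_toy_recovers_slope(self):
        """y = 0.5 x learned to 1e-3 by the composite linear weight."""
        arch = NetworkArchitecture(n_input=1, n_hidden=1, n_output=1,
                                   hidden_activation="identity")
        X = np.linspace(-1, 1, 50)[:, None]
        y = 0.5 * X[:, 0]
        genome0 = np.array([0.8, 0.0, 0.8, 0.0])
        final, history = train(
            genome0, arch, X, y,
            TrainConfig(max_epochs=8000, goal_mse=1e-12, learning_rate=0.05))
        W1, b1, W2, b2 = np.split(final, [1, 2, 3])
        assert float(W1[0] * W2[0]) == pytest.approx(0.5, abs=1e-3)

    def test_loss_non_increasing_on_convex_problem(self, rng):
        arch = NetworkArchitecture(n_input=3, n_hidden=2, n_output=1,
                                   hidden_activation="identity")
        X = rng.uniform(-1, 1, (30, 3))
        y = X @ np.array([0.2, -0.1, 0.3])
        genome0 = rng.normal(scale=0.1, size=arch.genome_length)
        _, history = train(genome0, arch, X, y,
                           TrainConfig(max_epochs=300, learning_rate=0.01))
        assert np.all(np.diff(history) <= 1e-12)

    def test_empty_training_set_rejected(self, rng):
        arch = NetworkArchitecture(n_input=2, n_hidden=2, n_output=1)
        with pytest.raises(ValueError):
            train(rng.normal(size=arch.genome_length), arch,
                  np.empty((0, 2)), np.empty(0))
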