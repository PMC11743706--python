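"""The three-layer multi-input single-output backpropagation regression net.

Architecture 10-13-1: ten regional-pressure inputs, a hidden layer sized by
the empirical rule ``hidden = input + output + a`` (a in [1, 9]; the
default a = 2 gives 13), one linear output.  Hidden activation is tanh by
default (logistic available).  Training is plain full-batch gradient
descent on the mean-squared error of the normalized data — learning rate
0.01, at most 8000 epochs, stopping early when the MSE reaches 1e-6 — with
the initial weights and biases supplied by the hybrid PSO-GA optimizer as a
flat genome.

Genome layout (fixed so the optimizer and the network agree bit-exactly):
``[W1 rows by hidden unit (n_hidden x n_input, C order), b1 (n_hidden),
W2 (n_output x n_hidden, C order), b2 (n_output)]`` — length 157 for
10-13-1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkArchitecture",
    "TrainConfig",
    "hidden_node_count",
    "random_genome",
    "unpack_genome",
    "pack_genome",
    "forward",
    "mse_loss",
    "gradient",
    "train",
]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "logistic": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda z: (s := 1.0 / (1.0 + np.exp(-z))) * (1.0 - s),
    ),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def hidden_node_count(
    n_input: int, n_output: int, a: int = 2, form: str = "as-printed"
) -> int:
    """Empirical hidden-layer sizing rule.

    ``as-printed``: hidden = n_input + n_output + a.  ``sqrt``: hidden =
    round(sqrt(n_input + n_output)) + a, the more common textbook variant.
    ``a`` is an integer constant in [1, 9].  The default (as-printed,
    a = 2) yields 13 hidden nodes for a 10-input 1-output regression net.
    """
    if not 1 <= a <= 9:
        raise ValueError("a must be in [1, 9]")
    if form == "as-printed":
        return n_input + n_output + a
    if form == "sqrt":
        return int(round(np.sqrt(n_input + n_output))) + a
    raise ValueError("form must be 'as-printed' or 'sqrt'")


@dataclass
class NetworkArchitecture:
    n_input: int = 10
    n_hidden: int = 13
    n_output: int = 1
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be >= 1")
        for name in (self.hidden_activation, self.output_activation):
            if name not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {name!r}")

    @property
    def genome_length(self) -> int:
        return (self.n_input * self.n_hidden + self.n_hidden
                + self.n_hidden * self.n_output + self.n_output)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_hidden": self.n_hidden,
            "n_output": self.n_output,
            "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkArchitecture":
        return cls(**d)


@dataclass
class TrainConfig:
    max_epochs: int = 8000
    goal_mse: float = 1e-6  # on the normalized scale
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.goal_mse <= 0 or self.learning_rate <= 0:
            raise ValueError("TrainConfig values must be positive")

    def to_dict(self) -> dict:
        return {"max_epochs": self.max_epochs, "goal_mse": self.goal_mse,
                "learning_rate": self.learning_rate}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


def random_genome(arch: NetworkArchitecture, rng: np.random.Generator,
                  bound: float = 1.0) -> np.ndarray:
    """Uniform genome in [-bound, bound], the optimizer's search box."""
    return rng.uniform(-bound, bound, arch.genome_length)


def unpack_genome(genome: np.ndarray, arch: NetworkArchitecture):
    """Split a flat genome into (W1, b1, W2, b2)."""
    genome = np.asarray(genome, dtype=float)
    if genome.shape != (arch.genome_length,):
        raise ValueError(
            f"genome length {genome.shape} does not match architecture "
            f"({arch.genome_length})"
        )
    i, h, o = arch.n_input, arch.n_hidden, arch.n_output
    pos = 0
    W1 = genome[pos:pos + h * i].reshape(h, i); pos += h * i
    b1 = genome[pos:pos + h]; pos += h
    W2 = genome[pos:pos + o * h].reshape(o, h); pos += o * h
    b2 = genome[pos:pos + o]
    return W1, b1, W2, b2


def pack_genome(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([np.ravel(W1), np.ravel(b1), np.ravel(W2), np.ravel(b2)])


def forward(genome: np.ndarray, arch: NetworkArchitecture, X: np.ndarray) -> np.ndarray:
    """Network prediction on normalized inputs.

    ``X`` may be a single input vector or an (n, n_input) matrix; returns a
    scalar prediction per row (for n_output = 1) or an (n, n_output) array.
    """
    W1, b1, W2, b2 = unpack_genome(genome, arch)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != arch.n_input:
        raise ValueError(f"expected {arch.n_input} input features, got {X.shape[1]}")
    act_h = _ACTIVATIONS[arch.hidden_activation][0]
    act_o = _ACTIVATIONS[arch.output_activation][0]
    H = act_h(X @ W1.T + b1)
    Y = act_o(H @ W2.T + b2)
    return Y[:, 0] if arch.n_output == 1 else Y


def mse_loss(genome, arch, X, y) -> float:
    """Mean squared error of the network on (X, y), normalized scale."""
    pred = forward(genome, arch, X)
    y = np.asarray(y, dtype=float)
    return float(np.mean((pred - y) ** 2))


def gradient(genome: np.ndarray, arch: NetworkArchitecture,
             X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic gradient of the MSE with respect to the flat genome.

    Standard backpropagation through the two layers; the loss is
    ``(1/n) sum (y_hat - y)^2`` so the gradient is invariant to duplicating
    the dataset.
    """
    W1, b1, W2, b2 = unpack_genome(genome, arch)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if arch.n_output == 1 and y.ndim == 1:
        Y = y[:, None]
    else:
        Y = np.atleast_2d(y)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty dataset")

    act_h, dact_h = _ACTIVATIONS[arch.hidden_activation]
    act_o, dact_o = _ACTIVATIONS[arch.output_activation]

    Z1 = X @ W1.T + b1
    H = act_h(Z1)
    Z2 = H @ W2.T + b2
    P = act_o(Z2)

    # dL/dP = 2 (P - Y) / (n * n_output-summed); loss averages over samples
    delta2 = 2.0 * (P - Y) / n * dact_o(Z2)      # (n, o)
    gW2 = delta2.T @ H                            # (o, h)
    gb2 = delta2.sum(axis=0)                      # (o,)
    delta1 = (delta2 @ W2) * dact_h(Z1)           # (n, h)
    gW1 = delta1.T @ X                            # (h, i)
    gb1 = delta1.sum(axis=0)                      # (h,)
    return pack_genome(gW1, gb1, gW2, gb2)


def train(
    genome0: np.ndarray,
    arch: NetworkArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-batch gradient descent from ``genome0``.

    Returns the final genome and the per-epoch loss history (the first
    entry is the loss of ``genome0``).  Stops when the MSE reaches
    ``goal_mse`` or after ``max_epochs`` updates.  Fully deterministic.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    genome = np.asarray(genome0, dtype=float).copy()
    history = [mse_loss(genome, arch, X, y)]
    for _ in range(cfg.max_epochs):
        if history[-1] <= cfg.goal_mse:
            break
        genome -= cfg.learning_rate * gradient(genome, arch, X, y)
        history.append(mse_loss(genome, arch, X, y))
    return genome, np.asarray(history)


def save_genome(path, genome: np.ndarray, arch: NetworkArchitecture) -> None:
    Path(path).write_text(json.dumps(
        {"architecture": arch.to_dict(), "genome": np.asarray(genome).tolist()},
        indent=2))


def load_genome(path) -> tuple[np.ndarray, NetworkArchitecture]:
    d = json.loads(Path(path).read_text())
    arch = NetworkArchitecture.from_dict(d["architecture"])
    return np.asarray(d["genome"], dtype=float), arch
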