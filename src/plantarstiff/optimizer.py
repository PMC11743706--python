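"""Hybrid particle-swarm / genetic-algorithm genome initializer.

The network's initial weights and biases are found by minimizing the
training-set RMSE (the fitness, computed on the normalized scale) over the
157-dimensional genome space with a small particle swarm (5 particles,
30 iterations, c1 = c2 = 4.5) that embeds a genetic algorithm: each PSO
iteration, a GA (population 5, up to 50 generations, arithmetic crossover
at rate 0.4, tournament selection, Gaussian mutation, elitism of 1) is run
on a copy of the current particle positions, and its best individual
replaces the swarm's worst particle (with its velocity reset to zero).

Two stabilizers make the aggressive acceleration coefficients usable: the
inertia weight decreases linearly from 0.9 to 0.4 over the iterations, and
velocities are clamped to half the position range with reflecting bounds
at +/-1 (the weight scale appropriate for data normalized to (0, 1)).
Without them, c1 = c2 = 4.5 sits far outside the classical PSO stability
region and the swarm diverges.

The GA's "accuracy" parameter (1e-6) is its early-stop tolerance: the GA
halts when the best fitness improves by less than this over a generation.

`optimize` works on any fitness function over a box, which is how the
property tests exercise it on analytic surrogates; `optimize_network` binds
it to the network-RMSE fitness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .network import NetworkArchitecture, forward

__all__ = [
    "OptimizerConfig",
    "fitness_rmse",
    "pso_step",
    "ga_run",
    "optimize",
    "optimize_network",
]


@dataclass
class OptimizerConfig:
    """Hybrid optimizer parameters.

    The first eight fields default to the standard parameterization of
    this hybrid (iterations 30, learning factors 4.5/4.5, swarm 5;
    GA generations 50, population 5, accuracy 1e-6, crossover 0.4); the
    rest are the constants the scheme leaves open, each a documented knob.
    """

    pso_iterations: int = 30
    c1: float = 4.5              # individual learning factor
    c2: float = 4.5              # population learning factor
    pso_swarm_size: int = 5
    ga_generations: int = 50
    ga_population: int = 5
    ga_accuracy: float = 1e-6    # GA early-stop tolerance on best fitness
    crossover_rate: float = 0.4
    mutation_rate: float = 0.1
    w_start: float = 0.9         # linear inertia-weight schedule
    w_end: float = 0.4
    position_bound: float = 1.0  # search box is [-bound, bound]^dim
    velocity_clamp_fraction: float = 0.5   # of the position range (2*bound)
    mutation_sigma_fraction: float = 0.1   # of the position range
    tournament_k: int = 2
    elitism: int = 1
    ga_seeding: str = "swarm"    # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.pso_iterations, self.pso_swarm_size, self.ga_generations,
                  self.ga_population, self.tournament_k)
        if min(counts) < 1:
            raise ValueError("all counts must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.position_bound <= 0 or self.velocity_clamp_fraction <= 0:
            raise ValueError("position_bound and velocity clamp must be positive")
        if self.ga_accuracy < 0 or self.elitism < 0:
            raise ValueError("ga_accuracy and elitism must be non-negative")
        if self.ga_seeding not in ("swarm", "random"):
            raise ValueError("ga_seeding must be 'swarm' or 'random'")

    @property
    def velocity_max(self) -> float:
        return self.velocity_clamp_fraction * 2.0 * self.position_bound

    @property
    def mutation_sigma(self) -> float:
        return self.mutation_sigma_fraction * 2.0 * self.position_bound

    def inertia_weight(self, iteration: int) -> float:
        """Linearly decreasing inertia weight for `iteration` in [0, n-1]."""
        if self.pso_iterations == 1:
            return self.w_start
        frac = iteration / (self.pso_iterations - 1)
        return self.w_start + (self.w_end - self.w_start) * frac

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OptimizerConfig":
        return cls(**d)


def fitness_rmse(genome: np.ndarray, arch: NetworkArchitecture,
                 X: np.ndarray, y: np.ndarray) -> float:
    """Fitness of a genome: RMSE of its network on the training set.

    ``sqrt((1/n_t) * sum (t_m - t_hat_m)^2)`` on the normalized scale.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty training set")
    pred = forward(genome, arch, X)
    return float(np.sqrt(np.mean((y - pred) ** 2)))


@dataclass
class _SwarmState:
    positions: np.ndarray       # (S, D)
    velocities: np.ndarray      # (S, D)
    fitness: np.ndarray         # (S,)
    pbest_pos: np.ndarray       # (S, D)
    pbest_fit: np.ndarray       # (S,)
    gbest_pos: np.ndarray       # (D,)
    gbest_fit: float


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    return np.array([fitness_fn(p) for p in positions])


def _init_swarm(fitness_fn, dim: int, cfg: OptimizerConfig,
                rng: np.random.Generator) -> _SwarmState:
    b = cfg.position_bound
    pos = rng.uniform(-b, b, (cfg.pso_swarm_size, dim))
    vel = np.zeros_like(pos)
    fit = _evaluate(fitness_fn, pos)
    best = int(np.argmin(fit))
    return _SwarmState(pos, vel, fit, pos.copy(), fit.copy(),
                       pos[best].copy(), float(fit[best]))


def _reflect(pos: np.ndarray, vel: np.ndarray, bound: float) -> None:
    """Reflect positions at the box walls in place, flipping velocity."""
    for _ in range(2):  # a particle can overshoot both walls once each
        over = pos > bound
        pos[over] = 2.0 * bound - pos[over]
        vel[over] *= -1.0
        under = pos < -bound
        pos[under] = -2.0 * bound - pos[under]
        vel[under] *= -1.0
    np.clip(pos, -bound, bound, out=pos)


def pso_step(state: _SwarmState, cfg: OptimizerConfig, iteration: int,
             fitness_fn: Callable[[np.ndarray], float],
             rng: np.random.Generator) -> None:
    """One PSO velocity/position update with best bookkeeping (in place).

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x), clamped; x <- x + v,
    reflected at the box walls.
    """
    w = cfg.inertia_weight(iteration)
    shape = state.positions.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    state.velocities = (
        w * state.velocities
        + cfg.c1 * r1 * (state.pbest_pos - state.positions)
        + cfg.c2 * r2 * (state.gbest_pos - state.positions)
    )
    np.clip(state.velocities, -cfg.velocity_max, cfg.velocity_max,
            out=state.velocities)
    state.positions = state.positions + state.velocities
    _reflect(state.positions, state.velocities, cfg.position_bound)

    state.fitness = _evaluate(fitness_fn, state.positions)
    improved = state.fitness < state.pbest_fit
    state.pbest_pos[improved] = state.positions[improved]
    state.pbest_fit[improved] = state.fitness[improved]
    best = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[best] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[best])
        state.gbest_pos = state.pbest_pos[best].copy()


def ga_run(seed_population: np.ndarray, cfg: OptimizerConfig,
           fitness_fn: Callable[[np.ndarray], float],
           rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Real-coded GA: tournament selection, arithmetic crossover, Gaussian mutation.

    Runs at most ``ga_generations`` generations with elitism, early-stopping
    when the best fitness improves by less than ``ga_accuracy`` over one
    generation.  Returns the best individual and its fitness.
    """
    pop = np.array(seed_population, dtype=float)
    if pop.ndim != 2 or pop.shape[0] == 0:
        raise ValueError("seed population must be a non-empty 2-D array")
    if pop.shape[0] != cfg.ga_population:
        # resize by cycling / truncating the seeds
        idx = np.resize(np.arange(pop.shape[0]), cfg.ga_population)
        pop = pop[idx].copy()
    fit = _evaluate(fitness_fn, pop)

    def tournament() -> np.ndarray:
        contenders = rng.integers(0, pop.shape[0], cfg.tournament_k)
        return pop[contenders[np.argmin(fit[contenders])]]

    for _ in range(cfg.ga_generations):
        prev_best = float(fit.min())
        elite_idx = np.argsort(fit)[:cfg.elitism]
        children = [pop[i].copy() for i in elite_idx]
        while len(children) < pop.shape[0]:
            p1, p2 = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                u = rng.random()
                child = u * p1 + (1.0 - u) * p2
            else:
                child = p1.copy()
            mask = rng.random(child.size) < cfg.mutation_rate
            child[mask] += rng.normal(0.0, cfg.mutation_sigma, int(mask.sum()))
            np.clip(child, -cfg.position_bound, cfg.position_bound, out=child)
            children.append(child)
        pop = np.array(children)
        fit = _evaluate(fitness_fn, pop)
        if prev_best - float(fit.min()) < cfg.ga_accuracy:
            break
    best = int(np.argmin(fit))
    return pop[best].copy(), float(fit[best])


def optimize(fitness_fn: Callable[[np.ndarray], float], dim: int,
             cfg: OptimizerConfig | None = None,
             rng: np.random.Generator | None = None,
             ) -> tuple[np.ndarray, np.ndarray]:
    """Run the full PSO-GA hybrid on an arbitrary fitness function.

    Per iteration: (1) PSO step; (2) GA on a copy of the current particle
    positions (or a fresh random population with ``ga_seeding='random'``);
    (3) the GA best replaces the worst particle, velocity reset to zero.
    Returns the best genome found and the per-iteration global-best fitness
    trace (non-increasing by construction; length ``pso_iterations``).
    """
    cfg = cfg or OptimizerConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = _init_swarm(fitness_fn, dim, cfg, rng)
    trace = np.empty(cfg.pso_iterations)

    for it in range(cfg.pso_iterations):
        pso_step(state, cfg, it, fitness_fn, rng)

        if cfg.ga_seeding == "swarm":
            seeds = state.positions.copy()
        else:
            seeds = rng.uniform(-cfg.position_bound, cfg.position_bound,
                                (cfg.ga_population, dim))
        ga_best, ga_fit = ga_run(seeds, cfg, fitness_fn, rng)

        worst = int(np.argmax(state.fitness))
        state.positions[worst] = ga_best
        state.velocities[worst] = 0.0
        state.fitness[worst] = ga_fit
        if ga_fit < state.pbest_fit[worst]:
            state.pbest_pos[worst] = ga_best.copy()
            state.pbest_fit[worst] = ga_fit
        if ga_fit < state.gbest_fit:
            state.gbest_fit = ga_fit
            state.gbest_pos = ga_best.copy()
        trace[it] = state.gbest_fit

    return state.gbest_pos.copy(), trace


def optimize_network(arch: NetworkArchitecture, train_X: np.ndarray,
                     train_y: np.ndarray, cfg: OptimizerConfig | None = None,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """PSO-GA search for the network genome minimizing training RMSE."""
    cfg = cfg or OptimizerConfig()
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    train_y = np.asarray(train_y, dtype=float)
    if train_y.size == 0:
        raise ValueError("empty training set")

    def fn(genome: np.ndarray) -> float:
        return fitness_rmse(genome, arch, train_X, train_y)

    return optimize(fn, arch.genome_length, cfg, rng)
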