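"""Equilibrium Optimizer (EO) for box-bounded continuous minimisation.

EO is a physics-inspired metaheuristic derived from a control-volume mass
balance: candidate solutions ("concentrations") relax toward an equilibrium
pool made of the best solutions found so far plus their mean.  Each particle
is pulled toward a randomly chosen pool candidate through an exponential
decay term ``F`` and perturbed by a mass-generation term ``G`` that sharpens
local search late in the run.

The implementation is a plain minimiser over a box: it knows nothing about
SVMs or feature masks.  The wrapper in :mod:`svmeo.selection` supplies the
objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EOConfig",
    "Bounds",
    "Particle",
    "EquilibriumPool",
    "EOResult",
    "initialize_population",
    "update_equilibrium_pool",
    "time_coefficient",
    "exponential_term",
    "generation_rate",
    "update_concentration",
    "memory_save",
    "run_eo",
]


@dataclass(frozen=True)
class EOConfig:
    """Constants governing the EO dynamics.

    Parameters
    ----------
    volume : float
        Control volume ``V`` in the mass-balance update (default 1).
    a1, a2 : float
        Exploration weight of the exponential term and the decay rate of
        the time coefficient (defaults 2 and 1).
    max_iterations : int
        Number of main-loop iterations.
    generation_probability : float
        Probability ``GP`` that the mass-generation term is suppressed for
        a particle in an iteration (default 0.5).
    population_size : int
        Number of particles; must be at least 5 so the equilibrium pool
        (4 bests + mean) is well defined.
    seed : int or None
        Seed for the run's random stream when :func:`run_eo` is not handed
        an explicit generator.
    """

    volume: float = 1.0
    a1: float = 2.0
    a2: float = 1.0
    max_iterations: int = 100
    generation_probability: float = 0.5
    population_size: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 5:
            raise ValueError(
                "population_size must be >= 5 (equilibrium pool needs 4 "
                f"bests plus their mean), got {self.population_size}"
            )
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.generation_probability <= 1.0:
            raise ValueError("generation_probability must lie in [0, 1]")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass(frozen=True)
class Bounds:
    """Per-dimension box constraints ``lower[j] < upper[j]``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-D arrays of equal length")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise ValueError("bounds must be finite")
        if not (lower < upper).all():
            raise ValueError("every lower bound must be strictly below its upper bound")

    @property
    def dimension(self) -> int:
        return self.lower.size

    def clip(self, position: np.ndarray) -> np.ndarray:
        return np.clip(position, self.lower, self.upper)


@dataclass
class Particle:
    """A candidate solution with one slot of memory.

    ``previous_*`` hold the particle's state from the previous iteration;
    :func:`memory_save` reverts the particle when the move made it worse.
    """

    position: np.ndarray
    fitness: float | None = None
    previous_position: np.ndarray | None = None
    previous_fitness: float | None = None


@dataclass(frozen=True)
class EquilibriumPool:
    """The 4 best population members plus their component-wise mean.

    The mean candidate is an attractor only and is never evaluated, so its
    fitness slot holds NaN.
    """

    candidates: tuple
    fitnesses: tuple

    def __post_init__(self) -> None:
        if len(self.candidates) != 5 or len(self.fitnesses) != 5:
            raise ValueError("equilibrium pool must hold exactly 5 candidates")

    @property
    def best_position(self) -> np.ndarray:
        return self.candidates[0]

    @property
    def best_fitness(self) -> float:
        return self.fitnesses[0]


@dataclass(frozen=True)
class EOResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray


def initialize_population(
    bounds: Bounds, config: EOConfig, rng: np.random.Generator
) -> list[Particle]:
    """Draw ``population_size`` particles uniformly inside the box.

    Every dimension j is ``lower[j] + u * (upper[j] - lower[j])`` with u
    uniform on [0, 1]; fitness is left unset.
    """
    span = bounds.upper - bounds.lower
    positions = bounds.lower + rng.random((config.population_size, bounds.dimension)) * span
    return [Particle(position=positions[i].copy()) for i in range(config.population_size)]


def update_equilibrium_pool(
    population: Sequence[Particle], pool: EquilibriumPool | None = None
) -> EquilibriumPool:
    """Build the pool: 4 lowest-fitness particles plus their mean.

    Ties are broken by particle index (stable sort), so the pool is fully
    deterministic.  Because every particle carries memory saving, the
    current population already holds each particle's best state, making
    this equal to a best-so-far pool inside :func:`run_eo`.  The ``pool``
    argument is accepted for signature symmetry but the result depends on
    the population alone.
    """
    for i, p in enumerate(population):
        if p.fitness is None or not np.isfinite(p.fitness):
            raise RuntimeError(f"particle {i} has no finite fitness; evaluate before pooling")
    order = sorted(range(len(population)), key=lambda i: (population[i].fitness, i))
    best = [population[i] for i in order[:4]]
    mean = np.mean([p.position for p in best], axis=0)
    candidates = tuple(p.position.copy() for p in best) + (mean,)
    fitnesses = tuple(float(p.fitness) for p in best) + (float("nan"),)
    return EquilibriumPool(candidates=candidates, fitnesses=fitnesses)


def time_coefficient(iteration: int, config: EOConfig) -> float:
    """Nonlinear clock ``t = (1 - Ite/Itemax)^(a2 * Ite/Itemax)``.

    Decays from 1 at iteration 0 to 0 at the final iteration, shifting the
    dynamics from exploration to exploitation.
    """
    if not 0 <= iteration <= config.max_iterations:
        raise ValueError("iteration must lie in [0, max_iterations]")
    frac = iteration / config.max_iterations
    return float((1.0 - frac) ** (config.a2 * frac))


def exponential_term(
    t: float, dimension: int, config: EOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Exponential decay coefficient ``F = a1 * sign(r - 0.5) * (e^(-lam*t) - 1)``.

    ``lam`` and ``r`` are fresh uniform [0,1) vectors per call.  Since
    ``e^(-lam*t) - 1 <= 0``, each component's sign is the opposite of
    ``sign(r - 0.5)`` and ``|F| < a1``.
    """
    lam = rng.random(dimension)
    r = rng.random(dimension)
    return config.a1 * np.sign(r - 0.5) * (np.exp(-lam * t) - 1.0)


def generation_rate(
    c_eq: np.ndarray,
    c: np.ndarray,
    f: np.ndarray,
    config: EOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mass-generation term ``G`` and the flow-rate vector it used.

    ``G = 0.5 * g1 * (Ceq - gam * C) * F`` when ``g2 >= GP``, else the zero
    vector; ``g1, g2`` are uniform scalars and ``gam`` a uniform vector.
    ``gam`` is returned because the concentration update divides by the
    same vector.
    """
    gam = rng.random(c.size)
    g1 = rng.random()
    g2 = rng.random()
    if g2 >= config.generation_probability:
        g = 0.5 * g1 * (c_eq - gam * c) * f
    else:
        g = np.zeros_like(c)
    return g, gam


def update_concentration(
    c: np.ndarray,
    c_eq: np.ndarray,
    f: np.ndarray,
    g: np.ndarray,
    gam: np.ndarray,
    config: EOConfig,
    bounds: Bounds,
) -> np.ndarray:
    """Mass-balance move ``C' = Ceq + (C - Ceq)*F + G/(gam*V) * (1 - F)``.

    The result is clipped into the box.  Components with ``gam == 0`` drop
    the generation term rather than dividing by zero.
    """
    gen = np.divide(
        g * (1.0 - f),
        gam * config.volume,
        out=np.zeros_like(g),
        where=gam > 0,
    )
    return bounds.clip(c_eq + (c - c_eq) * f + gen)


def memory_save(particle: Particle) -> Particle:
    """Keep the better of a particle's current and previous states.

    Mutates and returns the particle: if the previous fitness was strictly
    better the move is undone, otherwise the memory slots are overwritten
    with the current state.
    """
    if particle.fitness is None or particle.previous_fitness is None:
        raise RuntimeError("memory_save requires both current and previous fitness")
    if particle.previous_fitness < particle.fitness:
        particle.position = particle.previous_position.copy()
        particle.fitness = particle.previous_fitness
    else:
        particle.previous_position = particle.position.copy()
        particle.previous_fitness = particle.fitness
    return particle


def run_eo(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    config: EOConfig,
    rng: np.random.Generator | None = None,
) -> EOResult:
    """Minimise ``objective`` over the box with the full EO loop.

    Returns the best position and fitness over every evaluation made, plus
    a best-so-far trace of length ``max_iterations`` (non-increasing by
    construction of memory saving and the pool).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    population = initialize_population(bounds, config, rng)
    for p in population:
        p.fitness = float(objective(p.position))
        p.previous_position = p.position.copy()
        p.previous_fitness = p.fitness

    best_idx = min(range(len(population)), key=lambda i: (population[i].fitness, i))
    best_position = population[best_idx].position.copy()
    best_fitness = population[best_idx].fitness

    dim = bounds.dimension
    trace = np.empty(config.max_iterations)
    for ite in range(1, config.max_iterations + 1):
        pool = update_equilibrium_pool(population)
        t = time_coefficient(ite, config)
        for p in population:
            c_eq = pool.candidates[rng.integers(5)]
            f = exponential_term(t, dim, config, rng)
            g, gam = generation_rate(c_eq, p.position, f, config, rng)
            new_position = update_concentration(p.position, c_eq, f, g, gam, config, bounds)
            p.previous_position = p.position
            p.previous_fitness = p.fitness
            p.position = new_position
            p.fitness = float(objective(new_position))
            memory_save(p)
            if p.fitness < best_fitness:
                best_fitness = p.fitness
                best_position = p.position.copy()
        trace[ite - 1] = best_fitness
    return EOResult(best_position=best_position, best_fitness=best_fitness, fitness_trace=trace)
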