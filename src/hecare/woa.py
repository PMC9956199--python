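"""Whale Optimization Algorithm over bounded real vectors.

A population metaheuristic mimicking humpback bubble-net hunting.  Each
iteration every whale either

* **encircles** the current best ("prey"):  G' = G* - F o |R o G* - G|,
* **spirals** toward it on a logarithmic spiral:
  G' = |G* - G| e^{d s} cos(2 pi s) + G*  with s ~ U(-1, 1), or
* **explores** toward a random member:  G' = G_rand - F o |R o G_rand - G|,

where F = 2 f y - f and R = 2 y with y ~ U(0,1)^D per dimension, and the
scalar f decays linearly from 2 to 0 across iterations.  The spiral branch
fires with probability 1/2; otherwise large |F| (>= 1 in the sup norm)
selects exploration, small |F| exploitation.  Positions are clipped to the
search box after every move; the best-so-far solution is elitist (never
discarded), so the recorded best fitness is monotonically non-increasing.

Minimization convention throughout; negate the objective to maximize.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WOAError",
    "WOAConfig",
    "WOAResult",
    "decay_coefficient",
    "coefficient_vectors",
    "encircle_update",
    "spiral_update",
    "explore_update",
    "woa_step",
    "optimize",
    "random_search",
]


class WOAError(ValueError):
    pass


@dataclass(frozen=True)
class WOAConfig:
    """Population/iteration budget, spiral shape constant, bounds and seed."""

    lower: np.ndarray
    upper: np.ndarray
    population_size: int = 20
    iterations: int = 100
    spiral_constant: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape or self.lower.ndim != 1:
            raise WOAError("bounds must be 1-D arrays of equal length")
        if (self.lower >= self.upper).any():
            raise WOAError("lower bounds must be strictly below upper bounds")
        if self.population_size < 2:
            raise WOAError("population_size must be >= 2")
        if self.iterations < 1:
            raise WOAError("iterations must be >= 1")

    @property
    def dim(self) -> int:
        return len(self.lower)


@dataclass
class WOAResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[dict]  # per-iteration {"iteration", "best_fitness", "f"}


def decay_coefficient(iteration: int, total: int) -> float:
    """Linear decay f = 2 (1 - k/(K-1)): 2 at the first iteration, 0 at the last."""
    if total <= 0:
        raise WOAError("total iterations must be positive")
    if not 0 <= iteration < total:
        raise WOAError(f"iteration {iteration} outside [0, {total})")
    if total == 1:
        return 2.0
    return 2.0 * (1.0 - iteration / (total - 1))


def coefficient_vectors(f: float, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F = 2 f y - f (componentwise, range [-f, f]) and R = 2 y (range [0, 2])."""
    y = np.asarray(y, dtype=float)
    return 2.0 * f * y - f, 2.0 * y


def _clip(g: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    return np.clip(g, lower, upper)


def encircle_update(g, g_star, f_vec, r_vec, lower, upper) -> np.ndarray:
    """Shrinking encirclement of the best: G' = G* - F o |R o G* - G|."""
    s = np.abs(r_vec * g_star - g)
    return _clip(g_star - f_vec * s, lower, upper)


def spiral_update(g, g_star, d: float, s: float, lower, upper) -> np.ndarray:
    """Bubble-net spiral: G' = |G* - G| e^{d s} cos(2 pi s) + G*, s in [-1, 1]."""
    radius = np.abs(np.asarray(g_star) - np.asarray(g))
    return _clip(
        radius * np.exp(d * s) * np.cos(2.0 * np.pi * s) + g_star, lower, upper
    )


def explore_update(g, g_rand, f_vec, r_vec, lower, upper) -> np.ndarray:
    """Exploration toward a random whale: G' = G_rand - F o |R o G_rand - G|."""
    s = np.abs(r_vec * g_rand - g)
    return _clip(g_rand - f_vec * s, lower, upper)


def woa_step(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    best_position: np.ndarray,
    best_fitness: float,
    iteration: int,
    config: WOAConfig,
    rng: np.random.Generator,
    fitness_fn,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """One full population update; returns new state plus the decay value f.

    Per whale: p ~ U(0,1); p >= 0.5 takes the spiral branch, otherwise
    ||F||_inf >= 1 explores toward a random other whale and ||F||_inf < 1
    encircles the elite.  The elite is replaced only on strict improvement.
    """
    f = decay_coefficient(iteration, config.iterations)
    pop = positions.copy()
    n = len(pop)
    for i in range(n):
        p = rng.random()
        if p >= 0.5:
            s = rng.uniform(-1.0, 1.0)
            pop[i] = spiral_update(
                positions[i], best_position, config.spiral_constant, s,
                config.lower, config.upper,
            )
        else:
            y = rng.random(config.dim)
            f_vec, r_vec = coefficient_vectors(f, y)
            if np.max(np.abs(f_vec)) >= 1.0:
                j = i if n == 1 else int(rng.integers(n - 1))
                if j >= i:
                    j += 1  # exclude self
                pop[i] = explore_update(
                    positions[i], positions[j], f_vec, r_vec,
                    config.lower, config.upper,
                )
            else:
                pop[i] = encircle_update(
                    positions[i], best_position, f_vec, r_vec,
                    config.lower, config.upper,
                )
    new_fit = np.empty(n)
    for i in range(n):
        val = float(fitness_fn(pop[i]))
        if not np.isfinite(val):
            raise WOAError(f"fitness returned non-finite value for whale {i}")
        new_fit[i] = val
    best_idx = int(np.argmin(new_fit))
    if new_fit[best_idx] < best_fitness:
        best_fitness = float(new_fit[best_idx])
        best_position = pop[best_idx].copy()
    return pop, new_fit, best_position, best_fitness, f


def optimize(fitness_fn, config: WOAConfig) -> WOAResult:
    """Run the full WOA loop: population_size x iterations evaluations.

    Returns the elitist best position/fitness and the per-iteration history
    of the best fitness and decay coefficient.
    """
    rng = np.random.default_rng(config.seed)
    dim = config.dim
    positions = rng.uniform(config.lower, config.upper, size=(config.population_size, dim))
    fitnesses = np.empty(config.population_size)
    for i in range(config.population_size):
        val = float(fitness_fn(positions[i]))
        if not np.isfinite(val):
            raise WOAError(f"fitness returned non-finite value for whale {i}")
        fitnesses[i] = val
    best_idx = int(np.argmin(fitnesses))
    best_position = positions[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])

    history: list[dict] = []
    for k in range(config.iterations):
        positions, fitnesses, best_position, best_fitness, f = woa_step(
            positions, fitnesses, best_position, best_fitness, k, config, rng, fitness_fn
        )
        history.append({"iteration": k, "best_fitness": best_fitness, "f": f})
    return WOAResult(
        best_position=best_position, best_fitness=best_fitness, history=history
    )


def random_search(fitness_fn, config: WOAConfig) -> WOAResult:
    """Equal-budget uniform random search baseline (same evaluation count)."""
    rng = np.random.default_rng(config.seed)
    budget = config.population_size * (config.iterations + 1)
    best_position = None
    best_fitness = np.inf
    history: list[dict] = []
    for k in range(budget):
        x = rng.uniform(config.lower, config.upper)
        val = float(fitness_fn(x))
        if val < best_fitness:
            best_fitness = val
            best_position = x
        history.append({"iteration": k, "best_fitness": best_fitness, "f": 0.0})
    return WOAResult(
        best_position=best_position, best_fitness=best_fitness, history=history
    )
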