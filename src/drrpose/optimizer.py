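"""Phased differential evolution (PDE).

A DE/rand/2 minimiser with binomial crossover and greedy one-to-one
selection, whose control parameters switch at the halfway generation: the
scale factor F goes from an explorative 0.5 to a more exploitative 0.8, and
the crossover rate CR drops from above 0.5 to below 0.5.  A per-dimension
multiplier on F allows a smaller mutation scale on dimensions that move the
objective only weakly (in the registration setting, the depth translation).

Random-draw order (fixed so that an external replay of the generator
reproduces a run exactly):

1. initialisation: one ``rng.random((NP, D))`` block;
2. per generation, per individual ``i``:
   a. five mutually distinct donor indices distinct from ``i``, drawn by
      rejection sampling with ``rng.integers(0, NP)``, one at a time;
   b. ``j_rand = rng.integers(0, D)``;
   c. ``rng.random(D)`` crossover uniforms.

Trial vectors for a whole generation are built first and then evaluated and
selected together (generation-synchronous DE), so an image-registration
objective can render the entire generation in one batch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEConfig",
    "Population",
    "OptimizationResult",
    "initialize_population",
    "phase_controls",
    "mutate",
    "crossover",
    "select",
    "optimize",
]


@dataclass(frozen=True)
class DEConfig:
    """Settings for one phased-DE run.

    ``f_dim_scale`` multiplies the stage F per dimension (all ones by
    default); ``initial`` optionally injects a known starting vector as the
    first population member (warm start).
    """

    np_size: int = 10
    dim: int = 6
    gmax: int = 50
    bounds: tuple = ((0.0, 1.0),) * 6
    f_schedule: tuple[float, float] = (0.5, 0.8)
    cr_schedule: tuple[float, float] = (0.9, 0.3)
    f_dim_scale: tuple | None = None
    seed: int = 0
    initial: tuple | None = None

    def __post_init__(self) -> None:
        if self.np_size < 6:
            raise ValueError("DE/rand/2 needs NP >= 6 (five distinct donors plus the target)")
        if self.dim < 1:
            raise ValueError("dimensionality must be >= 1")
        if self.gmax < 1:
            raise ValueError("gmax must be >= 1")
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (self.dim, 2):
            raise ValueError(f"bounds must be {self.dim} (low, high) pairs, got shape {b.shape}")
        if np.any(b[:, 0] >= b[:, 1]):
            raise ValueError("every dimension needs low < high")
        for f in self.f_schedule:
            if not 0.0 < f <= 2.0:
                raise ValueError(f"F values must lie in (0, 2], got {f}")
        cr1, cr2 = self.cr_schedule
        for cr in (cr1, cr2):
            if not 0.0 <= cr < 1.0:
                raise ValueError(f"CR values must lie in [0, 1), got {cr}")
        if not cr1 > 0.5 > cr2:
            raise ValueError(
                f"the CR schedule must straddle 0.5 (first-half CR > 0.5 > second-half CR), got {cr1}, {cr2}"
            )
        scale = np.ones(self.dim) if self.f_dim_scale is None else np.asarray(self.f_dim_scale, dtype=float)
        if scale.shape != (self.dim,):
            raise ValueError(f"f_dim_scale must have {self.dim} entries")
        if np.any(scale <= 0):
            raise ValueError("f_dim_scale entries must be positive")
        object.__setattr__(self, "f_dim_scale", tuple(float(s) for s in scale))
        if self.initial is not None:
            init = np.asarray(self.initial, dtype=float)
            if init.shape != (self.dim,):
                raise ValueError(f"initial vector must have {self.dim} entries")
            if np.any(init < b[:, 0]) or np.any(init > b[:, 1]):
                raise ValueError("initial vector must lie within the bounds")
            object.__setattr__(self, "initial", tuple(float(v) for v in init))

    @property
    def lower(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)[:, 0]

    @property
    def upper(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)[:, 1]


@dataclass
class Population:
    """Candidate vectors with their fitness values at one generation."""

    vectors: np.ndarray
    fitnesses: np.ndarray
    generation: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitnesses))

    @property
    def best_vector(self) -> np.ndarray:
        return self.vectors[self.best_index]

    @property
    def best_fitness(self) -> float:
        return float(self.fitnesses[self.best_index])


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of one DE run, with the per-generation best-fitness trace."""

    best_vector: np.ndarray
    best_fitness: float
    trace: np.ndarray
    evaluations: int
    population: "Population | None" = None

    def trace_to_csv(self, path) -> None:
        rows = np.column_stack([np.arange(1, len(self.trace) + 1), self.trace])
        np.savetxt(path, rows, delimiter=",", header="generation,best_fitness", comments="", fmt="%.17g")


def _evaluate(objective, vectors, batch_objective=None) -> np.ndarray:
    if batch_objective is not None:
        fits = np.asarray(batch_objective(vectors), dtype=float)
    else:
        fits = np.array([objective(v) for v in vectors], dtype=float)
    if not np.all(np.isfinite(fits)):
        bad = int(np.argmax(~np.isfinite(fits)))
        raise ValueError(f"objective returned a non-finite value for vector {vectors[bad]}")
    return fits


def initialize_population(config: DEConfig, objective, rng=None, batch_objective=None) -> Population:
    """Uniformly random population within the bounds, with fitness evaluated."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.lower, config.upper
    vectors = lo + rng.random((config.np_size, config.dim)) * (hi - lo)
    if config.initial is not None:
        vectors[0] = config.initial
    fitnesses = _evaluate(objective, vectors, batch_objective)
    return Population(vectors=vectors, fitnesses=fitnesses, generation=0)


def phase_controls(generation: int, gmax: int, config: DEConfig) -> tuple[np.ndarray, float]:
    """Stage-switched control parameters for generation ``generation`` (1-based).

    The first stage covers generations 1..ceil(gmax/2); the second stage the
    remainder.  Returns the per-dimension F vector (stage F times the
    dimension scale) and the stage CR.
    """
    if not 1 <= generation <= gmax:
        raise ValueError(f"generation must lie in [1, {gmax}], got {generation}")
    first_half = generation <= math.ceil(gmax / 2)
    f_base = config.f_schedule[0] if first_half else config.f_schedule[1]
    cr = config.cr_schedule[0] if first_half else config.cr_schedule[1]
    return f_base * np.asarray(config.f_dim_scale), cr


def _distinct_indices(rng, np_size: int, exclude: int, count: int = 5) -> list[int]:
    chosen: list[int] = []
    while len(chosen) < count:
        r = int(rng.integers(0, np_size))
        if r != exclude and r not in chosen:
            chosen.append(r)
    return chosen


def mutate(pop: Population, target_index: int, f_vector, rng, config: DEConfig) -> np.ndarray:
    """DE/rand/2 mutant: ``X_r1 + F*(X_r2 - X_r3) + F*(X_r4 - X_r5)``.

    The five donor indices are mutually distinct and distinct from the
    target; the mutant is clipped to the search box.
    """
    x = pop.vectors
    if not 0 <= target_index < len(x):
        raise IndexError(f"target index {target_index} out of range")
    r1, r2, r3, r4, r5 = _distinct_indices(rng, len(x), target_index)
    f = np.asarray(f_vector, dtype=float)
    v = x[r1] + f * (x[r2] - x[r3]) + f * (x[r4] - x[r5])
    return np.clip(v, config.lower, config.upper)


def crossover(target, mutant, cr: float, rng) -> np.ndarray:
    """Binomial crossover: mutant coordinate where ``rand_j < CR`` or ``j = j_rand``."""
    target = np.asarray(target, dtype=float)
    mutant = np.asarray(mutant, dtype=float)
    if target.shape != mutant.shape:
        raise ValueError("target and mutant must have equal length")
    d = target.shape[0]
    j_rand = int(rng.integers(0, d))
    take = rng.random(d) < cr
    take[j_rand] = True
    return np.where(take, mutant, target)


def select(target, target_fitness: float, trial, objective) -> tuple[np.ndarray, float, bool]:
    """Greedy selection: the trial survives iff strictly better (lower).

    Returns (surviving vector, its fitness, whether the trial replaced the
    target).  Ties keep the incumbent.
    """
    trial = np.asarray(trial, dtype=float)
    f_trial = float(objective(trial))
    if not math.isfinite(f_trial):
        raise ValueError(f"objective returned a non-finite value for trial vector {trial}")
    if f_trial < target_fitness:
        return trial, f_trial, True
    return np.asarray(target, dtype=float), float(target_fitness), False


def optimize(objective, config: DEConfig, batch_objective=None) -> OptimizationResult:
    """Run phased DE and return the best vector found.

    Performs exactly ``NP * (gmax + 1)`` objective evaluations (the initial
    population plus one trial per individual per generation).  If
    ``batch_objective`` is given it is called with an (n, D) array and must
    return n fitnesses; it replaces per-vector objective calls for whole
    generations.
    """
    rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, objective, rng=rng, batch_objective=batch_objective)
    evaluations = config.np_size
    trace = np.empty(config.gmax)
    for g in range(1, config.gmax + 1):
        f_vec, cr = phase_controls(g, config.gmax, config)
        trials = np.empty_like(pop.vectors)
        for i in range(config.np_size):
            mutant = mutate(pop, i, f_vec, rng, config)
            trials[i] = crossover(pop.vectors[i], mutant, cr, rng)
        trial_fits = _evaluate(objective, trials, batch_objective)
        evaluations += config.np_size
        better = trial_fits < pop.fitnesses
        pop.vectors[better] = trials[better]
        pop.fitnesses[better] = trial_fits[better]
        pop.generation = g
        trace[g - 1] = pop.best_fitness
    return OptimizationResult(
        best_vector=pop.best_vector.copy(),
        best_fitness=pop.best_fitness,
        trace=trace,
        evaluations=evaluations,
        population=pop,
    )
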