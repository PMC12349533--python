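"""Classical benchmark functions for optimizer evaluation.

Six standard test functions with their usual search boxes and theoretical
optima: three unimodal (Schwefel 2.22, Schwefel 1.2, Schwefel 2.21), two
highly multimodal (Generalized Penalized 1 and 2, built from the sinusoidal
penalized sums with the u(x, a, k, m) boundary penalty), and the Kowalik
four-parameter least-squares fit of a rational model to its canonical
11-point data table.  A convergence-experiment runner executes any
optimizer honouring the :func:`drrpose.optimizer.optimize` contract over
functions x seeds and records the best-fitness traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .optimizer import DEConfig, OptimizationResult, optimize

__all__ = [
    "BenchmarkFunction",
    "ConvergenceRecord",
    "BENCHMARKS",
    "get_benchmark",
    "evaluate_benchmark",
    "run_convergence_experiment",
    "records_to_csv",
    "summarize_records",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A named test function with its search box and known optimum."""

    name: str
    label: str
    dim: int
    box: tuple[float, float]
    optimum: float
    minimizer: np.ndarray
    evaluator: Callable[[np.ndarray], float]

    def __call__(self, x) -> float:
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.shape != (self.dim,):
            raise ValueError(f"{self.name} expects dimension {self.dim}, got {x.shape[0]}")
        lo, hi = self.box
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(f"{self.name} input outside the search box [{lo}, {hi}]")
        return float(self.evaluator(x))

    @property
    def bounds(self) -> tuple:
        return (self.box,) * self.dim


def _schwefel_2_22(x: np.ndarray) -> float:
    ax = np.abs(x)
    return float(ax.sum() + ax.prod())


def _schwefel_1_2(x: np.ndarray) -> float:
    return float(np.sum(np.cumsum(x) ** 2))


def _schwefel_2_21(x: np.ndarray) -> float:
    return float(np.max(np.abs(x)))


def _u_penalty(x: np.ndarray, a: float, k: float, m: float) -> float:
    over = np.clip(x - a, 0.0, None)
    under = np.clip(-x - a, 0.0, None)
    return float(k * np.sum(over**m + under**m))


def _penalized_1(x: np.ndarray) -> float:
    # y-transform shifts the optimum to x = -1; penalty u(x, 10, 100, 4)
    d = x.size
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(np.pi / d * core + _u_penalty(x, 10.0, 100.0, 4.0))


def _penalized_2(x: np.ndarray) -> float:
    # optimum at x = 1; penalty u(x, 5, 100, 4)
    core = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return float(0.1 * core + _u_penalty(x, 5.0, 100.0, 4.0))


# canonical 11-point Kowalik data: measured values a_i at inverse abscissae
_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def _kowalik(x: np.ndarray) -> float:
    b = _KOWALIK_B
    model = x[0] * (b**2 + b * x[1]) / (b**2 + b * x[2] + x[3])
    return float(np.sum((_KOWALIK_A - model) ** 2))


def _registry() -> dict[str, BenchmarkFunction]:
    entries = [
        BenchmarkFunction("F1", "Schwefel 2.22", 30, (-10.0, 10.0), 0.0, np.zeros(30), _schwefel_2_22),
        BenchmarkFunction("F2", "Schwefel 1.2", 30, (-100.0, 100.0), 0.0, np.zeros(30), _schwefel_1_2),
        BenchmarkFunction("F3", "Schwefel 2.21", 30, (-100.0, 100.0), 0.0, np.zeros(30), _schwefel_2_21),
        BenchmarkFunction(
            "F4", "Generalized Penalized 1", 30, (-50.0, 50.0), 0.0, -np.ones(30), _penalized_1
        ),
        BenchmarkFunction(
            "F5", "Generalized Penalized 2", 30, (-50.0, 50.0), 0.0, np.ones(30), _penalized_2
        ),
        BenchmarkFunction(
            "F6",
            "Kowalik",
            4,
            (-5.0, 5.0),
            0.0003075,
            np.array([0.19283345, 0.19083624, 0.1231173, 0.13576599]),
            _kowalik,
        ),
    ]
    reg: dict[str, BenchmarkFunction] = {}
    for fn in entries:
        reg[fn.name] = fn
        reg[fn.label.lower().replace(" ", "_").replace(".", "_")] = fn
    return reg


BENCHMARKS = _registry()


def get_benchmark(name: str) -> BenchmarkFunction:
    try:
        return BENCHMARKS[name]
    except KeyError:
        known = sorted({f.name for f in BENCHMARKS.values()})
        raise KeyError(f"unknown benchmark {name!r}; known: {known}") from None


def evaluate_benchmark(name: str, x) -> float:
    """Evaluate the named benchmark at ``x`` (within its box)."""
    return get_benchmark(name)(x)


@dataclass(frozen=True)
class ConvergenceRecord:
    """One optimizer run on one benchmark function."""

    function: str
    optimizer: str
    seed: int
    trace: np.ndarray
    final_best: float
    best_vector: np.ndarray


def run_convergence_experiment(
    function_names: Sequence[str],
    iterations: int = 1000,
    population: int = 30,
    seeds: Sequence[int] = (0,),
    optimizer: Callable[..., OptimizationResult] | None = None,
    optimizer_name: str = "PDE",
    de_kwargs: dict | None = None,
) -> list[ConvergenceRecord]:
    """Run the optimizer on each (function, seed) pair and record the traces.

    ``optimizer`` defaults to the phased-DE :func:`optimize`; any callable
    with the signature ``optimizer(objective, config) -> OptimizationResult``
    can be plugged in for comparison studies.
    """
    opt = optimizer if optimizer is not None else optimize
    records: list[ConvergenceRecord] = []
    for name in function_names:
        fn = get_benchmark(name)
        for seed in seeds:
            config = DEConfig(
                np_size=population,
                dim=fn.dim,
                gmax=iterations,
                bounds=fn.bounds,
                seed=int(seed),
                **(de_kwargs or {}),
            )
            result = opt(fn, config)
            records.append(
                ConvergenceRecord(
                    function=fn.name,
                    optimizer=optimizer_name,
                    seed=int(seed),
                    trace=result.trace,
                    final_best=result.best_fitness,
                    best_vector=result.best_vector,
                )
            )
    return records


def records_to_csv(records: Sequence[ConvergenceRecord], path) -> None:
    """Long-format CSV: function, optimizer, seed, generation, best_fitness."""
    with open(path, "w") as fh:
        fh.write("function,optimizer,seed,generation,best_fitness\n")
        for rec in records:
            for g, v in enumerate(rec.trace, start=1):
                fh.write(f"{rec.function},{rec.optimizer},{rec.seed},{g},{v:.17g}\n")


def summarize_records(records: Sequence[ConvergenceRecord]) -> dict[str, dict[str, float]]:
    """Per-function summary over seeds: best, mean and sd of the final values."""
    summary: dict[str, dict[str, float]] = {}
    by_fn: dict[str, list[float]] = {}
    for rec in records:
        by_fn.setdefault(rec.function, []).append(rec.final_best)
    for name, finals in by_fn.items():
        arr = np.asarray(finals)
        summary[name] = {
            "best": float(arr.min()),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "runs": int(len(arr)),
        }
    return summary
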