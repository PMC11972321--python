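"""Standard test objectives and a uniform random-search baseline.

The baseline draws the same number of uniform box samples as a PCSO run
would evaluate, giving a like-for-like comparison of final best fitness.
"""

from __future__ import annotations

import numpy as np

from cardiopcso.pcso import OptimizationResult, PCSOConfig

__all__ = ["sphere", "rosenbrock", "rastrigin", "random_search", "BENCHMARKS"]


def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float((x**2).sum())


def rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float((100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2).sum())


def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + (x**2 - 10.0 * np.cos(2 * np.pi * x)).sum())


BENCHMARKS = {"sphere": sphere, "rosenbrock": rosenbrock, "rastrigin": rastrigin}


def random_search(objective, config: PCSOConfig, n_evals: int | None = None) -> OptimizationResult:
    """Uniform sampling of the box with the evaluation budget a PCSO run
    under ``config`` would use: pop_size * (max_iters + 1)."""
    if n_evals is None:
        n_evals = config.pop_size * (config.max_iters + 1)
    rng = np.random.default_rng(config.seed)
    best_f = np.inf
    best_x = None
    history = []
    for _ in range(n_evals):
        x = config.lower + rng.random(config.dim) * (config.upper - config.lower)
        f = float(objective(x))
        if f < best_f:
            best_f, best_x = f, x
        history.append(best_f)
    return OptimizationResult(
        best_position=best_x,
        best_fitness=best_f,
        history=np.asarray(history),
        evaluations=n_evals,
        config=config,
        seed=config.seed,
        n_iters=n_evals,
    )
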