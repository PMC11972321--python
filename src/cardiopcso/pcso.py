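"""Predator Crow Search Optimization (PCSO).

A bounded continuous minimizer hybridizing two population searches:

* a predator-style search whose agents ("prey") step towards the best
  position found so far (the raiding elite) using Brownian steps early and
  heavy-tailed Levy steps late, in three iteration phases keyed to the
  velocity ratio between raider and prey (iteration thirds), plus a masked
  long "raid jump" that perturbs a random subset of dimensions; and
* a crow search whose agents fly towards the memorized best position of a
  randomly chosen other crow, scaled by a flight length FL.

Each iteration the two proposals are blended 50/50 into a hybrid candidate
which is accepted per agent only if it improves that agent's fitness, so the
best-fitness history is non-increasing by construction.  All positions are
clipped to the box [lower, upper].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PCSOConfig",
    "Swarm",
    "OptimizationResult",
    "adaptive_M",
    "brownian_vector",
    "levy_vector",
    "phase_for",
    "init_population",
    "phase1_step",
    "phase2_step",
    "phase3_step",
    "raid_jump",
    "crow_step",
    "hybrid_update",
    "optimize",
]


@dataclass
class PCSOConfig:
    """Algorithm constants.

    ``pop_size`` is the number of agents (tau), ``max_iters`` the iteration
    budget (Qmax).  ``step_constant`` scales every phase step, ``flight_length``
    the crow flight, ``mask_prob`` the per-dimension Bernoulli mask of the
    raid jump, and ``levy_exponent`` the tail index of the Levy steps.
    """

    dim: int
    lower: np.ndarray | float
    upper: np.ndarray | float
    pop_size: int = 30
    max_iters: int = 100
    step_constant: float = 0.5
    flight_length: float = 2.0
    mask_prob: float = 0.2
    levy_exponent: float = 1.5
    seed: int = 0
    stagnation_window: int | None = None  # optional early stop, off by default

    def __post_init__(self):
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iters < 3:
            raise ValueError("max_iters must be >= 3")
        if not 0.0 <= self.mask_prob <= 1.0:
            raise ValueError("mask_prob must lie in [0, 1]")
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.dim,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.dim,)).copy()
        if not (np.isfinite(self.lower).all() and np.isfinite(self.upper).all()):
            raise ValueError("bounds must be finite")
        if np.any(self.lower > self.upper):
            raise ValueError("need lower <= upper elementwise")


@dataclass
class Swarm:
    """Population state: prey positions, crow positions, per-agent memory
    (personal best), fitness, and the global elite."""

    prey: np.ndarray
    crow: np.ndarray
    memory: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best fitness after each iteration
    evaluations: int
    config: PCSOConfig
    seed: int
    n_iters: int = field(default=0)


def adaptive_M(Q: int, Qmax: int) -> float:
    """Step-size decay M = (1 - Q/Qmax)^(2 Q/Qmax); 1 at the start, 0 at the end."""
    if Qmax <= 0:
        raise ValueError("Qmax must be > 0")
    if not 0 <= Q <= Qmax:
        raise ValueError(f"Q={Q} outside [0, {Qmax}]")
    frac = Q / Qmax
    if frac == 1.0:
        return 0.0
    return float((1.0 - frac) ** (2.0 * frac))


def brownian_vector(dim: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal step vector (Brownian motion increments)."""
    return rng.standard_normal(dim)


def levy_vector(dim: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric heavy-tailed step by Mantegna's algorithm.

    ``step = u / |v|^(1/alpha)`` with u ~ N(0, sigma_u^2), v ~ N(0,1) and
    sigma_u chosen so |step| has tail index ``alpha`` (P(|step|>t) ~ t^-alpha).
    """
    a = exponent
    sigma_u = (
        math.gamma(1 + a) * math.sin(math.pi * a / 2)
        / (math.gamma((1 + a) / 2) * a * 2 ** ((a - 1) / 2))
    ) ** (1 / a)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.standard_normal(dim)
    return u / np.abs(v) ** (1 / a)


def _clip(x: np.ndarray, cfg: PCSOConfig) -> np.ndarray:
    return np.clip(x, cfg.lower, cfg.upper)


def phase_for(Q: int, Qmax: int) -> int:
    """Phase dispatch by iteration thirds: 1 while Q < Qmax/3, 2 while
    Qmax/3 <= Q < 2 Qmax/3, 3 afterwards."""
    if Q < Qmax / 3:
        return 1
    if Q < 2 * Qmax / 3:
        return 2
    return 3


def init_population(config: PCSOConfig, objective=None) -> Swarm:
    """Uniform initialization S0 = Smin + rand (Smax - Smin) per dimension;
    crows start at the prey positions and memory at the initial positions."""
    rng = np.random.default_rng(config.seed)
    return _init_population(config, objective, rng)


def _init_population(config, objective, rng) -> Swarm:
    tau, dim = config.pop_size, config.dim
    prey = config.lower + rng.random((tau, dim)) * (config.upper - config.lower)
    fitness = (
        np.array([_eval(objective, p) for p in prey])
        if objective is not None
        else np.full(tau, np.inf)
    )
    i = int(np.argmin(fitness))
    return Swarm(
        prey=prey,
        crow=prey.copy(),
        memory=prey.copy(),
        fitness=fitness,
        best_position=prey[i].copy(),
        best_fitness=float(fitness[i]),
    )


def _eval(objective, x) -> float:
    f = float(objective(x))
    if not np.isfinite(f):
        raise RuntimeError(f"objective returned non-finite value {f} at position {x!r}")
    return f


def phase1_step(swarm: Swarm, Q: int, config: PCSOConfig, rng: np.random.Generator) -> Swarm:
    """High velocity ratio (exploration): Brownian steps towards the elite,
    step_i = Y_A (elite - Y_A prey_i), prey += C * U(0,1) * step."""
    tau, dim = swarm.prey.shape
    YA = rng.standard_normal((tau, dim))
    step = YA * (swarm.best_position[None, :] - YA * swarm.prey)
    Y = rng.random((tau, dim))
    swarm.prey = _clip(swarm.prey + config.step_constant * Y * step, config)
    return swarm


def phase2_step(swarm: Swarm, Q: int, config: PCSOConfig, rng: np.random.Generator) -> Swarm:
    """Unit velocity ratio: the first half of the population takes Levy
    steps against the elite, the second half Brownian steps scaled by the
    decay M (development vs discovery split)."""
    tau, dim = swarm.prey.shape
    half = (tau + 1) // 2
    M = adaptive_M(Q, config.max_iters)

    YR = np.array([levy_vector(dim, config.levy_exponent, rng) for _ in range(half)])
    step_a = YR * (swarm.best_position[None, :] - YR * swarm.prey[:half])
    Y = rng.random((half, dim))
    swarm.prey[:half] = swarm.prey[:half] + config.step_constant * Y * step_a

    YA = rng.standard_normal((tau - half, dim))
    step_b = YA * (YA * swarm.best_position[None, :] - swarm.prey[half:])
    swarm.prey[half:] = swarm.prey[half:] + config.step_constant * M * step_b

    swarm.prey = _clip(swarm.prey, config)
    return swarm


def phase3_step(swarm: Swarm, Q: int, config: PCSOConfig, rng: np.random.Generator) -> Swarm:
    """Low velocity ratio (exploitation): all agents take M-scaled Levy steps
    step_i = Y_R (Y_R elite - prey_i)."""
    tau, dim = swarm.prey.shape
    M = adaptive_M(Q, config.max_iters)
    YR = np.array([levy_vector(dim, config.levy_exponent, rng) for _ in range(tau)])
    step = YR * (YR * swarm.best_position[None, :] - swarm.prey)
    swarm.prey = _clip(swarm.prey + config.step_constant * M * step, config)
    return swarm


def raid_jump(
    prey_position: np.ndarray, config: PCSOConfig, Q: int, rng: np.random.Generator
) -> np.ndarray:
    """Masked long leap: candidate = prey + M (Smin + Y (Smax - Smin)) H,
    H elementwise Bernoulli(mask_prob) — a jump towards a random box point
    on a random subset of dimensions, shrinking as iterations progress."""
    prey_position = np.asarray(prey_position, dtype=float)
    single = prey_position.ndim == 1
    prey_position = np.atleast_2d(prey_position)
    n, dim = prey_position.shape
    M = adaptive_M(Q, config.max_iters)
    Y = rng.random((n, dim))
    H = (rng.random((n, dim)) < config.mask_prob).astype(float)
    jump = M * (config.lower + Y * (config.upper - config.lower)) * H
    out = _clip(prey_position + jump, config)
    return out[0] if single else out


def crow_step(
    crow_position: np.ndarray,
    memory_j: np.ndarray,
    flight_length: float,
    rng: np.random.Generator,
    config: PCSOConfig | None = None,
) -> np.ndarray:
    """Crow flight towards another agent's memory:
    pos + rand * FL * (mem_j - pos), rand a scalar U(0,1) per crow."""
    crow_position = np.asarray(crow_position, dtype=float)
    r = rng.random() if crow_position.ndim == 1 else rng.random((crow_position.shape[0], 1))
    out = crow_position + r * flight_length * (memory_j - crow_position)
    return _clip(out, config) if config is not None else out


def hybrid_update(raid_candidate: np.ndarray, crow_candidate: np.ndarray,
                  config: PCSOConfig | None = None) -> np.ndarray:
    """Even blend of the two proposals: 0.5 raid + 0.5 crow (convex, so it
    stays inside the elementwise interval of its inputs)."""
    raid_candidate = np.asarray(raid_candidate, dtype=float)
    crow_candidate = np.asarray(crow_candidate, dtype=float)
    if raid_candidate.shape != crow_candidate.shape:
        raise ValueError("candidate shapes differ")
    out = 0.5 * raid_candidate + 0.5 * crow_candidate
    return _clip(out, config) if config is not None else out


_PHASE_STEPS = {1: phase1_step, 2: phase2_step, 3: phase3_step}


def optimize(
    objective: Callable[[np.ndarray], float],
    config: PCSOConfig,
    callbacks: Sequence[Callable] | None = None,
) -> OptimizationResult:
    """Minimize ``objective`` over the box [lower, upper].

    Per iteration Q = 1..Qmax: the phase step for Q moves every prey, then
    each agent forms a raid-jump candidate and a crow candidate, blends them
    50/50, and accepts the blend only if it improves the agent's fitness
    (greedy, per agent).  Memory and the global elite update on acceptance.
    One objective evaluation per agent per iteration plus the initial sweep.
    """
    rng = np.random.default_rng(config.seed)
    swarm = _init_population(config, objective, rng)
    evaluations = config.pop_size
    tau = config.pop_size
    history = []

    for Q in range(1, config.max_iters + 1):
        swarm = _PHASE_STEPS[phase_for(Q, config.max_iters)](swarm, Q, config, rng)

        raid_cand = raid_jump(swarm.prey, config, Q, rng)
        # each crow follows a uniformly random other crow's memory
        j = (np.arange(tau) + rng.integers(1, tau, size=tau)) % tau
        crow_cand = crow_step(swarm.crow, swarm.memory[j], config.flight_length, rng, config)
        cand = hybrid_update(raid_cand, crow_cand, config)

        for i in range(tau):
            f = _eval(objective, cand[i])
            evaluations += 1
            if f < swarm.fitness[i]:
                swarm.fitness[i] = f
                swarm.prey[i] = cand[i]
                swarm.memory[i] = cand[i]
                if f < swarm.best_fitness:
                    swarm.best_fitness = f
                    swarm.best_position = cand[i].copy()
        swarm.crow = crow_cand  # crows fly regardless of acceptance

        history.append(swarm.best_fitness)
        if callbacks:
            for cb in callbacks:
                cb(Q, swarm)
        if (
            config.stagnation_window
            and len(history) > config.stagnation_window
            and history[-1] == history[-1 - config.stagnation_window]
        ):
            break

    return OptimizationResult(
        best_position=swarm.best_position.copy(),
        best_fitness=float(swarm.best_fitness),
        history=np.asarray(history),
        evaluations=evaluations,
        config=config,
        seed=config.seed,
        n_iters=len(history),
    )
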