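"""Particle-swarm optimizers with a Levy-flight mental-search operator.

Three derivative-free optimizers over box-bounded real vectors:

``pso``
    Canonical global-best particle swarm: velocities combine inertia,
    cognitive (personal-best) and social (global-best) attraction, with
    velocity and position clamping and an optionally decaying inertia weight.

``hms``
    A standalone mental-search baseline: each particle repeatedly perturbs
    its position with a Levy-flight candidate and moves greedily.

``hms_pso``
    The hybrid: every iteration runs the PSO velocity/position update, then
    a mental-search pass that may replace a particle's personal best with a
    Levy-flight candidate.  With the mental search disabled it reduces
    exactly to ``pso`` under the same RNG stream.

The mental-search candidate for particle position ``x`` is

    S = d * alpha * u * sigma / |v|^(1/beta) * x      (componentwise)

with scalar draws per candidate: ``mc ~ N(0,1)``, ``d`` the standard-normal
density at ``mc``, ``beta ~ U(beta_low, beta_high)``, ``sigma =
sin(pi*beta/2)``; ``u, v`` are per-dimension standard normals and ``alpha``
is the Levy scale (default 0.01).  The extra density factor ``d`` is not
part of the textbook Mantegna step but is retained as specified; the full
Mantegna sigma is available behind ``mantegna_sigma=True`` for sensitivity
checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "MentalSearchDraw",
    "OptimizationResult",
    "inertia_at",
    "initialize_swarm",
    "update_velocity",
    "draw_levy_candidate",
    "apply_mental_search",
    "optimize",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class SwarmConfig:
    """Settings for the swarm optimizers.

    ``w`` is either a constant inertia weight or a ``(w_max, w_min)`` pair,
    in which case the weight decays linearly from ``w_max`` at iteration 0
    to ``w_min`` at the final iteration.  ``v_max`` defaults to 20% of the
    per-dimension box width.  ``cluster_size`` is accepted for completeness
    with published parameter tables but unused: the hybrid has no clustered
    population phase.
    """

    dimension: int
    bounds: tuple = (-10.0, 10.0)  # scalars or per-dimension arrays
    population_size: int = 50
    max_iterations: int = 100
    w: Union[float, tuple] = (0.729, 0.4)
    c1: float = 1.49
    c2: float = 1.49
    beta_low: float = 0.3
    beta_high: float = 1.99
    levy_scale: float = 0.01
    v_max: Optional[Union[float, np.ndarray]] = None
    mental_search_enabled: bool = True
    candidates_per_particle: int = 1
    mantegna_sigma: bool = False
    cluster_size: int = 5  # accepted, unused
    seed: Optional[int] = None

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not (0 < self.beta_low < self.beta_high < 2):
            raise ValueError("require 0 < beta_low < beta_high < 2")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1, c2 must be non-negative")
        lo, hi = self.bounds
        lo = np.broadcast_to(np.asarray(lo, dtype=float), (self.dimension,)).copy()
        hi = np.broadcast_to(np.asarray(hi, dtype=float), (self.dimension,)).copy()
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("bounds must be finite")
        if np.any(lo >= hi):
            raise ValueError("lower bound must be < upper bound")
        self.bounds = (lo, hi)
        if self.v_max is None:
            self.v_max = 0.2 * (hi - lo)
        else:
            self.v_max = np.broadcast_to(
                np.asarray(self.v_max, dtype=float), (self.dimension,)).copy()
            if np.any(self.v_max <= 0):
                raise ValueError("v_max must be positive")

    @property
    def w_schedule(self) -> tuple:
        """(w_max, w_min); a constant w is a degenerate schedule."""
        if isinstance(self.w, (tuple, list)):
            return (float(self.w[0]), float(self.w[1]))
        return (float(self.w), float(self.w))

    def to_dict(self) -> dict:
        lo, hi = self.bounds
        d = {
            "dimension": self.dimension,
            "lower": lo.tolist(),
            "upper": hi.tolist(),
            "population_size": self.population_size,
            "max_iterations": self.max_iterations,
            "w": list(self.w) if isinstance(self.w, (tuple, list)) else self.w,
            "c1": self.c1,
            "c2": self.c2,
            "beta_low": self.beta_low,
            "beta_high": self.beta_high,
            "levy_scale": self.levy_scale,
            "v_max": np.asarray(self.v_max).tolist(),
            "mental_search_enabled": self.mental_search_enabled,
            "candidates_per_particle": self.candidates_per_particle,
            "mantegna_sigma": self.mantegna_sigma,
            "seed": self.seed,
        }
        return d


@dataclass
class SwarmState:
    positions: np.ndarray       # (pop, dim)
    velocities: np.ndarray      # (pop, dim)
    fitness: np.ndarray         # (pop,) fitness of current positions
    pbest: np.ndarray           # (pop, dim)
    pbest_fitness: np.ndarray   # (pop,)
    gbest: np.ndarray           # (dim,)
    gbest_fitness: float
    iteration: int = 0

    def refresh_gbest(self) -> None:
        """Set the global best to the fittest personal best (strict improvement
        only, so the incumbent wins ties)."""
        k = int(np.argmin(self.pbest_fitness))
        if self.pbest_fitness[k] < self.gbest_fitness:
            self.gbest = self.pbest[k].copy()
            self.gbest_fitness = float(self.pbest_fitness[k])


@dataclass(frozen=True)
class MentalSearchDraw:
    """One Levy-flight mental-search candidate and its intermediate draws."""
    mc: float
    d: float
    beta: float
    sigma: float
    u: np.ndarray
    v: np.ndarray
    S: np.ndarray


def inertia_at(t: int, t_max: int, w_max: float, w_min: float) -> float:
    """Linearly decaying inertia: w_max at t=0 down to w_min at t=t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    return (t_max - t) / t_max * (w_max - w_min) + w_min


def initialize_swarm(config: SwarmConfig, objective: Callable,
                     rng: Optional[np.random.Generator] = None) -> SwarmState:
    """Uniform positions within bounds, zero velocities, personal bests at
    the initial positions, global best at the fittest particle."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    x = rng.uniform(lo, hi, size=(config.population_size, config.dimension))
    fit = np.array([float(objective(xi)) for xi in x])
    k = int(np.argmin(fit))
    return SwarmState(
        positions=x,
        velocities=np.zeros_like(x),
        fitness=fit.copy(),
        pbest=x.copy(),
        pbest_fitness=fit.copy(),
        gbest=x[k].copy(),
        gbest_fitness=float(fit[k]),
    )


def update_velocity(v, x, p_b, p_g, w_t, c1, c2,
                    rng: Optional[np.random.Generator] = None,
                    v_max=None, r1=None, r2=None):
    """Inertia + cognitive + social velocity update with clamping.

    ``r1``/``r2`` default to per-component uniform [0,1] draws from ``rng``
    ("random vectors"); passing them explicitly supports deterministic
    checks.  The result is clamped to [-v_max, v_max] when given.
    """
    v = np.asarray(v, dtype=float)
    x = np.asarray(x, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if v.shape != x.shape or p_b.shape != x.shape:
        raise ValueError("v, x, p_b must share a shape")
    if r1 is None:
        r1 = rng.uniform(size=x.shape)
    if r2 is None:
        r2 = rng.uniform(size=x.shape)
    out = w_t * v + c1 * r1 * (p_b - x) + c2 * r2 * (p_g - x)
    if v_max is not None:
        out = np.clip(out, -np.asarray(v_max), np.asarray(v_max))
    return out


def draw_levy_candidate(x_i: np.ndarray, config: SwarmConfig,
                        rng: np.random.Generator) -> MentalSearchDraw:
    """Draw one mental-search candidate around position ``x_i``.

    Scalars ``mc`` (standard normal), ``d`` (normal density at mc), ``beta``
    (uniform in [beta_low, beta_high]) and ``sigma = sin(pi*beta/2)`` are
    shared across dimensions; ``u`` and ``v`` are per-dimension standard
    normals.  Zero entries of ``v`` are resampled so the |v|^(1/beta)
    divisor never vanishes.  The candidate is clamped to the box bounds.
    """
    dim = x_i.shape[0]
    mc = float(rng.standard_normal())
    d = math.exp(-0.5 * mc * mc) / _SQRT_2PI
    beta = float(rng.uniform(config.beta_low, config.beta_high))
    if config.mantegna_sigma:
        # full Mantegna scale for the numerator normal
        num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
        den = (math.gamma((1.0 + beta) / 2.0) * beta
               * 2.0 ** ((beta - 1.0) / 2.0))
        sigma = (num / den) ** (1.0 / beta)
    else:
        sigma = math.sin(math.pi * beta / 2.0)
    u = rng.standard_normal(dim)
    v = rng.standard_normal(dim)
    while np.any(v == 0.0):  # pragma: no cover - measure-zero event
        v = np.where(v == 0.0, rng.standard_normal(dim), v)
    step = d * config.levy_scale * u * sigma / np.abs(v) ** (1.0 / beta)
    lo, hi = config.bounds
    S = np.clip(step * x_i, lo[: dim] if lo.shape[0] != dim else lo,
                hi[: dim] if hi.shape[0] != dim else hi)
    return MentalSearchDraw(mc=mc, d=d, beta=beta, sigma=sigma, u=u, v=v, S=S)


def apply_mental_search(state: SwarmState, particle_index: int,
                        draw: MentalSearchDraw, objective: Callable) -> None:
    """Personal-best update: current position if it improves, else the
    mental-search candidate if that improves; the position itself is left
    unchanged.  Non-finite candidate fitness rejects the candidate."""
    i = particle_index
    f_s = float(objective(draw.S))
    if state.fitness[i] < state.pbest_fitness[i]:
        state.pbest[i] = state.positions[i].copy()
        state.pbest_fitness[i] = float(state.fitness[i])
    elif math.isfinite(f_s) and f_s < state.pbest_fitness[i]:
        state.pbest[i] = draw.S.copy()
        state.pbest_fitness[i] = f_s
    state.refresh_gbest()


@dataclass
class OptimizationResult:
    """Outcome of one optimizer run: best-ever solution, per-iteration
    best/mean fitness traces, evaluation count, and the config echo."""
    best_position: np.ndarray
    best_fitness: float
    fitness_trace: np.ndarray
    mean_fitness_trace: np.ndarray
    evaluation_count: int
    seed: Optional[int]
    algorithm: str
    config: dict = field(default_factory=dict)

    def trace_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "iteration": np.arange(1, len(self.fitness_trace) + 1),
            "best_fitness": self.fitness_trace,
            "mean_fitness": self.mean_fitness_trace,
        })

    def trace_to_csv(self, path) -> None:
        self.trace_dataframe().to_csv(path, index=False)


def optimize(objective: Callable, config: SwarmConfig,
             algorithm: str = "hms_pso") -> OptimizationResult:
    """Run ``algorithm`` in {"pso", "hms", "hms_pso"} on ``objective``.

    Identical seeds give identical results.  ``hms_pso`` with
    ``mental_search_enabled=False`` consumes the same RNG stream as ``pso``
    and produces a bitwise-identical trajectory.
    """
    if algorithm not in ("pso", "hms", "hms_pso"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    n_evals = 0

    def f(x):
        nonlocal n_evals
        n_evals += 1
        return float(objective(x))

    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    state = initialize_swarm(config, f, rng)
    w_max, w_min = config.w_schedule
    pso_phase = algorithm in ("pso", "hms_pso")
    mental_phase = (algorithm == "hms") or (
        algorithm == "hms_pso" and config.mental_search_enabled)

    best_trace = np.empty(config.max_iterations)
    mean_trace = np.empty(config.max_iterations)

    for t in range(config.max_iterations):
        w_t = inertia_at(t, config.max_iterations, w_max, w_min)

        if pso_phase:
            state.velocities = update_velocity(
                state.velocities, state.positions, state.pbest, state.gbest,
                w_t, config.c1, config.c2, rng, v_max=config.v_max)
            state.positions = np.clip(state.positions + state.velocities, lo, hi)
            state.fitness = np.array([f(xi) for xi in state.positions])

        if mental_phase:
            for i in range(config.population_size):
                draws = [draw_levy_candidate(state.positions[i], config, rng)
                         for _ in range(config.candidates_per_particle)]
                if algorithm == "hms":
                    # standalone baseline: greedy position move to the best
                    # candidate, then personal-best bookkeeping
                    f_cands = [f(dr.S) for dr in draws]
                    k = int(np.argmin(f_cands))
                    if math.isfinite(f_cands[k]) and f_cands[k] < state.fitness[i]:
                        state.positions[i] = draws[k].S.copy()
                        state.fitness[i] = f_cands[k]
                    if state.fitness[i] < state.pbest_fitness[i]:
                        state.pbest[i] = state.positions[i].copy()
                        state.pbest_fitness[i] = float(state.fitness[i])
                else:
                    for dr in draws:
                        apply_mental_search(state, i, dr, f)
        if pso_phase and not mental_phase:
            improved = state.fitness < state.pbest_fitness
            state.pbest[improved] = state.positions[improved].copy()
            state.pbest_fitness[improved] = state.fitness[improved]
        state.refresh_gbest()

        state.iteration = t + 1
        best_trace[t] = state.gbest_fitness
        mean_trace[t] = float(np.mean(state.pbest_fitness))

    return OptimizationResult(
        best_position=state.gbest.copy(),
        best_fitness=float(state.gbest_fitness),
        fitness_trace=best_trace,
        mean_fitness_trace=mean_trace,
        evaluation_count=n_evals,
        seed=config.seed,
        algorithm=algorithm,
        config=config.to_dict(),
    )
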