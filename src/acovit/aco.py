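"""Generic ant colony optimization over a layered graph of discrete choices.

The search space is an ordered list of layers, each offering a finite set of
candidate values. An ant builds a solution by picking one candidate per layer,
sampling candidate ``c`` in a layer with probability proportional to
``tau_c**alpha`` where ``tau_c`` is the pheromone trail on that candidate.
After each iteration every trail evaporates by a factor ``(1 - rho)`` and the
iteration-best ant deposits ``Q / (1 + F_best)`` along its path, so lower
fitness (fitnesses are losses) earns a larger deposit. Trails are floored at
``tau_min`` to keep selection probabilities well defined even under full
evaporation.

Pheromone lives on candidate *nodes*, not edges, which makes the dynamics
independent of layer ordering. There is no separate heuristic-desirability
term (equivalently its exponent is zero).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "PheromoneState",
    "AntSolution",
    "ACOConfig",
    "ConvergenceTrace",
    "initialize_pheromone",
    "sample_solution",
    "deposit_amount",
    "update_pheromone",
    "optimize",
]


@dataclass(frozen=True)
class SearchSpace:
    """Ordered layers of candidate values; candidates are opaque tokens."""

    layer_names: tuple[str, ...]
    candidates: tuple[tuple, ...]  # per layer, ordered candidate values

    def __post_init__(self) -> None:
        if len(self.layer_names) != len(self.candidates):
            raise ValueError("layer_names and candidates length mismatch")
        if not self.layer_names:
            raise ValueError("search space needs at least one layer")
        for name, cands in zip(self.layer_names, self.candidates):
            if not cands:
                raise ValueError(f"layer {name!r} has no candidates")
            labels = [str(c) for c in cands]
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate candidate labels in layer {name!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.candidates)

    def n_configs(self) -> int:
        return int(np.prod([len(c) for c in self.candidates]))

    def decode(self, choices: Sequence[int]) -> dict:
        """Map per-layer candidate indices to {layer name: candidate value}."""
        return {
            name: self.candidates[i][int(c)]
            for i, (name, c) in enumerate(zip(self.layer_names, choices))
        }


@dataclass(frozen=True)
class ACOConfig:
    n_ants: int = 10
    rho: float = 0.3          # evaporation rate in (0, 1]
    q_scale: float = 1.0      # deposit scale Q
    alpha: float = 1.0        # pheromone exponent
    tau0: float = 1.0         # initial trail
    tau_min: float = 0.05     # positive floor on trails (5% of tau0)
    max_iterations: int = 50
    patience: int = 10        # iterations without best-so-far improvement
    seed: int = 0
    elitist: bool = True      # additionally deposit along the global best

    def __post_init__(self) -> None:
        if self.n_ants < 1 or self.max_iterations < 1 or self.patience < 1:
            raise ValueError("n_ants, max_iterations and patience must be >= 1")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must lie in (0, 1]")
        if self.q_scale < 0 or self.alpha < 0:
            raise ValueError("q_scale and alpha must be >= 0")
        if self.tau0 <= 0 or self.tau_min <= 0:
            raise ValueError("tau0 and tau_min must be > 0")
        if self.tau_min > self.tau0:
            raise ValueError("tau_min must not exceed tau0")


@dataclass
class PheromoneState:
    """Per-layer, per-candidate positive trail values at iteration ``t``."""

    tau: list[np.ndarray]
    iteration: int = 0

    def copy(self) -> "PheromoneState":
        return PheromoneState([t.copy() for t in self.tau], self.iteration)


@dataclass
class AntSolution:
    """One candidate index per layer plus (once evaluated) a loss fitness."""

    choices: tuple[int, ...]
    fitness: float | None = None


@dataclass
class ConvergenceTrace:
    """Per-iteration record of iteration-best and best-so-far fitness."""

    iterations: list[int] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    best_so_far: list[float] = field(default_factory=list)

    def append(self, iteration: int, best: float, best_so_far: float) -> None:
        if self.best_so_far and best_so_far > self.best_so_far[-1]:
            raise ValueError("best-so-far must be non-increasing")
        self.iterations.append(iteration)
        self.best_fitness.append(best)
        self.best_so_far.append(best_so_far)

    def last_improvement_iteration(self) -> int:
        """Latest iteration index at which best-so-far strictly improved."""
        last = 0
        for i in range(1, len(self.best_so_far)):
            if self.best_so_far[i] < self.best_so_far[i - 1]:
                last = self.iterations[i]
        return last

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "best_fitness", "best_so_far"])
            w.writerows(zip(self.iterations, self.best_fitness, self.best_so_far))


def initialize_pheromone(space: SearchSpace, config: ACOConfig) -> PheromoneState:
    """All trails start at ``tau0``; the iteration counter starts at 0."""
    return PheromoneState(
        [np.full(len(c), config.tau0, dtype=np.float64) for c in space.candidates]
    )


def sample_solution(
    space: SearchSpace,
    pheromone: PheromoneState,
    config: ACOConfig,
    rng: np.random.Generator,
) -> AntSolution:
    """Draw one candidate per layer with probability ∝ tau**alpha."""
    if len(pheromone.tau) != space.n_layers:
        raise ValueError("pheromone state does not match search space")
    choices = []
    for tau in pheromone.tau:
        w = tau ** config.alpha
        p = w / w.sum()
        choices.append(int(rng.choice(len(tau), p=p)))
    return AntSolution(tuple(choices))


def deposit_amount(fitness: float, q_scale: float) -> float:
    """Deposit for a loss-valued fitness: ``Q / (1 + fitness)``.

    Decreasing in fitness, so better (lower-loss) ants deposit more; an
    infinite fitness deposits nothing.
    """
    if q_scale < 0:
        raise ValueError("q_scale must be >= 0")
    if fitness < 0 or math.isnan(fitness):
        raise ValueError("fitness must be >= 0 (shift losses to be non-negative)")
    if math.isinf(fitness):
        return 0.0
    return q_scale / (1.0 + fitness)


def _deposit(tau: list[np.ndarray], solution: AntSolution, delta: float) -> None:
    for layer, choice in enumerate(solution.choices):
        tau[layer][choice] += delta


def update_pheromone(
    pheromone: PheromoneState,
    best: AntSolution,
    delta: float,
    config: ACOConfig,
) -> PheromoneState:
    """Evaporate all trails, deposit ``delta`` along ``best``, floor, advance t."""
    if best.fitness is None:
        raise ValueError("best ant must be evaluated before depositing")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    new = pheromone.copy()
    for layer in range(len(new.tau)):
        new.tau[layer] *= 1.0 - config.rho
    _deposit(new.tau, best, delta)
    for layer in range(len(new.tau)):
        np.maximum(new.tau[layer], config.tau_min, out=new.tau[layer])
    new.iteration = pheromone.iteration + 1
    return new


def optimize(
    space: SearchSpace,
    fitness_fn: Callable[[AntSolution], float],
    config: ACOConfig,
) -> tuple[AntSolution, ConvergenceTrace]:
    """Run the full ACO loop and return the best evaluated solution.

    Each iteration samples ``n_ants`` solutions, evaluates them, lets the
    iteration-best deposit, evaporates all trails, and records the trace.
    Stops at ``max_iterations`` or after ``patience`` iterations without
    best-so-far improvement. Ties within an iteration are broken by lowest
    ant index; across iterations by first occurrence.
    """
    rng = np.random.default_rng(config.seed)
    pheromone = initialize_pheromone(space, config)
    trace = ConvergenceTrace()
    best_global: AntSolution | None = None
    stale = 0
    for t in range(config.max_iterations):
        ants = [sample_solution(space, pheromone, config, rng) for _ in range(config.n_ants)]
        for ant in ants:
            try:
                f = float(fitness_fn(ant))
            except Exception as exc:  # annotate with the offending configuration
                raise RuntimeError(
                    f"fitness evaluation failed for choices {space.decode(ant.choices)}"
                ) from exc
            if math.isnan(f) or f < 0:
                raise ValueError(
                    f"fitness must be a non-negative real, got {f} for "
                    f"{space.decode(ant.choices)}"
                )
            ant.fitness = f
        iter_best = min(ants, key=lambda a: a.fitness)  # stable: lowest index wins ties
        if best_global is None or iter_best.fitness < best_global.fitness:
            best_global = replace(iter_best)
            stale = 0
        else:
            stale += 1
        pheromone = update_pheromone(
            pheromone, iter_best, deposit_amount(iter_best.fitness, config.q_scale), config
        )
        if config.elitist and best_global.choices != iter_best.choices:
            _deposit(pheromone.tau, best_global,
                     deposit_amount(best_global.fitness, config.q_scale))
        trace.append(t, iter_best.fitness, best_global.fitness)
        if stale >= config.patience:
            break
    return best_global, trace
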