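"""Augmentation operators and ACO search for the best augmentation policy.

A policy is an ordered list of (operator, parameter) pairs. The policy
fitness combines the mean loss of a pluggable callback on N augmented
samples with a complexity penalty:

    F(W) = (1/N) * sum_i loss_fn(apply_policy(X_i), y_i) + lambda * Complexity(W)

Complexity(W) is additive over active operators: each contributes
``cost_weight * (1 + normalized parameter magnitude)``, where the magnitude
is min-max normalized over the operator's parameter grid (a single-value
grid normalizes to 0). The search space hands one layer per operator to the
generic ACO engine, with candidates ``{"off"} ∪ grid``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .aco import ACOConfig, ConvergenceTrace, SearchSpace, optimize
from .data import LabelledDataset

__all__ = [
    "AugmentationOp",
    "AugmentationPolicy",
    "PolicyFitnessConfig",
    "default_op_menu",
    "apply_policy",
    "policy_complexity",
    "policy_fitness",
    "search_policy",
]

OFF = "off"


@dataclass(frozen=True)
class AugmentationOp:
    """A named image operator with a finite parameter grid.

    ``fn(image, param, rng)`` must preserve shape and the [0, 1] range.
    """

    name: str
    grid: tuple
    fn: Callable[[np.ndarray, object, np.random.Generator], np.ndarray]
    cost_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError(f"op {self.name!r} has an empty parameter grid")
        if self.cost_weight < 0:
            raise ValueError("cost_weight must be >= 0")

    def normalized_magnitude(self, param) -> float:
        mags = np.array([abs(float(g)) if not isinstance(g, bool) else 0.0
                         for g in self.grid])
        m = abs(float(param)) if not isinstance(param, bool) else 0.0
        span = mags.max() - mags.min()
        if span <= 0:
            return 0.0
        return float((m - mags.min()) / span)


@dataclass
class AugmentationPolicy:
    """Ordered (op, parameter) pairs; each op appears at most once."""

    steps: list[tuple[AugmentationOp, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [op.name for op, _ in self.steps]
        if len(set(names)) != len(names):
            raise ValueError("each op may appear at most once in a policy")
        for op, param in self.steps:
            if param not in op.grid:
                raise ValueError(f"parameter {param!r} not in grid of {op.name!r}")

    def to_mapping(self, menu: Sequence[AugmentationOp]) -> dict:
        chosen = {op.name: param for op, param in self.steps}
        return {op.name: chosen.get(op.name, OFF) for op in menu}

    @classmethod
    def from_mapping(
        cls, menu: Sequence[AugmentationOp], mapping: dict
    ) -> "AugmentationPolicy":
        steps = []
        for op in menu:
            param = mapping.get(op.name, OFF)
            if param != OFF:
                if param not in op.grid:  # YAML round-trips ints/floats loosely
                    matches = [g for g in op.grid if float(g) == float(param)]
                    if not matches:
                        raise ValueError(f"{param!r} not in grid of {op.name!r}")
                    param = matches[0]
                steps.append((op, param))
        return cls(steps)


@dataclass(frozen=True)
class PolicyFitnessConfig:
    lam: float = 0.01  # accuracy/complexity trade-off
    n_eval: int = 16   # samples drawn per fitness evaluation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0 or self.n_eval < 1:
            raise ValueError("need lam >= 0 and n_eval >= 1")


# --- operator implementations -------------------------------------------------

def _clip(img: np.ndarray) -> np.ndarray:
    return np.clip(img, 0.0, 1.0)


def _hflip(img, param, rng):
    return img[:, ::-1].copy()


def _rotate(img, degrees, rng):
    deg = float(degrees)
    if deg % 90 == 0:  # exact pixel permutation for quarter turns
        return np.rot90(img, k=int(deg // 90) % 4).copy()
    return _clip(ndimage.rotate(img, deg, reshape=False, order=1, mode="reflect"))


def _brightness(img, shift, rng):
    return _clip(img + float(shift))


def _contrast(img, scale, rng):
    return _clip((img - 0.5) * float(scale) + 0.5)


def _noise(img, sigma, rng):
    return _clip(img + float(sigma) * rng.standard_normal(img.shape))


def _translate(img, shift_px, rng):
    return _clip(ndimage.shift(img, (float(shift_px), 0.0), order=1, mode="reflect"))


def default_op_menu() -> list[AugmentationOp]:
    """Flip / rotate / brightness / contrast / speckle-like noise / translate."""
    return [
        AugmentationOp("hflip", (True,), _hflip),
        AugmentationOp("rotate", (-10.0, -5.0, 5.0, 10.0, 90.0), _rotate),
        AugmentationOp("brightness", (-0.2, -0.1, 0.1, 0.2), _brightness),
        AugmentationOp("contrast", (0.8, 1.2), _contrast),
        AugmentationOp("noise", (0.01, 0.05), _noise),
        AugmentationOp("translate", (-4.0, 4.0), _translate),
    ]


# --- policy evaluation --------------------------------------------------------

def apply_policy(
    image: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply each step in order; output stays in [0, 1] at the input shape."""
    out = image
    for op, param in policy.steps:
        out = op.fn(out, param, rng)
    return _clip(np.asarray(out, dtype=np.float64))


def policy_complexity(policy: AugmentationPolicy) -> float:
    """Additive cost: sum of cost_weight * (1 + normalized |parameter|)."""
    return float(
        sum(op.cost_weight * (1.0 + op.normalized_magnitude(param))
            for op, param in policy.steps)
    )


def policy_fitness(
    policy: AugmentationPolicy,
    loss_fn: Callable[[np.ndarray, int], float],
    dataset: LabelledDataset,
    cfg: PolicyFitnessConfig,
) -> float:
    """Mean augmented-sample loss over a seeded subsample, plus complexity."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    if len(dataset) < cfg.n_eval:
        raise ValueError(f"dataset has {len(dataset)} < n_eval={cfg.n_eval} samples")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.choice(len(dataset), size=cfg.n_eval, replace=False)
    total = 0.0
    for i in idx:
        aug = apply_policy(dataset.images[i], policy, rng)
        loss = float(loss_fn(aug, int(dataset.labels[i])))
        if not np.isfinite(loss) or loss < 0:
            raise ValueError(f"loss_fn returned invalid value {loss}")
        total += loss
    return total / cfg.n_eval + cfg.lam * policy_complexity(policy)


def _policy_space(menu: Sequence[AugmentationOp]) -> SearchSpace:
    return SearchSpace(
        tuple(op.name for op in menu),
        tuple((OFF,) + tuple(op.grid) for op in menu),
    )


def decode_policy(
    menu: Sequence[AugmentationOp], choices: Sequence[int]
) -> AugmentationPolicy:
    steps = []
    for op, c in zip(menu, choices):
        if c > 0:
            steps.append((op, op.grid[c - 1]))
    return AugmentationPolicy(steps)


def search_policy(
    op_menu: Sequence[AugmentationOp],
    loss_fn: Callable[[np.ndarray, int], float],
    dataset: LabelledDataset,
    cfg: PolicyFitnessConfig,
    aco_config: ACOConfig,
) -> tuple[AugmentationPolicy, ConvergenceTrace]:
    """ACO search over {off} ∪ grid per operator, minimizing policy fitness."""
    if not op_menu:
        raise ValueError("op_menu is empty")
    space = _policy_space(op_menu)
    cache: dict[tuple, float] = {}

    def fitness(solution) -> float:
        key = tuple(solution.choices)
        if key not in cache:
            cache[key] = policy_fitness(
                decode_policy(op_menu, key), loss_fn, dataset, cfg
            )
        return cache[key]

    best, trace = optimize(space, fitness, aco_config)
    return decode_policy(op_menu, best.choices), trace
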