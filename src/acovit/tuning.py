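"""ACO applications: hyperparameter tuning and wrapper feature selection.

Hyperparameter search runs the generic ant colony over a layered grid of
learning rate, batch size and dense-layer width, minimizing

    F(theta) = validation cross-entropy + lambda * Complexity(theta)

where Complexity(theta) is the dense-layer width normalized by the largest
width in the grid — the only capacity term in the space, so it lands in
(0, 1]. Each candidate configuration is trained for a small fixed epoch
budget by a pluggable ``train_eval_fn`` so comparisons across ants are fair.

Feature selection treats every feature as an include/exclude layer. Subsets
are scored by the validation log-loss of a cheap regularized linear softmax
(multinomial logistic regression) on a fixed stratified 70/30 split, plus
``lambda * |subset| / p``; the empty subset scores +inf so the returned mask
is never empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import train_test_split

from .aco import ACOConfig, AntSolution, ConvergenceTrace, SearchSpace, optimize

__all__ = [
    "HyperparamSpace",
    "TrainEvalResult",
    "FeatureSelectionResult",
    "model_complexity",
    "hyperparam_fitness",
    "tune",
    "select_features_aco",
]


@dataclass(frozen=True)
class HyperparamSpace:
    """Finite grids for the tunable training knobs.

    Defaults centre on the conventional starting point: learning rate 0.01,
    batch size 32 and a 512-neuron dense layer, each embedded in its grid.
    """

    learning_rate: tuple[float, ...] = (0.1, 0.01, 0.001, 0.0001)
    batch_size: tuple[int, ...] = (16, 32, 64)
    dense_neurons: tuple[int, ...] = (128, 256, 512, 1024)
    initial: dict = field(
        default_factory=lambda: {
            "learning_rate": 0.01, "batch_size": 32, "dense_neurons": 512,
        }
    )

    def __post_init__(self) -> None:
        grids = {
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "dense_neurons": self.dense_neurons,
        }
        for name, grid in grids.items():
            if not grid:
                raise ValueError(f"grid for {name} is empty")
            if self.initial[name] not in grid:
                raise ValueError(f"initial {name} must be a grid member")

    def to_search_space(self) -> SearchSpace:
        return SearchSpace(
            ("learning_rate", "batch_size", "dense_neurons"),
            (self.learning_rate, self.batch_size, self.dense_neurons),
        )


@dataclass(frozen=True)
class TrainEvalResult:
    """Outcome of training one candidate configuration for a few epochs."""

    loss: float          # validation mean cross-entropy
    accuracy: float      # validation accuracy in [0, 1]
    epochs: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.loss) or self.loss < 0:
            raise ValueError("validation loss must be finite and >= 0")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class FeatureSelectionResult:
    mask: np.ndarray      # boolean inclusion flag per feature
    fitness: float
    trace: ConvergenceTrace

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("feature mask must include at least one feature")

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "selected_features": np.flatnonzero(self.mask).tolist(),
                    "n_features": int(self.mask.size),
                    "fitness": float(self.fitness),
                },
                fh,
            )


def model_complexity(config: dict, space: HyperparamSpace) -> float:
    """Capacity penalty: dense width / max grid width, in (0, 1]."""
    return float(config["dense_neurons"]) / max(space.dense_neurons)


def hyperparam_fitness(
    config: dict,
    train_eval_fn: Callable[[dict], TrainEvalResult],
    lam: float,
    space: HyperparamSpace,
) -> float:
    """Validation loss plus ``lam`` times the capacity penalty."""
    result = train_eval_fn(config)
    if not np.isfinite(result.loss):
        raise ValueError(f"non-finite validation loss for config {config}")
    return result.loss + lam * model_complexity(config, space)


def tune(
    space: HyperparamSpace,
    train_eval_fn: Callable[[dict], TrainEvalResult],
    lam: float = 0.1,
    aco_config: ACOConfig | None = None,
) -> tuple[dict, ConvergenceTrace]:
    """ACO search over the hyperparameter grid; returns the best config found.

    Best-so-far retention inside the optimizer guarantees the returned
    configuration's fitness is the minimum over every evaluated one.
    """
    if aco_config is None:
        aco_config = ACOConfig()
    search = space.to_search_space()
    cache: dict[tuple, float] = {}

    def fitness(solution: AntSolution) -> float:
        key = tuple(solution.choices)
        if key not in cache:
            cache[key] = hyperparam_fitness(
                search.decode(key), train_eval_fn, lam, space
            )
        return cache[key]

    best, trace = optimize(search, fitness, aco_config)
    return search.decode(best.choices), trace


def select_features_aco(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 0.02,
    aco_config: ACOConfig | None = None,
    classifier_seed: int = 0,
) -> FeatureSelectionResult:
    """Wrapper feature selection: one {include, exclude} ACO layer per feature.

    Fitness of a subset S is the validation log-loss of a regularized linear
    softmax trained on S (fixed stratified 70/30 split) plus
    ``lam * |S| / p``. The empty subset is assigned +inf so at least one
    feature always survives.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be (n, p) with one label per row")
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    if aco_config is None:
        aco_config = ACOConfig(n_ants=16, max_iterations=40, patience=12, rho=0.2)
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=0.3, random_state=classifier_seed, stratify=y
    )
    space = SearchSpace(
        tuple(f"f{i}" for i in range(p)),
        tuple(("exclude", "include") for _ in range(p)),
    )
    cache: dict[tuple, float] = {}

    def subset_loss(mask: np.ndarray) -> float:
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            return np.inf
        clf = LogisticRegression(max_iter=200, random_state=classifier_seed)
        clf.fit(X_tr[:, cols], y_tr)
        probs = clf.predict_proba(X_va[:, cols])
        return float(log_loss(y_va, probs, labels=clf.classes_)) + lam * cols.size / p

    def fitness(solution: AntSolution) -> float:
        key = tuple(solution.choices)
        if key not in cache:
            cache[key] = subset_loss(np.array(key, dtype=bool))
        return cache[key]

    best, trace = optimize(space, fitness, aco_config)
    mask = np.array(best.choices, dtype=bool)
    if not mask.any():  # all ants proposed empty subsets only; keep best single
        singles = [subset_loss(np.eye(p, dtype=bool)[j]) for j in range(p)]
        mask = np.eye(p, dtype=bool)[int(np.argmin(singles))]
        return FeatureSelectionResult(mask, float(min(singles)), trace)
    return FeatureSelectionResult(mask, float(best.fitness), trace)
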