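"""Class-imbalance mitigation: SMOTE oversampling and weighted cross-entropy.

SMOTE synthesizes minority-class samples by interpolating between an
existing sample and one of its k nearest same-class neighbours:

    x_new = x_i + u * (x_nn - x_i),   u ~ Uniform(0, 1)

Neighbour search runs on flattened, bicubic-downsampled (64x64) copies for
speed; the interpolation itself happens at full resolution between the
chosen parents, so synthetic samples are exact convex combinations of two
originals and stay inside the [0, 1] pixel range.

Class weights are inverse-frequency, ``w_c = N_total / (C * N_c)``, so a
balanced dataset gets unit weights and ``sum_c w_c * N_c == N_total``.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize
from sklearn.neighbors import NearestNeighbors

from .data import LabelledDataset

__all__ = ["smote_resample", "class_weights", "weighted_cross_entropy"]

_NEIGHBOR_RES = (64, 64)


def _neighbor_space(images: np.ndarray) -> np.ndarray:
    """Flatten images for neighbour search, downsampling if above 64x64."""
    n, h, w = images.shape
    if h <= _NEIGHBOR_RES[0] and w <= _NEIGHBOR_RES[1]:
        return images.reshape(n, -1)
    small = np.stack(
        [resize(img, _NEIGHBOR_RES, order=3, anti_aliasing=True) for img in images]
    )
    return small.reshape(n, -1)


def smote_resample(
    dataset: LabelledDataset,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
    target: str | dict[int, int] = "majority",
) -> LabelledDataset:
    """Oversample minority classes up to ``target`` per-class counts.

    ``target`` is either ``"majority"`` (raise every class to the largest
    class count) or a mapping {class id: desired count}. Originals are kept
    untouched and synthetic samples are appended with their flag set.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    counts = dataset.class_counts()
    if target == "majority":
        goal = {c: int(counts.max()) for c in range(dataset.n_classes)}
    else:
        goal = {int(c): int(v) for c, v in target.items()}
    new_images, new_labels = [], []
    for c, want in goal.items():
        have = int(counts[c])
        n_new = want - have
        if n_new < 0:
            raise ValueError(
                f"target {want} for class {dataset.class_names[c]!r} is below "
                f"its current count {have}; undersampling is not supported"
            )
        if n_new == 0:
            continue
        if have < 2:
            raise ValueError(
                f"class {dataset.class_names[c]!r} has {have} sample(s); "
                "need >= 2 to interpolate"
            )
        idx = np.where(dataset.labels == c)[0]
        originals = dataset.images[idx]
        k = min(k_neighbors, have - 1)
        nn = NearestNeighbors(n_neighbors=k)
        nn.fit(_neighbor_space(originals))
        # querying without X excludes each point from its own neighbour list
        neighbors = nn.kneighbors(return_distance=False)  # (have, k)
        for _ in range(n_new):
            i = int(rng.integers(have))
            j = int(neighbors[i][int(rng.integers(k))])
            u = float(rng.uniform())
            new_images.append(originals[i] + u * (originals[j] - originals[i]))
            new_labels.append(c)
    if not new_images:
        return dataset
    images = np.concatenate([dataset.images, np.stack(new_images)])
    labels = np.concatenate([dataset.labels, np.array(new_labels)])
    synthetic = np.concatenate(
        [dataset.synthetic, np.ones(len(new_labels), dtype=bool)]
    )
    return LabelledDataset(images, labels, dataset.class_names, synthetic)


def class_weights(counts: np.ndarray | list[int]) -> np.ndarray:
    """Inverse-frequency weights ``w_c = N / (C * N_c)``; balanced → all ones."""
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("every class count must be >= 1")
    return counts.sum() / (len(counts) * counts)


def weighted_cross_entropy(
    probs: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    eps: float = 1e-12,
) -> float:
    """Mean of ``w_{y_i} * (-log p_i[y_i])`` over samples.

    Rows of ``probs`` must sum to 1 within 1e-6; probabilities are clipped to
    ``[eps, 1]`` before the log.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if probs.ndim != 2 or len(probs) != len(labels):
        raise ValueError("probs must be (n, C) with one row per label")
    if probs.shape[1] != len(weights):
        raise ValueError("weights length must equal the class count")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each probability row must sum to 1 within 1e-6")
    if len(labels) and (labels.min() < 0 or labels.max() >= probs.shape[1]):
        raise ValueError("label out of range")
    p = np.clip(probs[np.arange(len(labels)), labels], eps, 1.0)
    return float(np.mean(weights[labels] * -np.log(p)))
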