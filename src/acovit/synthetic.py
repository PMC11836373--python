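"""Synthetic OCT-like fixtures, toy optimizer landscapes and feature matrices.

The image generator emulates the gross appearance of a retinal B-scan: a
stack of smooth horizontal bands of graded intensity (the retinal layers)
with a mild sinusoidal warp, one class-specific lesion overlay, and
multiplicative speckle — the noise model appropriate to coherent imaging:

* ``CNV``    — one bright elliptical blob below the band stack
               (neovascular membrane under the retina);
* ``DME``    — 1–3 dark round pockets inside the bands (intraretinal fluid);
* ``Drusen`` — 3–8 small bright bumps deforming a band boundary
               (sub-RPE deposits);
* ``Normal`` — clean bands, no overlay.

Class imbalance defaults mirror the Kermany OCT benchmark's printed
per-class proportions 37,206 : 11,349 : 8,617 : 26,323
(CNV : DME : Drusen : Normal), scaled to any requested total.

These fixtures are synthetic by construction: they reproduce layered
geometry, lesion polarity and speckle statistics, not the appearance
statistics of real scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aco import SearchSpace
from .data import LabelledDataset

__all__ = [
    "CLASS_NAMES",
    "KERMANY_COUNTS",
    "SyntheticSpec",
    "ToyLandscape",
    "scaled_kermany_counts",
    "generate_oct_like",
    "generate_dataset",
    "toy_landscape",
    "informative_features",
]

CLASS_NAMES = ("CNV", "DME", "Drusen", "Normal")
KERMANY_COUNTS = (37206, 11349, 8617, 26323)


def scaled_kermany_counts(total: int) -> tuple[int, ...]:
    """Scale the benchmark per-class counts to ``total`` (largest remainder)."""
    if total < 4:
        raise ValueError("need total >= 4 to represent four classes")
    weights = np.array(KERMANY_COUNTS, dtype=np.float64)
    exact = weights / weights.sum() * total
    floors = np.floor(exact).astype(int)
    rem = total - floors.sum()
    order = np.argsort(-(exact - floors), kind="stable")
    floors[order[:rem]] += 1
    return tuple(int(c) for c in floors)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters for OCT-like fixtures."""

    height: int = 64
    width: int = 64
    counts: tuple[int, int, int, int] = (120, 40, 30, 90)
    speckle_sigma: float = 0.05
    lesion_amplitude: tuple[float, float] = (0.2, 0.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("images must be at least 16x16")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be >= 0")
        if sum(c > 0 for c in self.counts) < 2:
            raise ValueError("at least two classes must be non-empty")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be >= 0")


def _band_template(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Warped layer-stack base image and the per-pixel warped row coordinate.

    All base randomness is drawn here, *before* any overlay randomness, so two
    classes generated from the same seed share an identical band template.
    """
    h, w = spec.height, spec.width
    n_bands = int(rng.integers(4, 7))
    top = rng.uniform(0.18, 0.23)
    bottom = rng.uniform(0.74, 0.80)
    edges = np.linspace(top, bottom, n_bands + 1)
    edges += rng.uniform(-0.01, 0.01, size=edges.shape)
    intensities = rng.uniform(0.45, 0.65, size=n_bands)
    intensities[0] = rng.uniform(0.70, 0.80)   # bright inner limiting band
    intensities[-1] = rng.uniform(0.70, 0.80)  # bright RPE band
    amp = rng.uniform(0.5, 1.5)
    freq = rng.uniform(0.5, 1.5)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.arange(w)
    warp = amp * np.sin(2 * np.pi * freq * x / w + phase)
    rows = np.arange(h)[:, None] - warp[None, :]  # warped row coordinate
    img = np.full((h, w), 0.06)
    frac = rows / h
    for b in range(n_bands):
        mask = (frac >= edges[b]) & (frac < edges[b + 1])
        img[mask] = intensities[b]
    # soften boundaries a touch for less cartoonish layers
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(img, sigma=0.7)
    return np.clip(img, 0.0, 1.0), frac


def _overlay(
    class_id: int,
    img: np.ndarray,
    frac: np.ndarray,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the class lesion; return (image, boolean lesion mask)."""
    h, w = img.shape
    lo, hi = spec.lesion_amplitude
    mask = np.zeros_like(img, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    if class_id == 0:  # CNV: bright ellipse below the band stack
        cy = rng.uniform(0.86, 0.92) * h
        cx = rng.uniform(0.30, 0.70) * w
        ry = rng.uniform(0.05, 0.08) * h
        rx = rng.uniform(0.14, 0.22) * w
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img = img + rng.uniform(lo, hi) * mask
    elif class_id == 1:  # DME: dark round fluid pockets inside the bands
        for _ in range(int(rng.integers(2, 5))):
            cy = rng.uniform(0.38, 0.62) * h
            cx = rng.uniform(0.15, 0.85) * w
            r = rng.uniform(0.07, 0.12) * min(h, w)
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            img = img - rng.uniform(lo, hi) * m * (~mask)
            mask |= m
    elif class_id == 2:  # Drusen: small bright bumps on a deep band boundary
        by = rng.uniform(0.70, 0.76)
        for _ in range(int(rng.integers(4, 10))):
            cx = rng.uniform(0.1, 0.9) * w
            rx = rng.uniform(0.03, 0.06) * w
            ry = rng.uniform(0.04, 0.07) * h
            cy = by * h
            m = ((yy - (cy - ry)) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
            img = np.where(m & ~mask, img + rng.uniform(lo, hi), img)
            mask |= m
    elif class_id != 3:
        raise ValueError(f"class_id must be 0..3, got {class_id}")
    return np.clip(img, 0.0, 1.0), mask


def generate_oct_like(
    class_id: int,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    return_mask: bool = False,
):
    """One OCT-like image for ``class_id`` (0=CNV, 1=DME, 2=Drusen, 3=Normal).

    With ``speckle_sigma == 0`` the output is deterministic given the
    generator state; the band template depends only on draws made before the
    overlay, so same-state images of different classes differ only inside
    the lesion mask.
    """
    img, frac = _band_template(spec, rng)
    img, mask = _overlay(class_id, img, frac, spec, rng)
    if spec.speckle_sigma > 0:
        z = rng.standard_normal(img.shape)
        img = img * (1.0 + spec.speckle_sigma * z)
    img = np.clip(img, 0.0, 1.0)
    if return_mask:
        return img, mask
    return img


def generate_dataset(spec: SyntheticSpec) -> LabelledDataset:
    """Labelled dataset with exactly the requested per-class counts.

    Each sample draws from its own child generator spawned from ``spec.seed``,
    so datasets are reproducible and samples independent; the final order is
    a seeded shuffle.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = sum(spec.counts)
    children = ss.spawn(n_total + 1)
    images, labels = [], []
    k = 0
    for class_id, count in enumerate(spec.counts):
        for _ in range(count):
            rng = np.random.default_rng(children[k])
            images.append(generate_oct_like(class_id, spec, rng))
            labels.append(class_id)
            k += 1
    order = np.random.default_rng(children[-1]).permutation(n_total)
    return LabelledDataset(
        np.stack(images)[order], np.array(labels)[order], CLASS_NAMES
    )


@dataclass
class ToyLandscape:
    """Enumerable fitness landscape with a known argmin, for optimizer tests."""

    space: SearchSpace
    table: dict  # tuple of choices -> fitness
    argmin: tuple[int, ...]
    unique: bool = True
    _fn: object = field(default=None, repr=False)

    def fitness_fn(self):
        table = self.table

        def fn(solution) -> float:
            return table[tuple(solution.choices)]

        return fn

    def brute_force_min(self) -> float:
        return min(self.table.values())


def _enumerate(sizes):
    import itertools

    return itertools.product(*[range(s) for s in sizes])


def toy_landscape(name: str) -> ToyLandscape:
    """Named toy landscapes: ``additive_4x5``, ``deceptive_2x2``, ``flat``."""
    if name == "additive_4x5":
        # Separable per-layer costs with a unique minimum at (2, 0, 4, 1).
        costs = [
            [0.40, 0.25, 0.05, 0.55, 0.80],
            [0.03, 0.50, 0.30, 0.70, 0.45],
            [0.60, 0.35, 0.50, 0.20, 0.07],
            [0.55, 0.04, 0.25, 0.65, 0.40],
        ]
        space = SearchSpace(
            tuple(f"layer{i}" for i in range(4)),
            tuple(tuple(f"c{j}" for j in range(5)) for _ in range(4)),
        )
        table = {
            cfg: sum(costs[i][c] for i, c in enumerate(cfg))
            for cfg in _enumerate((5, 5, 5, 5))
        }
        return ToyLandscape(space, table, (2, 0, 4, 1), unique=True)
    if name == "deceptive_2x2":
        # Global optimum sits off the greedy (per-layer marginal) path.
        space = SearchSpace(
            ("layer0", "layer1"), (("a", "b"), ("a", "b"))
        )
        table = {(0, 0): 0.10, (0, 1): 1.00, (1, 0): 0.90, (1, 1): 0.15}
        return ToyLandscape(space, table, (0, 0), unique=True)
    if name == "flat":
        space = SearchSpace(
            ("layer0", "layer1"), (("a", "b", "c"), ("a", "b", "c"))
        )
        table = {cfg: 1.0 for cfg in _enumerate((3, 3))}
        return ToyLandscape(space, table, (0, 0), unique=False)
    raise ValueError(f"unknown landscape {name!r}")


def informative_features(
    n: int,
    p: int,
    k_informative: int,
    rng: np.random.Generator,
    n_classes: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian feature matrix where only the first ``k_informative`` columns
    carry class signal (class means separated by 2 standard deviations).

    Returns ``(X, y, ground_truth_mask)``.
    """
    if not (1 <= k_informative <= p):
        raise ValueError("need 1 <= k_informative <= p")
    y = np.arange(n) % n_classes
    y = y[rng.permutation(n)]
    X = rng.standard_normal((n, p))
    # effect size 2: adjacent class means are 2 sigma apart on signal columns
    shifts = (y - (n_classes - 1) / 2.0) * 2.0
    X[:, :k_informative] += shifts[:, None]
    mask = np.zeros(p, dtype=bool)
    mask[:k_informative] = True
    return X, y, mask
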