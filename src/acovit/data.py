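"""Shared data containers: grayscale images and labelled image datasets.

Images are 2-D ``float64`` arrays with values in [0, 1]. Datasets keep a
uniform-shape image stack, integer class labels, class names and a per-sample
synthetic flag (set for interpolated SMOTE samples so provenance survives a
round-trip to disk).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "as_gray_image",
    "LabelledDataset",
    "read_gray_image",
    "write_gray_image",
]


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and coerce an array to a [0, 1] float64 grayscale image."""
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return img


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale image file, mapped linearly to [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 3:  # collapse RGB(A) written by other tools
        raw = raw[..., :3].mean(axis=-1)
    info = np.iinfo(raw.dtype) if np.issubdtype(raw.dtype, np.integer) else None
    img = raw.astype(np.float64)
    if info is not None:
        img /= info.max
    return np.clip(img, 0.0, 1.0)


def write_gray_image(path: str | Path, image: np.ndarray, bitdepth: int = 8) -> None:
    """Write a [0, 1] image as 8-bit (default) or 16-bit grayscale PNG/TIFF."""
    img = as_gray_image(image)
    if bitdepth == 8:
        out = np.round(img * 255.0).astype(np.uint8)
    elif bitdepth == 16:
        out = np.round(img * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8 or 16")
    iio.imwrite(path, out)


@dataclass
class LabelledDataset:
    """Images with integer class labels in ``{0..C-1}``.

    ``synthetic`` flags samples created by oversampling rather than drawn
    from the source distribution.
    """

    images: np.ndarray  # (n, H, W) float64 in [0, 1]
    labels: np.ndarray  # (n,) int
    class_names: tuple[str, ...]
    synthetic: np.ndarray = field(default=None)  # (n,) bool

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, H, W) stack")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        c = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= c):
            raise ValueError(f"labels must lie in [0, {c - 1}]")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)
            if len(self.synthetic) != len(self.labels):
                raise ValueError("synthetic flag length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: Sequence[int]) -> "LabelledDataset":
        idx = np.asarray(indices, dtype=np.int64)
        return LabelledDataset(
            self.images[idx], self.labels[idx], self.class_names, self.synthetic[idx]
        )

    def to_directory(self, root: str | Path, bitdepth: int = 8) -> None:
        """Write a directory-per-class layout plus a ``manifest.csv``.

        Synthetic samples get a ``_syn####`` filename suffix.
        """
        root = Path(root)
        root.mkdir(parents=True, exist_ok=True)
        rows = []
        per_class_idx = {name: 0 for name in self.class_names}
        syn_idx = 0
        for i in range(len(self)):
            name = self.class_names[self.labels[i]]
            cdir = root / name
            cdir.mkdir(exist_ok=True)
            if self.synthetic[i]:
                fname = f"{name}_{per_class_idx[name]:05d}_syn{syn_idx:04d}.png"
                syn_idx += 1
            else:
                fname = f"{name}_{per_class_idx[name]:05d}.png"
            per_class_idx[name] += 1
            write_gray_image(cdir / fname, self.images[i], bitdepth=bitdepth)
            rows.append((f"{name}/{fname}", name, int(self.synthetic[i])))
        with open(root / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["filename", "class", "synthetic"])
            w.writerows(rows)

    @classmethod
    def from_directory(cls, root: str | Path) -> "LabelledDataset":
        """Read a directory-per-class layout (classes sorted by name)."""
        root = Path(root)
        class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
        if not class_dirs:
            raise ValueError(f"no class subdirectories under {root}")
        images, labels, synthetic = [], [], []
        names = tuple(p.name for p in class_dirs)
        for ci, cdir in enumerate(class_dirs):
            for f in sorted(cdir.iterdir()):
                if f.suffix.lower() not in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}:
                    continue
                images.append(read_gray_image(f))
                labels.append(ci)
                synthetic.append("_syn" in f.stem)
        return cls(np.stack(images), np.array(labels), names, np.array(synthetic))
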