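"""Windowed-attention Vision Transformer with multi-scale patches.

The classifier tokenizes a B-scan at several patch sizes (multi-scale
embedding), runs shared encoder blocks over each scale's token grid, and
fuses mean-pooled per-scale summaries in a dense head. Three modifications
to plain ViT attention target OCT imagery:

* **Windowed attention** — token ``i`` attends only to tokens within
  Chebyshev radius ``r`` on its scale's patch grid (self-inclusive), cutting
  the cost from O(N^2 d) to O(N k d) with ``k = |N(i)| <= (2r+1)^2``.
* **Relative positional bias** — a learnable per-head table ``P(Δrow, Δcol)``
  added to attention logits, so interactions depend on displacement, not
  absolute position. Initialized to zero.
* **Content-aware weighting** — per-patch pixel variance, min-max normalized
  over the image's patches, enters the logits as an additive bias
  ``γ · g_j`` with learnable gain γ. High-variance patches (layer
  boundaries, lesions) therefore draw extra attention.

Per head the attention logit is

    logit(i, j) = (q_i · k_j) / sqrt(d_h) + P(offset(i, j)) + γ · g_j

for ``j ∈ N(i)`` and −∞ otherwise, followed by a softmax over ``N(i)``.

Implemented on the package's reverse-mode autodiff core and trained with
Adam; everything is float64 NumPy and bitwise deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Tensor, concat, einsum, gelu, layer_norm, softmax

__all__ = [
    "ModelConfig",
    "PatchGrid",
    "WindowSpec",
    "MultiScaleEmbeddings",
    "extract_patches",
    "embed_multiscale",
    "neighborhood",
    "neighbor_table",
    "content_weights",
    "windowed_attention",
    "count_attention_pairs",
    "forward_classify",
    "ViTClassifier",
    "Adam",
]


@dataclass(frozen=True)
class ModelConfig:
    scales: tuple[int, ...] = (8, 16)
    d: int = 64
    heads: int = 4
    blocks: int = 2
    window_radius: int = 1
    dense_neurons: int = 512
    n_classes: int = 4
    mlp_ratio: int = 2
    content_gain_init: float = 0.25
    dtype: str = "float32"  # training precision; float64 for oracle checks
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d % self.heads != 0:
            raise ValueError("d must be divisible by heads")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.scales or any(s < 1 for s in self.scales):
            raise ValueError("scales must be positive")
        if self.window_radius < 0 or self.blocks < 1 or self.dense_neurons < 1:
            raise ValueError("invalid architecture sizes")

    def to_dict(self) -> dict:
        return {
            "scales": list(self.scales), "d": self.d, "heads": self.heads,
            "blocks": self.blocks, "window_radius": self.window_radius,
            "dense_neurons": self.dense_neurons, "n_classes": self.n_classes,
            "mlp_ratio": self.mlp_ratio,
            "content_gain_init": self.content_gain_init, "dtype": self.dtype,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["scales"] = tuple(d["scales"])
        return cls(**d)


@dataclass(frozen=True)
class PatchGrid:
    patch_size: tuple[int, int]
    rows: int
    cols: int

    @property
    def token_count(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class WindowSpec:
    """Neighborhoods within Chebyshev radius ``r`` on a token grid.

    ``idx[i]`` lists the members of N(i) padded to ``k_max`` entries;
    ``valid[i]`` marks the real ones. Every token neighbours itself.
    """

    radius: int
    grid: PatchGrid
    idx: np.ndarray = field(repr=False)     # (N, k_max) int
    valid: np.ndarray = field(repr=False)   # (N, k_max) bool
    offset_index: np.ndarray = field(repr=False)  # (N, k_max) int into bias table

    @property
    def k_max(self) -> int:
        return self.idx.shape[1]

    @property
    def table_size(self) -> int:
        return (2 * self.radius + 1) ** 2


@dataclass
class MultiScaleEmbeddings:
    """Per-scale token sequences sharing one embedding dimension."""

    tokens: list[np.ndarray]   # per scale: (token_count, d)
    grids: list[PatchGrid]
    d: int

    @property
    def token_count(self) -> int:
        return sum(g.token_count for g in self.grids)


# --- tokenization ------------------------------------------------------------

def _pad_to_multiple(images: np.ndarray, m: int, n: int) -> np.ndarray:
    """Reflect-pad (bottom/right) a (..., H, W) stack to multiples of (m, n)."""
    h, w = images.shape[-2:]
    ph = (-h) % m
    pw = (-w) % n
    if ph == 0 and pw == 0:
        return images
    pad = [(0, 0)] * (images.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(images, pad, mode="reflect")


def extract_patches(
    image: np.ndarray, patch_size: int | tuple[int, int]
) -> tuple[np.ndarray, PatchGrid]:
    """Tile ``image`` into patches, reflect-padding to a whole number of tiles.

    Patches are enumerated row-major from the top-left; reassembling them
    reproduces the padded image exactly.
    """
    m, n = (patch_size, patch_size) if np.isscalar(patch_size) else patch_size
    if m < 1 or n < 1:
        raise ValueError("patch size must be positive")
    img = np.asarray(image, dtype=np.float64)
    padded = _pad_to_multiple(img, m, n)
    rows, cols = padded.shape[0] // m, padded.shape[1] // n
    patches = (
        padded.reshape(rows, m, cols, n).transpose(0, 2, 1, 3).reshape(-1, m, n)
    )
    return patches, PatchGrid((m, n), rows, cols)


def _patchify_batch(images: np.ndarray, m: int) -> tuple[np.ndarray, PatchGrid]:
    """(B, H, W) -> (B, N, m*m) flattened square patches plus the grid."""
    padded = _pad_to_multiple(images, m, m)
    b = padded.shape[0]
    rows, cols = padded.shape[1] // m, padded.shape[2] // m
    flat = (
        padded.reshape(b, rows, m, cols, m)
        .transpose(0, 1, 3, 2, 4)
        .reshape(b, rows * cols, m * m)
    )
    return flat, PatchGrid((m, m), rows, cols)


def _batch_content_weights(flat: np.ndarray) -> np.ndarray:
    """(B, N, p) flattened patches -> (B, N) normalized variances."""
    var = flat.var(axis=-1)
    lo = var.min(axis=-1, keepdims=True)
    hi = var.max(axis=-1, keepdims=True)
    span = hi - lo
    return np.where(span > 0, (var - lo) / np.where(span > 0, span, 1.0), 0.0)


def content_weights(patches: np.ndarray) -> np.ndarray:
    """Per-patch pixel variance of one image's (N, m, n) patches, min-max
    normalized to [0, 1] over the image; all-equal variances map to 0."""
    if patches.ndim != 3 or patches.shape[0] < 1:
        raise ValueError("expected a non-empty (N, m, n) patch stack")
    return _batch_content_weights(patches.reshape(1, patches.shape[0], -1))[0]


def neighborhood(i: int, grid: PatchGrid, r: int) -> np.ndarray:
    """Indices within Chebyshev distance ``r`` of token ``i`` (incl. ``i``)."""
    ri, ci = divmod(int(i), grid.cols)
    rows = np.arange(max(0, ri - r), min(grid.rows, ri + r + 1))
    cols = np.arange(max(0, ci - r), min(grid.cols, ci + r + 1))
    return (rows[:, None] * grid.cols + cols[None, :]).ravel()


def neighbor_table(grid: PatchGrid, r: int) -> WindowSpec:
    """Padded neighbour-index / validity / relative-offset tables for a grid."""
    n = grid.token_count
    k_max = min(2 * r + 1, grid.rows) * min(2 * r + 1, grid.cols)
    idx = np.zeros((n, k_max), dtype=np.int64)
    valid = np.zeros((n, k_max), dtype=bool)
    off = np.zeros((n, k_max), dtype=np.int64)
    width = 2 * r + 1
    for i in range(n):
        nb = neighborhood(i, grid, r)
        idx[i, : len(nb)] = nb
        valid[i, : len(nb)] = True
        dr = nb // grid.cols - i // grid.cols
        dc = nb % grid.cols - i % grid.cols
        off[i, : len(nb)] = (dr + r) * width + (dc + r)
    return WindowSpec(r, grid, idx, valid, off)


def count_attention_pairs(grid: PatchGrid, r: int) -> int:
    """Total attended pairs ``sum_i |N(i)|``; bounded by N * (2r+1)^2."""
    rows = np.arange(grid.rows)
    row_extent = np.minimum(rows + r, grid.rows - 1) - np.maximum(rows - r, 0) + 1
    cols = np.arange(grid.cols)
    col_extent = np.minimum(cols + r, grid.cols - 1) - np.maximum(cols - r, 0) + 1
    return int(row_extent.sum() * col_extent.sum())


# --- parameters --------------------------------------------------------------

def init_params(config: ModelConfig) -> dict[str, Tensor]:
    rng = np.random.default_rng(config.seed)
    d, table = config.d, (2 * config.window_radius + 1) ** 2
    dt = np.dtype(config.dtype)

    def w(*shape):
        return Tensor(rng.normal(0.0, 0.02, size=shape).astype(dt))

    p: dict[str, Tensor] = {}
    for s in config.scales:
        p[f"embed_w_{s}"] = w(s * s, d)
        p[f"embed_b_{s}"] = Tensor(np.zeros(d))
        p[f"scale_emb_{s}"] = w(d)
    for b in range(config.blocks):
        for name in ("q", "k", "v", "proj"):
            p[f"b{b}_{name}_w"] = w(d, d)
            p[f"b{b}_{name}_b"] = Tensor(np.zeros(d))
        p[f"b{b}_relpos"] = Tensor(np.zeros((config.heads, table)))
        p[f"b{b}_ln1_g"] = Tensor(np.ones(d))
        p[f"b{b}_ln1_b"] = Tensor(np.zeros(d))
        p[f"b{b}_ln2_g"] = Tensor(np.ones(d))
        p[f"b{b}_ln2_b"] = Tensor(np.zeros(d))
        hidden = config.mlp_ratio * d
        p[f"b{b}_mlp_w1"] = w(d, hidden)
        p[f"b{b}_mlp_b1"] = Tensor(np.zeros(hidden))
        p[f"b{b}_mlp_w2"] = w(hidden, d)
        p[f"b{b}_mlp_b2"] = Tensor(np.zeros(d))
    p["gamma"] = Tensor(np.array(config.content_gain_init))
    p["ln_f_g"] = Tensor(np.ones(d))
    p["ln_f_b"] = Tensor(np.zeros(d))
    p["head_w1"] = w(d * len(config.scales), config.dense_neurons)
    p["head_b1"] = Tensor(np.zeros(config.dense_neurons))
    p["head_w2"] = w(config.dense_neurons, config.n_classes)
    p["head_b2"] = Tensor(np.zeros(config.n_classes))
    return {k: Tensor(v.data.astype(dt)) for k, v in p.items()}


# --- attention ---------------------------------------------------------------

def _mha(
    x: Tensor,
    window: WindowSpec,
    relpos: Tensor,
    g: np.ndarray,
    gamma: Tensor,
    heads: int,
    wq, bq, wk, bk, wv, bv, wo, bo,
) -> Tensor:
    """Windowed multi-head attention over (B, N, d) tokens.

    ``g`` is the (B, N) content-weight array (a constant in the graph).
    """
    b, n, d = x.shape
    dh = d // heads
    scale = 1.0 / np.sqrt(dh)

    def split(t: Tensor) -> Tensor:  # (B,N,d) -> (B,H,N,dh)
        return t.reshape(b, n, heads, dh).transpose((0, 2, 1, 3))

    dt = x.data.dtype
    q = split(x @ wq + bq)
    k = split(x @ wk + bk)
    v = split(x @ wv + bv)
    kn = k.take(window.idx, axis=2)            # (B,H,N,k,dh)
    vn = v.take(window.idx, axis=2)
    logits = einsum("bhnd,bhnkd->bhnk", q, kn) * scale
    bias = relpos.take(window.offset_index, axis=1)  # (H,N,k)
    logits = logits + bias.reshape(1, heads, n, window.k_max)
    gn = g[:, window.idx].astype(dt)            # (B,N,k) constant
    logits = logits + gamma * Tensor(gn.reshape(b, 1, n, window.k_max))
    mask = np.where(window.valid, 0.0, -1e9).astype(dt)
    attn = softmax(logits + Tensor(mask.reshape(1, 1, n, window.k_max)), axis=-1)
    out = einsum("bhnk,bhnkd->bhnd", attn, vn)
    out = out.transpose((0, 2, 1, 3)).reshape(b, n, d)
    return out @ wo + bo


def windowed_attention(
    tokens: np.ndarray,
    window: WindowSpec,
    relpos_table: np.ndarray,
    g: np.ndarray,
    heads: int,
    gamma: float = 0.0,
    params: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Single windowed-attention layer on (N, d) tokens; returns (N, d).

    ``params`` may supply q/k/v/proj weights (keys ``q_w``, ``q_b``, ...);
    otherwise they are drawn from ``seed``. ``relpos_table`` has one row per
    head over the ``(2r+1)^2`` clipped offsets.
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    n, d = tokens.shape
    if len(g) != n:
        raise ValueError(f"content weights length {len(g)} != token count {n}")
    if params is None:
        rng = np.random.default_rng(seed)
        params = {}
        for name in ("q", "k", "v", "proj"):
            params[f"{name}_w"] = rng.normal(0.0, 0.02, size=(d, d))
            params[f"{name}_b"] = np.zeros(d)
    out = _mha(
        Tensor(tokens.reshape(1, n, d)),
        window,
        Tensor(np.asarray(relpos_table, dtype=np.float64)),
        np.asarray(g, dtype=np.float64).reshape(1, n),
        Tensor(np.asarray(gamma, dtype=np.float64)),
        heads,
        Tensor(params["q_w"]), Tensor(params["q_b"]),
        Tensor(params["k_w"]), Tensor(params["k_b"]),
        Tensor(params["v_w"]), Tensor(params["v_b"]),
        Tensor(params["proj_w"]), Tensor(params["proj_b"]),
    )
    return out.data[0]


# --- the classifier ----------------------------------------------------------

def embed_multiscale(
    image: np.ndarray,
    config: ModelConfig,
    params: dict[str, Tensor] | None = None,
) -> MultiScaleEmbeddings:
    """Tokenize one image at every configured scale (linear patch projection
    plus a learnable per-scale embedding)."""
    if params is None:
        params = init_params(config)
    img = np.asarray(image, dtype=np.float64)[None]
    tokens, grids = [], []
    for s in config.scales:
        flat, grid = _patchify_batch(img, s)
        t = flat[0] @ params[f"embed_w_{s}"].data + params[f"embed_b_{s}"].data
        tokens.append(t + params[f"scale_emb_{s}"].data)
        grids.append(grid)
    return MultiScaleEmbeddings(tokens, grids, config.d)


def _log_softmax(logits: Tensor) -> Tensor:
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()


class ViTClassifier:
    """Multi-scale windowed-attention transformer for grayscale images."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params = init_params(config)
        self._windows: dict[tuple, list[WindowSpec]] = {}

    # -- forward --------------------------------------------------------------

    def _pos_emb(self, scale: int, grid: PatchGrid) -> Tensor:
        """Learned absolute position embedding for one scale's token grid.

        Created on first use for a given grid shape (deterministically from
        the model seed) so the model can localize lesions; the relative bias
        inside attention only ever sees displacements.
        """
        key = f"pos_emb_{scale}_{grid.rows}x{grid.cols}"
        if key not in self.params:
            rng = np.random.default_rng(
                (self.config.seed, scale, grid.rows, grid.cols)
            )
            emb = rng.normal(0.0, 0.02, size=(grid.token_count, self.config.d))
            self.params[key] = Tensor(emb.astype(np.dtype(self.config.dtype)))
        return self.params[key]

    def _window_specs(self, shape: tuple[int, int]) -> list[WindowSpec]:
        if shape not in self._windows:
            specs = []
            for s in self.config.scales:
                _, grid = _patchify_batch(np.zeros((1, *shape)), s)
                specs.append(neighbor_table(grid, self.config.window_radius))
            self._windows[shape] = specs
        return self._windows[shape]

    def forward(self, images: np.ndarray) -> Tensor:
        """Class logits (B, C) for a (B, H, W) image stack in [0, 1]."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        cfg, p = self.config, self.params
        specs = self._window_specs(images.shape[1:])
        pooled = []
        dt = np.dtype(cfg.dtype)
        for s, window in zip(cfg.scales, specs):
            flat, grid = _patchify_batch(images, s)
            g = _batch_content_weights(flat)  # (B, N)
            # patches centred to [-1, 1] so embeddings are not DC-dominated
            x = Tensor((2.0 * flat - 1.0).astype(dt)) @ p[f"embed_w_{s}"] \
                + p[f"embed_b_{s}"]
            x = x + self._pos_emb(s, grid)
            x = x + p[f"scale_emb_{s}"]
            for b in range(cfg.blocks):
                h = layer_norm(x, p[f"b{b}_ln1_g"], p[f"b{b}_ln1_b"])
                x = x + _mha(
                    h, window, p[f"b{b}_relpos"], g, p["gamma"], cfg.heads,
                    p[f"b{b}_q_w"], p[f"b{b}_q_b"],
                    p[f"b{b}_k_w"], p[f"b{b}_k_b"],
                    p[f"b{b}_v_w"], p[f"b{b}_v_b"],
                    p[f"b{b}_proj_w"], p[f"b{b}_proj_b"],
                )
                h2 = layer_norm(x, p[f"b{b}_ln2_g"], p[f"b{b}_ln2_b"])
                x = x + gelu(h2 @ p[f"b{b}_mlp_w1"] + p[f"b{b}_mlp_b1"]) \
                    @ p[f"b{b}_mlp_w2"] + p[f"b{b}_mlp_b2"]
            x = layer_norm(x, p["ln_f_g"], p["ln_f_b"])
            pooled.append(x.mean(axis=1))  # (B, d)
        feat = concat(pooled, axis=-1)
        hid = gelu(feat @ p["head_w1"] + p["head_b1"])
        return hid @ p["head_w2"] + p["head_b2"]

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images), axis=-1).data

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=-1)

    # -- training -------------------------------------------------------------

    def loss(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        weights: np.ndarray | None = None,
        label_smoothing: float = 0.0,
    ) -> Tensor:
        """Weighted categorical cross-entropy (mean over the batch)."""
        logits = self.forward(images)
        n, c = logits.shape
        labels = np.asarray(labels, dtype=np.int64)
        dt = np.dtype(self.config.dtype)
        onehot = np.zeros((n, c), dtype=dt)
        onehot[np.arange(n), labels] = 1.0
        if label_smoothing > 0.0:
            onehot = onehot * (1.0 - label_smoothing) + label_smoothing / c
            onehot = onehot.astype(dt)
        w = np.ones(n, dtype=dt) if weights is None else \
            np.asarray(weights, dtype=dt)[labels]
        ls = _log_softmax(logits)
        per_sample = (ls * Tensor(onehot)).sum(axis=-1)
        return -(per_sample * Tensor(w)).mean()

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 3e-3,
        class_weights: np.ndarray | None = None,
        seed: int = 0,
        augment_fn=None,
        warmup_fraction: float = 0.1,
        cosine_decay: bool = False,
        clip_norm: float = 1.0,
        ema_decay: float | None = 0.99,
        label_smoothing: float = 0.1,
    ) -> list[float]:
        """Adam training with linear warmup, cosine decay of the peak
        learning rate, global gradient-norm clipping and an exponential
        moving average of the weights (the EMA weights are what the model
        keeps — short runs are noisy and the average generalizes better).
        Returns the mean loss per epoch.

        ``augment_fn(batch_images, rng)`` may perturb each batch in-flight.
        """
        rng = np.random.default_rng(seed)
        self.forward(images[:1])  # materialize position embeddings
        opt = Adam(self.params, lr=lr)
        ema = {k: p.data.copy() for k, p in self.params.items()} \
            if ema_decay is not None else None
        history = []
        n = len(images)
        total_steps = max(1, epochs * int(np.ceil(n / batch_size)))
        warmup = max(1, int(warmup_fraction * total_steps))
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batch = images[idx]
                if augment_fn is not None:
                    batch = augment_fn(batch, rng)
                loss = self.loss(batch, labels[idx], class_weights,
                                 label_smoothing=label_smoothing)
                opt.zero_grad()
                loss.backward()
                if clip_norm is not None:
                    total = np.sqrt(sum(
                        float((p.grad ** 2).sum())
                        for p in self.params.values() if p.grad is not None
                    ))
                    if total > clip_norm:
                        scale = clip_norm / total
                        for p in self.params.values():
                            if p.grad is not None:
                                p.grad = p.grad * scale
                if step < warmup:
                    opt.lr = lr * (step + 1) / warmup
                elif cosine_decay:
                    frac = (step - warmup) / max(1, total_steps - warmup)
                    opt.lr = lr * 0.5 * (1.0 + np.cos(np.pi * frac))
                else:
                    opt.lr = lr
                opt.step()
                if ema is not None:
                    # decay warmup keeps the average honest on short runs
                    d = min(ema_decay, (1.0 + step) / (10.0 + step))
                    for k, p in self.params.items():
                        ema[k] += (1.0 - d) * (p.data - ema[k])
                step += 1
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)))
        if ema is not None:
            for k, p in self.params.items():
                p.data = ema[k]
        return history

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "ViTClassifier":
        path = Path(path)
        with open(path.with_suffix(".yaml")) as fh:
            config = ModelConfig.from_dict(yaml.safe_load(fh))
        model = cls(config)
        with np.load(path.with_suffix(".npz")) as npz:
            for k in npz.files:  # includes lazily created position embeddings
                model.params[k] = Tensor(npz[k])
        return model


def forward_classify(
    image: np.ndarray,
    params: dict[str, Tensor] | None,
    config: ModelConfig,
) -> np.ndarray:
    """Class probability vector for a single image (sums to 1)."""
    model = ViTClassifier(config)
    if params is not None:
        model.params = params
    return model.predict_proba(np.asarray(image)[None])[0]


class Adam:
    """Adam over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            p.data = p.data - self.lr * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + self.eps
            )
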