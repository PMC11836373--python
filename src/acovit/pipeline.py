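"""End-to-end pipeline: data → wavelet preprocessing → (optional) policy
search → imbalance handling → (optional) hyperparameter search → transformer
training → evaluation.

Every stage is seeded from one master seed via ``numpy``'s ``SeedSequence``
so a rerun with an identical :class:`RunConfig` reproduces the report
exactly. Artifacts (metrics CSV/YAML, convergence traces, checkpoint) land
in ``out_dir`` when one is given, so each stage can be re-run from its
predecessor's output.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import augment as aug
from .aco import ACOConfig
from .data import LabelledDataset
from .dwt import preprocess_batch
from .imbalance import class_weights, smote_resample, weighted_cross_entropy
from .metrics import MetricsReport, confusion_matrix, macro_metrics
from .synthetic import SyntheticSpec, generate_dataset
from .tuning import HyperparamSpace, TrainEvalResult, tune
from .vit import ModelConfig, ViTClassifier

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "stratified_split"]

log = logging.getLogger("acovit")

IMBALANCE_MODES = ("none", "smote", "weighted", "smote+weighted")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    # data: a directory-per-class path, or a synthetic generation spec
    data_dir: str | None = None
    synthetic: SyntheticSpec | None = field(
        default_factory=lambda: SyntheticSpec()
    )
    # preprocessing
    wavelet: str = "haar"
    dwt_levels: int = 2
    retain_fraction: float = 0.5
    # augmentation policy search
    search_augment: bool = False
    augment_lambda: float = 0.01
    augment_n_eval: int = 16        # samples per policy-fitness evaluation
    augment_iterations: int = 15    # ACO iterations for the policy search
    # imbalance handling
    imbalance_mode: str = "smote+weighted"
    smote_k: int = 5
    weights_from_original: bool = False  # weigh by pre-SMOTE counts in hybrid mode
    # model / training
    model: ModelConfig = field(default_factory=ModelConfig)
    hpo: bool = False
    hpo_lambda: float = 0.1
    hpo_epochs: int = 3
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-2
    val_fraction: float = 0.2
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.imbalance_mode not in IMBALANCE_MODES:
            raise ValueError(f"imbalance_mode must be one of {IMBALANCE_MODES}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")


@dataclass
class PipelineResult:
    model: ViTClassifier
    report: MetricsReport
    history: list[float]
    artifacts: dict[str, str] = field(default_factory=dict)


def stratified_split(
    dataset: LabelledDataset, val_fraction: float, seed: int
) -> tuple[LabelledDataset, LabelledDataset]:
    """Seeded stratified split; every class is represented in both parts."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == c)
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size))) if idx.size > 1 else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(val_idx))


class _Stage:
    """Context manager logging per-stage wall time and naming failures."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", self.name, dt)
        return False


def _load_dataset(cfg: RunConfig) -> LabelledDataset:
    if cfg.data_dir is not None:
        return LabelledDataset.from_directory(cfg.data_dir)
    if cfg.synthetic is None:
        raise ValueError("RunConfig needs data_dir or a synthetic spec")
    return generate_dataset(cfg.synthetic)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full four-stage pipeline and return the trained model,
    the validation metrics report and the paths of any written artifacts."""
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(6)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    with _Stage("load_data"):
        dataset = _load_dataset(cfg)
        original_counts = dataset.class_counts()

    with _Stage("dwt_preprocess"):
        images = preprocess_batch(
            dataset.images, cfg.wavelet, cfg.dwt_levels, cfg.retain_fraction
        )
        dataset = LabelledDataset(
            images, dataset.labels, dataset.class_names, dataset.synthetic
        )

    with _Stage("split"):
        train, val = stratified_split(dataset, cfg.val_fraction, int(seeds[0]))

    policy = None
    if cfg.search_augment:
        with _Stage("search_augment"):
            menu = aug.default_op_menu()
            probe = ViTClassifier(cfg.model)  # frozen probe net scores policies

            def probe_loss(image: np.ndarray, label: int) -> float:
                probs = probe.predict_proba(image[None])
                return weighted_cross_entropy(probs, np.array([label]),
                                              np.ones(cfg.model.n_classes))

            policy, trace = aug.search_policy(
                menu, probe_loss, train,
                aug.PolicyFitnessConfig(lam=cfg.augment_lambda,
                                        n_eval=cfg.augment_n_eval,
                                        seed=int(seeds[1])),
                ACOConfig(seed=int(seeds[1]),
                          max_iterations=cfg.augment_iterations,
                          patience=max(2, cfg.augment_iterations // 3)),
            )
            if out:
                trace.to_csv(out / "augment_trace.csv")
                with open(out / "augment_policy.yaml", "w") as fh:
                    yaml.safe_dump(policy.to_mapping(menu), fh)
                artifacts["augment_policy"] = str(out / "augment_policy.yaml")

    with _Stage("imbalance"):
        weights = None
        if cfg.imbalance_mode in ("smote", "smote+weighted"):
            train = smote_resample(
                train, cfg.smote_k, np.random.default_rng(int(seeds[2]))
            )
        if cfg.imbalance_mode in ("weighted", "smote+weighted"):
            counts = (
                original_counts
                if cfg.weights_from_original
                else train.class_counts()
            )
            weights = class_weights(counts)

    model_cfg = cfg.model
    lr, batch = cfg.learning_rate, cfg.batch_size
    if cfg.hpo:
        with _Stage("hyperparameter_search"):
            space = HyperparamSpace()

            def train_eval(conf: dict) -> TrainEvalResult:
                probe_cfg = ModelConfig(**{
                    **model_cfg.to_dict(),
                    "dense_neurons": int(conf["dense_neurons"]),
                })
                m = ViTClassifier(probe_cfg)
                m.fit(train.images, train.labels, epochs=cfg.hpo_epochs,
                      batch_size=int(conf["batch_size"]),
                      lr=float(conf["learning_rate"]),
                      class_weights=weights, seed=int(seeds[3]))
                probs = m.predict_proba(val.images)
                loss = weighted_cross_entropy(
                    probs, val.labels, np.ones(probe_cfg.n_classes))
                acc = float((probs.argmax(1) == val.labels).mean())
                return TrainEvalResult(loss, acc, cfg.hpo_epochs)

            best, trace = tune(space, train_eval, cfg.hpo_lambda,
                               ACOConfig(seed=int(seeds[3]), n_ants=6,
                                         max_iterations=8, patience=4))
            lr = float(best["learning_rate"])
            batch = int(best["batch_size"])
            model_cfg = ModelConfig(**{
                **model_cfg.to_dict(), "dense_neurons": int(best["dense_neurons"]),
            })
            if out:
                trace.to_csv(out / "hpo_trace.csv")
                with open(out / "hpo_best.yaml", "w") as fh:
                    yaml.safe_dump(best, fh)
                artifacts["hpo_best"] = str(out / "hpo_best.yaml")

    with _Stage("train"):
        model = ViTClassifier(model_cfg)
        augment_fn = None
        if policy is not None and policy.steps:
            def augment_fn(batch_imgs, rng):  # noqa: E306
                return np.stack(
                    [aug.apply_policy(im, policy, rng) for im in batch_imgs]
                )
        history = model.fit(
            train.images, train.labels, epochs=cfg.epochs, batch_size=batch,
            lr=lr, class_weights=weights, seed=int(seeds[4]),
            augment_fn=augment_fn,
        )

    with _Stage("evaluate"):
        preds = model.predict(val.images)
        cm = confusion_matrix(val.labels, preds, dataset.n_classes)
        report = macro_metrics(cm)
        # minority class resolved from the ORIGINAL (pre-resampling) supports
        minority = int(np.argmin(original_counts))
        row = cm[minority].sum()
        report.minority_class_accuracy = (
            float(cm[minority, minority] / row) if row > 0 else 0.0
        )
        report.extra["n_val"] = int(len(val))
        report.extra["imbalance_mode"] = cfg.imbalance_mode

    if out:
        with _Stage("write_artifacts"):
            report.to_csv(out / "metrics.csv")
            with open(out / "metrics.yaml", "w") as fh:
                yaml.safe_dump(report.to_dict(), fh)
            model.save(out / "checkpoint")
            cfg_dict = asdict(cfg)
            cfg_dict["model"] = cfg.model.to_dict()
            with open(out / "run_config.yaml", "w") as fh:
                yaml.safe_dump(cfg_dict, fh)
            artifacts.update(
                metrics=str(out / "metrics.csv"),
                checkpoint=str(out / "checkpoint.npz"),
                run_config=str(out / "run_config.yaml"),
            )

    return PipelineResult(model, report, history, artifacts)
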