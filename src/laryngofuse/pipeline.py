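"""End-to-end orchestration: generate/ingest -> filter -> extract -> tune ->
train -> evaluate, plus artifact writing and reproducibility records."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .autoencoder import AutoencoderClassifier
from .extractors import (
    ExtractorSpec,
    build_alexnet_extractor,
    build_capsnet_extractor,
    build_squeezenet_extractor,
    extract_features,
)
from .labels import ClassLabel, CLASS_NAMES, N_CLASSES
from .metrics import MetricsReport, compute_metrics
from .ooa import DEFAULT_AE_SPACE, tune_ae_hyperparams
from .preprocessing import FilterConfig, preprocess_dataset
from .synthetic import DatasetManifest, GeneratorConfig, generate_dataset, load_patch

logger = logging.getLogger("laryngofuse")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the failing stage."""


@dataclass
class ExtractorTrainConfig:
    input_side: int = 64
    epochs: int = 3
    batch_size: int = 16
    learning_rate: float = 1e-3


@dataclass
class OOAConfig:
    n: int = 4
    T: int = 3
    dims: list[dict] = field(default_factory=lambda: [dict(d) for d in DEFAULT_AE_SPACE])
    fitness_metric: str = "precision"
    ae_epochs: int = 40


@dataclass
class AETrainConfig:
    recon_epochs: int = 60
    finetune_epochs: int = 120
    # optional training-length checkpoints: evaluate the classifier on the
    # test split at these fine-tuning epochs during one training run
    checkpoints: tuple[int, ...] = ()


@dataclass
class RunConfig:
    """Full pipeline configuration; all sub-configs validate on use."""

    seed: int = 0
    out_dir: str = "runs/laryngofuse"
    data_dir: str | None = None          # ingest an existing tree instead of generating
    data: GeneratorConfig = field(default_factory=GeneratorConfig)
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    filter: FilterConfig = field(default_factory=FilterConfig)
    extractor: ExtractorTrainConfig = field(default_factory=ExtractorTrainConfig)
    ooa: OOAConfig = field(default_factory=OOAConfig)
    ae: AETrainConfig = field(default_factory=AETrainConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "data" in kwargs:
            kwargs["data"] = GeneratorConfig(**kwargs["data"])
        if "filter" in kwargs:
            kwargs["filter"] = FilterConfig(**kwargs["filter"])
        if "extractor" in kwargs:
            kwargs["extractor"] = ExtractorTrainConfig(**kwargs["extractor"])
        if "ooa" in kwargs:
            kwargs["ooa"] = OOAConfig(**kwargs["ooa"])
        if "ae" in kwargs:
            kwargs["ae"] = AETrainConfig(**kwargs["ae"])
        if "split_fractions" in kwargs:
            kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["ae"]["checkpoints"] = list(self.ae.checkpoints)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def ingest_external_dataset(
    root_dir: str | Path,
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    expected_per_class: int = 330,
) -> DatasetManifest:
    """Build a manifest from a directory tree with class-named subfolders.

    Folder names are matched case-insensitively onto the four tissue
    classes; an unknown folder is an error naming the accepted classes.
    Counts are logged against the reference composition (330 per class)
    with a warning on mismatch.  Splits are assigned stratified by class.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    subdirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not subdirs:
        raise ValueError(f"dataset root {root} contains no class subdirectories")
    rows = []
    for sub in subdirs:
        try:
            label = ClassLabel.from_name(sub.name)
        except ValueError as exc:
            raise ValueError(f"unrecognized class folder {sub.name!r}: {exc}") from exc
        files = sorted(p for p in sub.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if len(files) != expected_per_class:
            logger.warning("class %s has %d images (reference composition: %d)",
                           label.name, len(files), expected_per_class)
        rng = np.random.default_rng([seed, 2000 + int(label)])
        order = rng.permutation(len(files))
        n_train = int(np.floor(len(files) * split_fractions[0]))
        n_val = int(np.floor(len(files) * split_fractions[1]))
        split_of = np.empty(len(files), dtype=object)
        split_of[order[:n_train]] = "train"
        split_of[order[n_train : n_train + n_val]] = "val"
        split_of[order[n_train + n_val :]] = "test"
        for i, f in enumerate(files):
            rows.append((f"{label.name}_{f.stem}", str(f), label.name, split_of[i]))
    import pandas as pd

    return DatasetManifest(pd.DataFrame(rows, columns=list(DatasetManifest.COLUMNS)))


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out
        return wrapped
    return decorator


def build_extractors(cfg: RunConfig) -> list:
    side = cfg.extractor.input_side
    seeds = [int(s) for s in np.random.SeedSequence(cfg.seed).generate_state(3) % 2**31]
    return [
        build_alexnet_extractor(ExtractorSpec("alexnet_style", side), seed=seeds[0]),
        build_squeezenet_extractor(ExtractorSpec("squeezenet_style", side), seed=seeds[1]),
        build_capsnet_extractor(ExtractorSpec("capsnet", side), seed=seeds[2]),
    ]


def _load_split(manifest: DatasetManifest, split: str) -> tuple[list[np.ndarray], np.ndarray]:
    sub = manifest.subset(split)
    images = [load_patch(p) for p in sub.records["file_path"]]
    return images, sub.labels()


def run_pipeline(cfg: RunConfig) -> tuple[MetricsReport, dict[str, Path]]:
    """Execute the full pipeline and write artifacts under ``cfg.out_dir``.

    Stages: generate (or ingest) -> median filter -> extractor training and
    fused feature extraction -> osprey hyperparameter tuning -> final
    autoencoder-classifier training -> test-split evaluation.  Writes
    ``metrics.json``, ``confusion_matrix.csv``, ``ooa_history.csv``,
    ``manifest.csv``, the model bundle and a reproducibility record.
    Deterministic in ``cfg.seed``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("generate")
    def stage_generate() -> DatasetManifest:
        if cfg.data_dir is not None:
            return ingest_external_dataset(cfg.data_dir, cfg.split_fractions, seed=cfg.seed)
        return generate_dataset(cfg.data, out / "data", cfg.split_fractions)

    @_stage("preprocess")
    def stage_preprocess(manifest: DatasetManifest) -> DatasetManifest:
        return preprocess_dataset(manifest, cfg.filter, out / "filtered")

    @_stage("extract")
    def stage_extract(manifest: DatasetManifest):
        extractors = build_extractors(cfg)
        train_imgs, y_train = _load_split(manifest, "train")
        fit_seeds = [int(s) for s in np.random.SeedSequence([cfg.seed, 7]).generate_state(3) % 2**31]
        for ex, s in zip(extractors, fit_seeds):
            prepared = np.stack([ex.prepare(im) for im in train_imgs])
            ex.fit(prepared, y_train, epochs=cfg.extractor.epochs,
                   batch_size=cfg.extractor.batch_size, lr=cfg.extractor.learning_rate, seed=s)
        features, labels = {}, {}
        for split in ("train", "val", "test"):
            imgs, y = _load_split(manifest, split)
            features[split] = extract_features(imgs, extractors)
            labels[split] = y
        np.save(out / "features_train.npy", features["train"])
        manifest.save(out / "manifest.csv")
        return features, labels

    @_stage("tune")
    def stage_tune(features, labels):
        best_h, result = tune_ae_hyperparams(
            features["train"], labels["train"], features["val"], labels["val"],
            dims=cfg.ooa.dims, n=cfg.ooa.n, T=cfg.ooa.T, seed=cfg.seed,
            fitness_metric=cfg.ooa.fitness_metric, ae_epochs=cfg.ooa.ae_epochs,
            n_classes=N_CLASSES,
        )
        result.history.to_csv(out / "ooa_history.csv", index=False)
        return best_h, result

    @_stage("train")
    def stage_train(features, labels, best_h) -> AutoencoderClassifier:
        clf = AutoencoderClassifier(best_h, n_classes=N_CLASSES)

        def checkpoint(epoch: int, model: AutoencoderClassifier) -> None:
            post = model.predict_proba(features["test"])
            rep = compute_metrics(labels["test"], np.argmax(post, axis=1), post,
                                  class_names=CLASS_NAMES)
            rep.save_json(out / f"metrics_epoch_{epoch}.json")

        clf.fit(features["train"], labels["train"], seed=cfg.seed,
                recon_epochs=cfg.ae.recon_epochs, finetune_epochs=cfg.ae.finetune_epochs,
                checkpoint_callback=checkpoint if cfg.ae.checkpoints else None,
                checkpoints=tuple(cfg.ae.checkpoints))
        clf.save(out / "model")
        return clf

    @_stage("evaluate")
    def stage_evaluate(clf, features, labels) -> MetricsReport:
        post = clf.predict_proba(features["test"])
        y_pred = np.argmax(post, axis=1)
        report = compute_metrics(labels["test"], y_pred, post, class_names=CLASS_NAMES)
        report.save_json(out / "metrics.json")
        report.save_confusion_csv(out / "confusion_matrix.csv")
        return report

    manifest = stage_generate()
    filtered = stage_preprocess(manifest)
    features, labels = stage_extract(filtered)
    best_h, ooa_result = stage_tune(features, labels)
    clf = stage_train(features, labels, best_h)
    report = stage_evaluate(clf, features, labels)

    record = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "best_hyperparams": vars(best_h),
        "ooa_best_fitness": float(ooa_result.best_fitness),
    }
    (out / "reproducibility.json").write_text(json.dumps(record, indent=2))

    artifacts = {name: out / fname for name, fname in [
        ("metrics", "metrics.json"), ("confusion_matrix", "confusion_matrix.csv"),
        ("ooa_history", "ooa_history.csv"), ("manifest", "manifest.csv"),
        ("model", "model.npz"), ("reproducibility", "reproducibility.json"),
    ]}
    return report, artifacts
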