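"""Training loop, evaluation, and ablation driver.

Protocol defaults follow the full-scale recipe: Adam (β1 = 0.9, β2 = 0.999)
with initial learning rate 1e-4, exponential decay 0.96 per epoch, batch
size 32, up to 100 epochs, 256×256 random crops for training and the center
crop for evaluation.  The best-validation-accuracy state is checkpointed.
Tests and the synthetic smoke runs scale these down (tiny backbone, 64×64
crops, a handful of epochs) without changing the protocol's structure.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import (DatasetManifest, crop, images_to_batch, resize_short_side)
from .losses import balanced_focal_loss, cross_entropy, focal_loss
from .metrics import MetricsReport, compute_metrics, confusion
from .network import NetworkConfig, PestNet, build_model, save_checkpoint
from .nn import Adam, ExponentialLR, softmax

__all__ = ["TrainConfig", "RunLog", "train", "evaluate", "ablate",
           "predict_proba", "format_ablation_table"]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    lr_decay: float = 0.96
    batch_size: int = 32
    max_epochs: int = 100
    crop_size: int = 256
    seed: int = 0
    loss_name: str = "bfl"            # {cel, fl, bfl}
    gamma: float = 2.0
    alpha_scope: str = "dataset"      # {dataset, batch}
    normalize_imagenet: bool = False
    model: NetworkConfig = field(default_factory=NetworkConfig)
    checkpoint_path: str | None = None
    log_path: str | None = None
    verbose: bool = False

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_name not in ("cel", "fl", "bfl"):
            raise ValueError(f"unknown loss {self.loss_name!r}")
        if self.alpha_scope not in ("dataset", "batch"):
            raise ValueError(f"unknown alpha scope {self.alpha_scope!r}")
        if isinstance(self.model, dict):
            self.model = NetworkConfig.from_dict(self.model)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = NetworkConfig.from_dict(d["model"])
        if "betas" in d:
            d["betas"] = tuple(d["betas"])
        return cls(**d)


@dataclass
class RunLog:
    records: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0
    checkpoint_path: str | None = None


def _loss_fn(cfg: TrainConfig, dataset_counts: np.ndarray):
    if cfg.loss_name == "cel":
        return lambda logits, labels, counts: cross_entropy(logits, labels)
    if cfg.loss_name == "fl":
        return lambda logits, labels, counts: focal_loss(
            logits, labels, gamma=cfg.gamma)

    def bfl(logits, labels, counts):
        if cfg.alpha_scope == "batch":
            hist = np.bincount(labels, minlength=len(dataset_counts))
        else:
            hist = dataset_counts
        return balanced_focal_loss(logits, labels, hist, gamma=cfg.gamma)

    return bfl


def _prep_train_image(img: np.ndarray, size: int, rng) -> np.ndarray:
    if min(img.shape[:2]) != size:
        img = resize_short_side(img, size)
    return crop(img, "random", size=size, rng=rng)


def _prep_eval_image(img: np.ndarray, size: int) -> np.ndarray:
    if min(img.shape[:2]) != size:
        img = resize_short_side(img, size)
    return crop(img, "center", size=size)


def train(cfg: TrainConfig, train_manifest: DatasetManifest,
          val_manifest: DatasetManifest | None = None,
          model: PestNet | None = None) -> tuple:
    """Train a model under ``cfg``; returns (model, RunLog).

    Fully reproducible from ``cfg.seed``: model initialisation, shuffling
    and crop offsets all derive from it.  A non-finite loss aborts with a
    diagnostic dump of the offending step.
    """
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = build_model(cfg.model, seed=cfg.seed)
    counts = np.bincount(train_manifest.labels,
                         minlength=cfg.model.num_classes)
    loss_fn = _loss_fn(cfg, counts)
    opt = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas)
    sched = ExponentialLR(opt, cfg.lr_decay)
    log = RunLog()
    n = len(train_manifest)
    best_state = None
    log_fh = open(cfg.log_path, "w") if cfg.log_path else None

    try:
        for epoch in range(cfg.max_epochs):
            model.train()
            order = rng.permutation(n)
            epoch_loss, t0 = 0.0, time.time()
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                imgs = [_prep_train_image(train_manifest.image(i),
                                          cfg.crop_size, rng) for i in idx]
                batch = images_to_batch(imgs, cfg.normalize_imagenet)
                labels = train_manifest.labels[idx]
                logits = model(batch)
                loss = loss_fn(logits, labels, counts)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}, step "
                        f"{start // cfg.batch_size}: loss={loss.item()!r}, "
                        f"lr={opt.lr:.3e}, batch labels={labels.tolist()}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(idx)
            epoch_loss /= n

            record = {"epoch": epoch, "train_loss": epoch_loss,
                      "lr": opt.lr, "wall_time": time.time() - t0}
            if val_manifest is not None and len(val_manifest):
                report = evaluate(model, val_manifest,
                                  batch_size=cfg.batch_size,
                                  crop_size=cfg.crop_size,
                                  normalize_imagenet=cfg.normalize_imagenet)
                record["val"] = report.as_dict()
                if report.acc > log.best_val_acc:
                    log.best_val_acc = report.acc
                    log.best_epoch = epoch
                    best_state = model.state_dict()
            log.records.append(record)
            if log_fh:
                slim = {k: v for k, v in record.items()}
                log_fh.write(json.dumps(slim, default=float) + "\n")
                log_fh.flush()
            if cfg.verbose:
                msg = f"epoch {epoch}: loss {epoch_loss:.4f} lr {opt.lr:.2e}"
                if "val" in record:
                    msg += f" val_acc {record['val']['acc']:.3f}"
                print(msg)
            sched.step()
    finally:
        if log_fh:
            log_fh.close()

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    if cfg.checkpoint_path:
        save_checkpoint(model, cfg.checkpoint_path,
                        extra={"best_epoch": log.best_epoch,
                               "best_val_acc": log.best_val_acc})
        log.checkpoint_path = cfg.checkpoint_path
    return model, log


def predict_proba(model: PestNet, manifest: DatasetManifest,
                  batch_size: int = 32, crop_size: int | None = None,
                  normalize_imagenet: bool = False) -> np.ndarray:
    """Class probabilities for every manifest record (center-crop, eval mode)."""
    model.eval()
    crop_size = crop_size or model.cfg.input_size
    probs = []
    for start in range(0, len(manifest), batch_size):
        idx = range(start, min(start + batch_size, len(manifest)))
        imgs = [_prep_eval_image(manifest.image(i), crop_size) for i in idx]
        logits = model(images_to_batch(imgs, normalize_imagenet))
        probs.append(softmax(logits, axis=1).data)
    return np.concatenate(probs, axis=0)


def evaluate(model: PestNet, manifest: DatasetManifest, batch_size: int = 32,
             crop_size: int | None = None,
             normalize_imagenet: bool = False) -> MetricsReport:
    """Center-crop evaluation: one accumulated confusion matrix, full report."""
    if manifest.num_classes > model.cfg.num_classes:
        raise ValueError(
            f"manifest has {manifest.num_classes} classes, model expects "
            f"{model.cfg.num_classes}")
    probs = predict_proba(model, manifest, batch_size, crop_size,
                          normalize_imagenet)
    pred = probs.argmax(axis=1)
    cm = confusion(pred, manifest.labels, model.cfg.num_classes)
    return compute_metrics(cm)


def ablate(base_cfg: TrainConfig, arms: dict,
           train_manifest: DatasetManifest, val_manifest: DatasetManifest,
           test_manifest: DatasetManifest) -> dict:
    """Train/evaluate one model per arm under identical seed and data.

    ``arms`` maps arm name -> dict of overrides; keys prefixed ``model.``
    override the network config, the rest override the train config.
    """
    results = {}
    for name, overrides in arms.items():
        cfg_d = base_cfg.to_dict()
        for key, value in overrides.items():
            if key.startswith("model."):
                cfg_d["model"][key[len("model."):]] = value
            else:
                cfg_d[key] = value
        cfg = TrainConfig.from_dict(cfg_d)
        model, _ = train(cfg, train_manifest, val_manifest)
        results[name] = evaluate(model, test_manifest,
                                 batch_size=cfg.batch_size,
                                 crop_size=cfg.crop_size,
                                 normalize_imagenet=cfg.normalize_imagenet)
    return results


def format_ablation_table(results: dict) -> str:
    header = f"{'arm':<24}{'Acc':>8}{'MPre':>8}{'MRec':>8}{'MF1':>8}{'GM':>8}"
    lines = [header, "-" * len(header)]
    for name, rep in results.items():
        lines.append(f"{name:<24}{rep.acc:>8.4f}{rep.mpre:>8.4f}"
                     f"{rep.mrec:>8.4f}{rep.mf1:>8.4f}{rep.gm:>8.4f}")
    return "\n".join(lines)
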