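"""Training loop: SGD with the step-decay schedule, focal (or plain
cross-entropy) loss, and best-validation-AUC checkpoint selection.

The schedule is lr = lr0 * decay_factor ** floor(epoch / decay_every) with
lr0 = 0.01, decay 0.1 every 20 epochs over 60 epochs by default. After each
epoch the model is scored on the validation split by ROC-AUC; the weights
of the best epoch (earliest on ties) are kept and restored at the end, and
the test split is meant to be evaluated once, on that checkpoint only. The
optimizer constants (Nesterov momentum 0.9, weight decay 5e-4, batch 32,
global gradient-norm clip 1.0) are package choices, all config-exposed. Before
each validation pass the head's feature-standardization statistics are
recalibrated on a fixed subsample of the training images, since statistics
tracked mid-epoch describe weights that have since moved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .attention import MNAttentionNet
from .losses import cross_entropy, focal_dlogits, focal_loss
from .metrics import roc_auc
from .nn import SGD
from .pipeline import DatasetManifest, materialize
from .synthetic import LabeledImage

__all__ = ["TrainConfig", "TrainResult", "lr_at_epoch", "select_best_epoch",
           "train"]

# ImageNet channel statistics, used when fine-tuning from pretrained weights
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class TrainConfig:
    epochs: int = 60
    lr0: float = 0.01
    decay_factor: float = 0.1
    decay_every: int = 20
    loss: str = "focal"  # focal | cross_entropy
    gamma: float = 2.0
    batch_size: int = 32
    seed: int = 0
    momentum: float = 0.9
    weight_decay: float = 5e-4
    clip_norm: float = 1.0
    pretrained: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.lr0 <= 0 or self.decay_every < 1 \
                or self.batch_size < 1:
            raise ValueError("epochs, lr0, decay_every and batch_size must be positive")
        if self.loss not in ("focal", "cross_entropy"):
            raise ValueError(f"loss must be focal or cross_entropy, got {self.loss!r}")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decayed learning rate at a 0-based epoch index."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


def select_best_epoch(val_aucs) -> int:
    """0-based index of the maximal validation AUC; earliest epoch on ties."""
    val_aucs = np.asarray(val_aucs, dtype=float)
    if val_aucs.size == 0:
        raise ValueError("empty validation history")
    return int(np.argmax(val_aucs))


@dataclass
class TrainResult:
    best_epoch: int  # 1-based, as logged
    best_val_auc: float
    best_weights: dict
    history: pd.DataFrame = field(repr=False)


def _stack(images: list[LabeledImage]):
    x = np.stack([img.pixels for img in images])
    y = np.array([img.label for img in images], dtype=np.int64)
    return x, y


def train(model: MNAttentionNet, manifest: DatasetManifest,
          images: dict[str, LabeledImage], cfg: TrainConfig,
          log=None) -> TrainResult:
    """Train on the manifest's train split, select by validation ROC-AUC.

    All randomness (batch shuffling; augmentation parameters live in the
    manifest) derives from ``cfg.seed``. The model is left holding the
    best-epoch weights.
    """
    train_imgs = materialize(manifest, images, "train")
    val_imgs = materialize(manifest, images, "val")
    for name, imgs in [("train", train_imgs), ("val", val_imgs)]:
        labels = {img.label for img in imgs}
        if labels != {0, 1}:
            raise ValueError(f"{name} split must contain both classes, "
                             f"found labels {sorted(labels)}")
    x_train, y_train = _stack(train_imgs)
    x_val, y_val = _stack(val_imgs)

    if cfg.pretrained:
        model.mean, model.std = IMAGENET_MEAN.copy(), IMAGENET_STD.copy()
    else:
        model.fit_normalization(x_train)

    opt = SGD(model.parameters(), momentum=cfg.momentum,
              weight_decay=cfg.weight_decay, clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed)
    gamma = cfg.gamma if cfg.loss == "focal" else 0.0

    # fixed subsample for per-epoch feature-statistics recalibration
    recal_idx = np.arange(len(x_train))

    history = []
    best_auc, best_epoch, best_weights = -np.inf, -1, None
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        perm = rng.permutation(len(x_train))
        losses, counts = [], []
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            xb = model.preprocess(x_train[idx])
            yb = y_train[idx]
            out = model.forward(xb, train=True)
            p = out["probs"][:, 1]
            loss = focal_loss(p, yb, gamma) if cfg.loss == "focal" \
                else cross_entropy(p, yb)
            opt.zero_grad()
            model.backward(focal_dlogits(out["probs"], yb, gamma), out)
            opt.step(lr)
            losses.append(loss * len(idx))
            counts.append(len(idx))
        train_loss = float(np.sum(losses) / np.sum(counts))
        # refresh head feature statistics on the epoch-final weights before
        # scoring validation (stats tracked mid-epoch describe stale weights)
        model.recalibrate_feature_norm(x_train[recal_idx])
        val_auc = float(roc_auc(model.predict_proba(x_val), y_val))
        history.append({"epoch": epoch + 1, "lr": lr,
                        "train_loss": train_loss, "val_auc": val_auc})
        if log is not None:
            log(f"epoch {epoch + 1}/{cfg.epochs} lr={lr:g} "
                f"train_loss={train_loss:.4f} val_auc={val_auc:.4f}")
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch + 1
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return TrainResult(best_epoch=best_epoch, best_val_auc=best_auc,
                       best_weights=best_weights,
                       history=pd.DataFrame(history))
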