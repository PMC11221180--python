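"""Profusion classification nets, losses, k-fold training, and the cascade.

Two classification routes are provided:

* **Single-model route** — one staged convolutional network grades a
  subregion crop's profusion (4 softmax classes).  The architecture is
  generated from a small baseline by *compound scaling*: per-stage block
  counts are multiplied by a depth factor ``d`` (rounded up) and channel
  counts by a width factor ``ω`` (rounded, minimum 1), and the input
  resolution ``r`` is a free parameter.  The engine's blocks are plain
  conv–ReLU stacks; what is modelled is the scaling law, not any
  particular pretrained backbone.

* **Cascade (multi-stage joint) route** — three residual-style binary
  networks applied sequentially to the whole preprocessed image:
  stage 1 separates Normal from diseased, stage 2 separates stage III
  from I/II, stage 3 separates I from II.  Stage 2 is trained only on
  diseased examples and stage 3 only on stage-I/II examples, so each
  net specializes on the distinction it owns.

Training uses Adam with a stepped learning-rate schedule (×0.1 every 15
epochs by default), cross-entropy losses, and k-fold cross-validation
that retains the model from the best-validation-accuracy fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import nn
from .staging import StageLabel

__all__ = [
    "CompoundScalingConfig", "TrainConfig", "ProfusionLabel",
    "scale_depths", "scale_channels", "build_profusion_net", "build_binary_net",
    "relu", "cross_entropy", "binary_cross_entropy",
    "kfold_indices", "train_classifier", "train_binary",
    "predict_proba", "predict",
    "BinaryNet", "CascadeModel", "cascade_predict",
]

EPS = 1e-12

#: baseline staged architecture the scaling factors act on
BASELINE_STAGE_DEPTHS: tuple[int, ...] = (1, 2, 2, 3)
BASELINE_STAGE_CHANNELS: tuple[int, ...] = (16, 24, 40, 80)
BASELINE_STEM_CHANNELS: int = 32


@dataclass(frozen=True)
class CompoundScalingConfig:
    """Compound-scaling factors: depth d, width ω, input resolution r."""

    depth_factor: float = 1.0
    width_factor: float = 1.0
    resolution: int = 64

    def validate(self) -> None:
        if self.depth_factor <= 0 or self.width_factor <= 0:
            raise ValueError("depth_factor and width_factor must be > 0")
        if self.resolution < 32:
            raise ValueError(f"resolution must be >= 32, got {self.resolution}")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults follow the reference training recipe."""

    batch_size: int = 32
    init_lr: float = 1e-4
    lr_decay: float = 0.1
    decay_every_epochs: int = 15
    max_iterations: int = 1000
    epochs: int = 30
    folds: int = 5
    seed: int = 0
    class_weights: bool = False

    def validate(self) -> None:
        if min(self.batch_size, self.max_iterations, self.epochs) < 1 or self.init_lr <= 0:
            raise ValueError("batch_size, max_iterations, epochs and init_lr must be positive")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")

    def lr_at_epoch(self, epoch: int) -> float:
        return self.init_lr * self.lr_decay ** (epoch // self.decay_every_epochs)


@dataclass(frozen=True)
class ProfusionLabel:
    level: int
    large_opacity: bool = False

    def __post_init__(self):
        if self.level not in (0, 1, 2, 3):
            raise ValueError(f"profusion level must be in {{0..3}}, got {self.level!r}")


def relu(x):
    """f(x) = max(0, x)."""
    return np.maximum(0, x)


def scale_depths(base_depths: Sequence[int], depth_factor: float) -> tuple[int, ...]:
    """Per-stage block counts × d, rounded up."""
    return tuple(int(math.ceil(n * depth_factor)) for n in base_depths)


def scale_channels(base_channels: Sequence[int], width_factor: float) -> tuple[int, ...]:
    """Per-stage channel counts × ω, rounded, floored at 1."""
    return tuple(max(1, int(round(c * width_factor))) for c in base_channels)


def build_profusion_net(cfg: CompoundScalingConfig, n_classes: int = 4,
                        base_depths: Sequence[int] = BASELINE_STAGE_DEPTHS,
                        base_channels: Sequence[int] = BASELINE_STAGE_CHANNELS,
                        stem_channels: int = BASELINE_STEM_CHANNELS,
                        seed: int = 0) -> nn.Sequential:
    """Compound-scaled staged CNN: stem → stages → GAP → softmax head.

    The stem and the first block of every stage downsample ×2, so the
    input resolution must survive ``1 + n_stages`` halvings.
    """
    cfg.validate()
    depths = scale_depths(base_depths, cfg.depth_factor)
    channels = scale_channels(base_channels, cfg.width_factor)
    stem = max(1, int(round(stem_channels * cfg.width_factor)))
    n_down = 1 + len(depths)
    if cfg.resolution < 2 ** n_down:
        raise ValueError(
            f"resolution {cfg.resolution} too small for {len(depths)} stages "
            f"(needs >= {2 ** n_down})")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Conv2D(1, stem, 3, stride=2, rng=rng), nn.ReLU()]
    prev = stem
    for n_blocks, c in zip(depths, channels):
        for b in range(n_blocks):
            stride = 2 if b == 0 else 1
            layers += [nn.Conv2D(prev, c, 3, stride=stride, rng=rng), nn.ReLU()]
            prev = c
    layers += [nn.GlobalAvgPool(), nn.Dense(prev, n_classes, rng=rng)]
    return nn.Sequential(layers)


def build_binary_net(resolution: int = 64, widths: Sequence[int] = (8, 16, 32),
                     seed: int = 0, pool: str = "concat") -> nn.Sequential:
    """Residual-style binary classifier: stem + residual blocks + 1-logit head.

    The head pools the final feature map globally: ``avg``, ``max``, or
    ``concat`` (both).  Max pooling matters when the discriminative
    feature is small and localized — e.g. a single large opacity — which
    average pooling would dilute.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Conv2D(1, widths[0], 3, stride=2, rng=rng), nn.ReLU()]
    prev = widths[0]
    for w in widths[1:]:
        layers.append(nn.ResidualBlock(prev, w, stride=2, rng=rng))
        prev = w
    if pool == "avg":
        layers += [nn.GlobalAvgPool()]
    elif pool == "max":
        layers += [nn.GlobalMaxPool()]
    elif pool == "concat":
        layers += [_AvgMaxPool()]
        prev = 2 * prev
    else:
        raise ValueError(f"pool must be avg/max/concat, got {pool!r}")
    layers += [nn.Dense(prev, 1, rng=rng)]
    return nn.Sequential(layers)


class _AvgMaxPool(nn.Layer):
    """Concatenated global average + global max pooling."""

    def __init__(self):
        super().__init__()
        self.avg = nn.GlobalAvgPool()
        self.mx = nn.GlobalMaxPool()

    def forward(self, x):
        return np.concatenate([self.avg.forward(x), self.mx.forward(x)], axis=1)

    def backward(self, dy):
        c = dy.shape[1] // 2
        return self.avg.backward(dy[:, :c]) + self.mx.backward(dy[:, c:])


def _clamp(p):
    return np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0)


def cross_entropy(pred: Sequence[float], y) -> float:
    """Multiclass cross-entropy −Σ y_i log p_i (ε-clamped inside the log).

    ``y`` may be a one-hot vector or a class index.
    """
    p = _clamp(pred)
    y = np.asarray(y)
    if y.ndim == 0:
        onehot = np.zeros_like(p)
        onehot[int(y)] = 1.0
        y = onehot
    return float(-(y * np.log(p)).sum())


def binary_cross_entropy(p: float, y: int) -> float:
    """−[y·log p + (1−y)·log(1−p)], ε-clamped."""
    p = float(np.clip(p, EPS, 1 - EPS))
    if y not in (0, 1):
        raise ValueError(f"binary label must be 0 or 1, got {y!r}")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)))


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Disjoint shuffled folds covering range(n); sizes differ by ≤ 1."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, rem = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        w = base + (1 if i < rem else 0)
        folds.append(np.sort(order[start:start + w]))
        start += w
    return folds


def _to_batch(images) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    if arr.ndim == 3:
        arr = arr[:, None]
    return arr


def predict_proba(model: nn.Sequential, images, batch: int = 32) -> np.ndarray:
    x = _to_batch(images)
    out = []
    for i in range(0, len(x), batch):
        out.append(nn.softmax(model.forward(x[i:i + batch]), axis=1))
    return np.concatenate(out)


def predict(model: nn.Sequential, images, batch: int = 32) -> np.ndarray:
    return predict_proba(model, images, batch).argmax(axis=1)


def _train_softmax(model: nn.Sequential, x, y, cfg: TrainConfig, n_classes: int,
                   xv=None, yv=None, weights=None):
    """SGD loop shared by folds; returns per-epoch (loss, val_acc) curves."""
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.param_layers(), lr=cfg.init_lr,
                  decay_factor=cfg.lr_decay, decay_every=cfg.decay_every_epochs)
    steps = 0
    curves = {"loss": [], "val_acc": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits = model.forward(x[idx])
            p = nn.softmax(logits, axis=1)
            onehot = np.eye(n_classes, dtype=np.float32)[y[idx]]
            w = weights[y[idx]][:, None] if weights is not None else 1.0
            losses.append(float(-(np.log(np.clip(p, EPS, 1)) * onehot * w).sum() / len(idx)))
            model.backward(((p - onehot) * w / len(idx)).astype(np.float32))
            opt.step(epoch)
            steps += 1
            if steps >= cfg.max_iterations:
                break
        curves["loss"].append(float(np.mean(losses)))
        if xv is not None:
            curves["val_acc"].append(float((predict(model, xv) == yv).mean()))
        if steps >= cfg.max_iterations:
            break
    return curves


def train_simple(model: nn.Sequential, images, labels, cfg: TrainConfig,
                 val_images=None, val_labels=None, n_classes: int = 4) -> dict:
    """Single-split softmax training (no CV); returns loss/val-acc curves.

    Used when train and validation sets are fixed externally, e.g. when
    the training set contains augmented copies that must not leak into
    validation.
    """
    cfg.validate()
    x = _to_batch(images)
    y = np.asarray(labels, dtype=np.int64)
    xv = _to_batch(val_images) if val_images is not None else None
    yv = np.asarray(val_labels, dtype=np.int64) if val_labels is not None else None
    return _train_softmax(model, x, y, cfg, n_classes, xv=xv, yv=yv)


def train_classifier(model_factory: Callable[[], nn.Sequential], images, labels,
                     cfg: TrainConfig, n_classes: int = 4):
    """k-fold cross-validated training; retains the best-fold model.

    ``model_factory`` builds a fresh (deterministically initialized)
    network per fold.  Returns ``(best_model, fold_reports)`` where each
    report carries the fold's loss curve and validation accuracy.
    """
    cfg.validate()
    x = _to_batch(images)
    y = np.asarray(labels, dtype=np.int64)
    present = np.bincount(y, minlength=n_classes)
    missing = [c for c in range(n_classes) if present[c] == 0]
    if missing:
        raise ValueError(f"class {missing[0]} absent from training data")
    weights = None
    if cfg.class_weights:
        weights = (len(y) / (n_classes * np.maximum(present, 1))).astype(np.float32)
    folds = kfold_indices(len(y), cfg.folds, cfg.seed)
    reports, best = [], (-1.0, None)
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        model = model_factory()
        curves = _train_softmax(model, x[train_idx], y[train_idx], cfg, n_classes,
                                xv=x[val_idx], yv=y[val_idx], weights=weights)
        acc = curves["val_acc"][-1] if curves["val_acc"] else 0.0
        reports.append({"fold": f, "val_indices": val_idx, "loss": curves["loss"],
                        "val_acc": curves["val_acc"], "final_val_acc": acc})
        if acc > best[0]:
            best = (acc, model)
    return best[1], reports


class BinaryNet:
    """A trained binary head: wraps a net producing one sigmoid logit."""

    def __init__(self, net: nn.Sequential | None = None, trained: bool = False):
        self.net = net
        self.trained = trained

    def predict_prob(self, img: np.ndarray) -> float:
        """P(positive class) for a single image."""
        if not self.trained or self.net is None:
            raise ValueError("binary net has not been trained")
        logit = self.net.forward(_to_batch([img]))
        return float(nn.sigmoid(logit)[0, 0])


def train_binary(net: nn.Sequential, images, labels, cfg: TrainConfig) -> BinaryNet:
    """Train a binary net with sigmoid BCE; returns a ready BinaryNet."""
    cfg.validate()
    x = _to_batch(images)
    y = np.asarray(labels, dtype=np.float32)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binary labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both binary classes must be present")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.param_layers(), lr=cfg.init_lr,
                  decay_factor=cfg.lr_decay, decay_every=cfg.decay_every_epochs)
    steps = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logit = net.forward(x[idx])
            p = nn.sigmoid(logit)[:, 0]
            grad = ((p - y[idx]) / len(idx)).astype(np.float32)[:, None]
            net.backward(grad)
            opt.step(epoch)
            steps += 1
            if steps >= cfg.max_iterations:
                break
        if steps >= cfg.max_iterations:
            break
    return BinaryNet(net, trained=True)


@dataclass
class CascadeModel:
    """Three binary deciders applied in sequence (see module docstring)."""

    stage1: BinaryNet  # positive = diseased (I/II/III)
    stage2: BinaryNet  # positive = stage III
    stage3: BinaryNet  # positive = stage II (vs I)


def cascade_predict(cascade: CascadeModel, img: np.ndarray,
                    threshold: float = 0.5) -> StageLabel:
    """Sequential staging: Normal short-circuits, then III, then II vs I.

    Every combination of the three binary outcomes maps to exactly one
    stage; downstream nets are not consulted once an earlier decision
    resolves the label.
    """
    for name in ("stage1", "stage2", "stage3"):
        bn = getattr(cascade, name)
        if not getattr(bn, "trained", True):
            raise ValueError(f"cascade component {name} has not been trained")
    if cascade.stage1.predict_prob(img) < threshold:
        return StageLabel.NORMAL
    if cascade.stage2.predict_prob(img) >= threshold:
        return StageLabel.III
    if cascade.stage3.predict_prob(img) >= threshold:
        return StageLabel.II
    return StageLabel.I
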