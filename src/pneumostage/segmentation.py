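"""U-Net lung-field segmentation: architecture, training loop, IoU.

The network is the classic encoder–decoder with skip connections: each
encoder level halves the spatial size (2×2 max pool) and doubles the
channel count; the decoder mirrors it with nearest-neighbour upsampling
and concatenates the matching encoder feature map before convolving.  A
final 1×1 convolution produces one sigmoid logit per pixel; masks are
binarized at 0.5.

Defaults are desk-scale (depth 3, 16 base channels, 128² inputs) so a
full training run on phantom data fits in minutes on one CPU; deeper /
wider configurations are reachable through :class:`UNetConfig`.
Training minimizes pixelwise binary cross-entropy with Adam and keeps
the weights of the best-validation-IoU epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = ["UNetConfig", "SegTrainReport", "UNet", "build_unet", "train_segmenter",
           "predict_mask", "iou"]


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 3
    base_channels: int = 16
    input_size: int = 128
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2 ** self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


@dataclass
class SegTrainReport:
    """Per-epoch curves; list lengths equal the number of completed epochs."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_iou: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_iou: float = 0.0


class UNet:
    """Encoder–decoder with skip concatenations; outputs per-pixel logits."""

    def __init__(self, cfg: UNetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, base = cfg.depth, cfg.base_channels
        ch = [base * 2 ** l for l in range(d)]
        bott = base * 2 ** d
        self.enc = []
        prev = 1
        for c in ch:
            self.enc.append((nn.Conv2D(prev, c, 3, rng=rng), nn.ReLU()))
            prev = c
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = (nn.Conv2D(prev, bott, 3, rng=rng), nn.ReLU())
        self.ups = [nn.Upsample2() for _ in range(d)]
        self.dec = []
        cur = bott
        for c in reversed(ch):
            reduce = nn.Conv2D(cur, c, 3, rng=rng)
            fuse = nn.Conv2D(2 * c, c, 3, rng=rng)
            self.dec.append((reduce, nn.ReLU(), fuse, nn.ReLU()))
            cur = c
        self.head = nn.Conv2D(cur, 1, 1, pad=0, rng=rng)

    def param_layers(self) -> list[nn.Layer]:
        out = [conv for conv, _ in self.enc]
        out.append(self.bottleneck[0])
        for reduce, _, fuse, _ in self.dec:
            out += [reduce, fuse]
        out.append(self.head)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        for (conv, relu), pool in zip(self.enc, self.pools):
            x = relu.forward(conv.forward(x))
            skips.append(x)
            x = pool.forward(x)
        conv, relu = self.bottleneck
        x = relu.forward(conv.forward(x))
        self._skip_channels = [s.shape[1] for s in skips]
        for up, (reduce, relu1, fuse, relu2), skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            x = relu1.forward(reduce.forward(x))
            x = np.concatenate([x, skip], axis=1)
            x = relu2.forward(fuse.forward(x))
        return self.head.forward(x)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        dskips = [None] * len(self.dec)
        for i in range(len(self.dec) - 1, -1, -1):
            reduce, relu1, fuse, relu2 = self.dec[i]
            d = fuse.backward(relu2.backward(dy))
            c = d.shape[1] // 2
            dskips[i] = d[:, c:].copy()
            dy = self.ups[i].backward(reduce.backward(relu1.backward(d[:, :c])))
        conv, relu = self.bottleneck
        dy = conv.backward(relu.backward(dy))
        for l in range(len(self.enc) - 1, -1, -1):
            dy = self.pools[l].backward(dy)
            dy = dy + dskips[len(self.enc) - 1 - l]
            econv, erelu = self.enc[l]
            dy = econv.backward(erelu.backward(dy))

    def state(self):
        return [{k: v.copy() for k, v in lay.params.items()} for lay in self.param_layers()]

    def load_state(self, state) -> None:
        for lay, st in zip(self.param_layers(), state):
            for k in lay.params:
                lay.params[k][...] = st[k]


def build_unet(cfg: UNetConfig) -> UNet:
    """Construct a U-Net; rejects input sizes not divisible by 2^depth."""
    return UNet(cfg)


def _to_batch(images) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return arr[:, None, :, :]


def predict_mask(model: UNet, img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Segment one image; probability map thresholded (default 0.5)."""
    logits = model.forward(_to_batch([img]))
    return nn.sigmoid(logits)[0, 0] > threshold


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 if both are empty."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    pred = pred.astype(bool)
    truth = truth.astype(bool)
    union = (pred | truth).sum()
    if union == 0:
        return 1.0
    return float((pred & truth).sum() / union)


def _mean_iou(model: UNet, x: np.ndarray, y: np.ndarray, batch: int = 8) -> float:
    vals = []
    for i in range(0, len(x), batch):
        p = nn.sigmoid(model.forward(x[i:i + batch])) > 0.5
        for j in range(p.shape[0]):
            vals.append(iou(p[j, 0], y[i + j, 0] > 0.5))
    return float(np.mean(vals))


def _mean_bce(model: UNet, x: np.ndarray, y: np.ndarray, batch: int = 8) -> float:
    tot, n = 0.0, 0
    for i in range(0, len(x), batch):
        p = np.clip(nn.sigmoid(model.forward(x[i:i + batch])), 1e-12, 1 - 1e-12)
        yy = y[i:i + batch]
        tot += float(-(yy * np.log(p) + (1 - yy) * np.log(1 - p)).sum())
        n += yy.size
    return tot / n


def train_segmenter(model: UNet, pairs, val_pairs, epochs: int = 20,
                    batch_size: int = 4, lr: float = 1e-3, seed: int = 0,
                    target_iou: float | None = None) -> SegTrainReport:
    """Train on (image, mask) pairs; keep best-validation-IoU weights.

    ``target_iou`` optionally stops training once validation IoU reaches
    it; the report then covers only the completed epochs.
    """
    if len(pairs) == 0:
        raise ValueError("training set is empty")
    shapes = {np.asarray(im).shape for im, _ in list(pairs) + list(val_pairs)}
    if len(shapes) > 1:
        raise ValueError(f"all images must share one shape, got {shapes}")
    x = _to_batch([im for im, _ in pairs])
    y = _to_batch([np.asarray(m, dtype=np.float32) for _, m in pairs])
    xv = _to_batch([im for im, _ in val_pairs]) if len(val_pairs) else x
    yv = _to_batch([np.asarray(m, dtype=np.float32) for _, m in val_pairs]) if len(val_pairs) else y

    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.param_layers(), lr=lr)
    report = SegTrainReport()
    best_state = model.state()
    for epoch in range(epochs):
        order = rng.permutation(len(x))
        losses = []
        for i in range(0, len(x), batch_size):
            idx = order[i:i + batch_size]
            logits = model.forward(x[idx])
            p = nn.sigmoid(logits)
            yy = y[idx]
            pc = np.clip(p, 1e-12, 1 - 1e-12)
            losses.append(float(-(yy * np.log(pc) + (1 - yy) * np.log(1 - pc)).mean()))
            model.backward(((p - yy) / yy.size).astype(np.float32))
            opt.step(epoch)
        report.train_loss.append(float(np.mean(losses)))
        report.val_loss.append(_mean_bce(model, xv, yv))
        report.train_iou.append(_mean_iou(model, x, y))
        vi = _mean_iou(model, xv, yv)
        report.val_iou.append(vi)
        if vi > report.best_val_iou:
            report.best_val_iou = vi
            report.best_epoch = epoch
            best_state = model.state()
        if target_iou is not None and vi >= target_iou:
            break
    model.load_state(best_state)
    return report
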