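"""Residual U-Net embryo segmentation: model, loss, IoU, training.

The segmenter maps a single-channel grayscale frame to per-pixel logits
for "embryo inside the eggshell" vs background.  It is a U-Net whose
encoder and decoder stages are built from residual blocks (two 3x3
convolutions with batch normalisation and ReLU plus an additive identity
shortcut, projected by a 1x1 convolution when channel counts change).
Downsampling uses 2x2 max pooling, upsampling 2x2 transposed
convolutions, and encoder features are concatenated into the matching
decoder stage; a final 1x1 convolution produces the one-channel logit
map.  Feature-map counts double at each downsampling and halve on the
way up.

Training minimises the sigmoid binary cross-entropy on logits and tracks
the intersection-over-union (IoU) of the 0.5-thresholded sigmoid output
(equivalently: logit >= 0) against the annotated masks; the checkpoint
with the highest validation IoU is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .imaging import validate_mask

__all__ = [
    "SegNetConfig",
    "SegTrainConfig",
    "ResidualBlock",
    "ResUNet",
    "build_segmenter",
    "bce_with_logits",
    "binarize_logits",
    "iou",
    "train_segmenter",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
    "SegTrainResult",
]


@dataclass
class SegNetConfig:
    """Architecture hyper-parameters of the residual U-Net.

    ``base_features`` is the width of the first encoder stage (the
    classical U-Net convention of 64 is the default); ``depth`` counts
    encoder stages, so inputs must be divisible by ``2**depth``.
    """

    in_channels: int = 1
    base_features: int = 64
    depth: int = 4
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.depth < 1 or self.base_features < 1:
            raise ValueError("depth and base_features must be positive")


@dataclass
class SegTrainConfig:
    """Training protocol: Adam, lr 0.002, batch 20, 80 epochs, 80:20 split."""

    epochs: int = 80
    batch_size: int = 20
    learning_rate: float = 0.002
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


class ResidualBlock(nn.Layer):
    """conv3x3-BN-ReLU-conv3x3-BN(-dropout) + shortcut, then ReLU.

    The shortcut is the identity when input and output channel counts
    agree and a 1x1 projection convolution otherwise.  Dropout sits after
    the block's second convolution.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.main = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31))),
        )
        self.shortcut = (
            None
            if in_ch == out_ch
            else nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, rng=rng), nn.BatchNorm2d(out_ch)
            )
        )
        self._relu_mask = None

    def params(self):
        ps = self.main.params()
        if self.shortcut is not None:
            ps += self.shortcut.params()
        return ps

    def state_arrays(self):
        arrays = self.main.state_arrays()
        if self.shortcut is not None:
            arrays += self.shortcut.state_arrays()
        return arrays

    def forward(self, x, train: bool = False):
        y = self.main.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        out = y + s
        if train:
            self._relu_mask = out > 0
        return np.maximum(out, 0.0)

    def backward(self, gy):
        g = gy * self._relu_mask
        self._relu_mask = None
        gx = self.main.backward(g)
        gx = gx + (g if self.shortcut is None else self.shortcut.backward(g))
        return gx


class ResUNet(nn.Layer):
    """Residual U-Net; see module docstring for the stage layout."""

    def __init__(self, cfg: SegNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        f, d, p = cfg.base_features, cfg.depth, cfg.dropout_rate

        def stage(in_ch, out_ch):
            return nn.Sequential(
                ResidualBlock(in_ch, out_ch, p, rng), ResidualBlock(out_ch, out_ch, p, rng)
            )

        self.enc = []
        ch = cfg.in_channels
        for i in range(d):
            self.enc.append(stage(ch, f * 2**i))
            ch = f * 2**i
        self.pools = [nn.MaxPool2d(2, 2) for _ in range(d)]
        self.bottleneck = stage(ch, f * 2**d)
        self.ups = []
        self.dec = []
        ch = f * 2**d
        for i in reversed(range(d)):
            skip_ch = f * 2**i
            self.ups.append(nn.ConvTranspose2d(ch, skip_ch, 2, 2, rng=rng))
            self.dec.append(stage(2 * skip_ch, skip_ch))
            ch = skip_ch
        self.head = nn.Conv2d(f, 1, 1, rng=rng)

    def _children(self):
        return (
            self.enc + self.pools + [self.bottleneck] + self.ups + self.dec + [self.head]
        )

    def params(self):
        return [p for c in self._children() for p in c.params()]

    def state_arrays(self):
        return [a for c in self._children() for a in c.state_arrays()]

    def forward(self, x, train: bool = False):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2], x.shape[3]
        div = 2**self.cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2**depth = {div}"
            )
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_ch = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, gy):
        g = self.head.backward(gy)
        skip_grads = []
        # walk decoder stages in reverse construction order
        for i in reversed(range(len(self.dec))):
            g = self.dec[i].backward(g)
            sc = self._skip_ch[i]
            skip_grads.append(g[:, :sc])
            g = self.ups[i].backward(g[:, sc:])
        g = self.bottleneck.backward(g)
        skip_grads.reverse()  # now ordered bottom-of-U first
        for i in reversed(range(len(self.enc))):
            g = self.pools[i].backward(g)
            g = g + skip_grads[len(self.enc) - 1 - i]
            g = self.enc[i].backward(g)
        return g


def build_segmenter(cfg: SegNetConfig | None = None, seed: int = 0) -> ResUNet:
    """Construct a residual U-Net from its configuration."""
    return ResUNet(cfg or SegNetConfig(), seed=seed)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> float:
    """Mean sigmoid binary cross-entropy; stable for any finite logits."""
    return nn.bce_with_logits(logits, targets)


def binarize_logits(logits: np.ndarray) -> np.ndarray:
    """Threshold logits at 0 (sigmoid at 0.5); the boundary maps to 1."""
    logits = np.asarray(logits)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    return (logits >= 0.0).astype(np.uint8)


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Two empty masks agree perfectly that there is no embryo, so the
    empty/empty case is defined as 1.0.
    """
    pred = np.asarray(validate_mask(pred), dtype=np.int64)
    truth = np.asarray(validate_mask(truth), dtype=np.int64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = int((pred * truth).sum())
    union = int(pred.sum() + truth.sum() - inter)
    if union == 0:
        return 1.0
    return inter / union


@dataclass
class SegTrainResult:
    """Trained segmenter plus its per-epoch curves and best-epoch metadata."""

    model: ResUNet
    history: pd.DataFrame
    best_epoch: int
    best_val_iou: float
    net_config: SegNetConfig
    train_config: SegTrainConfig
    seed: int
    train_indices: np.ndarray = field(repr=False, default=None)
    val_indices: np.ndarray = field(repr=False, default=None)


def _micro_iou(inter: int, pred_sum: int, truth_sum: int) -> float:
    union = pred_sum + truth_sum - inter
    return 1.0 if union == 0 else inter / union


def train_segmenter(
    images: np.ndarray,
    masks: np.ndarray,
    train_cfg: SegTrainConfig | None = None,
    net_cfg: SegNetConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> SegTrainResult:
    """Train the residual U-Net and return the best-validation-IoU model.

    ``images`` is (N, H, W) in [0,1], ``masks`` (N, H, W) binary.  The
    dataset is split into train/validation by a seeded shuffle, Adam
    minimises the BCE-with-logits loss, per-epoch train/validation loss
    and micro-averaged IoU are recorded, and the parameters from the
    epoch with the highest validation IoU are restored before returning.
    """
    train_cfg = train_cfg or SegTrainConfig()
    net_cfg = net_cfg or SegNetConfig()
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if images.ndim != 3 or masks.shape != images.shape:
        raise ValueError("expected matching (N, H, W) image and mask stacks")
    n = images.shape[0]
    if not np.isin(np.unique(masks), (0.0, 1.0)).all():
        raise ValueError("masks must be binary")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(train_cfg.val_fraction * n)))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if len(tr_idx) < train_cfg.batch_size:
        raise ValueError(
            f"training split ({len(tr_idx)}) smaller than one batch "
            f"({train_cfg.batch_size})"
        )

    model = ResUNet(net_cfg, seed=int(rng.integers(2**31)))
    opt = nn.Adam(model.params(), lr=train_cfg.learning_rate)

    rows = []
    best = (-1.0, -1, None)  # (val_iou, epoch, state)
    for epoch in range(train_cfg.epochs):
        perm = rng.permutation(len(tr_idx))
        ep_losses = []
        inter = psum = tsum = 0
        for start in range(0, len(tr_idx), train_cfg.batch_size):
            idx = tr_idx[perm[start : start + train_cfg.batch_size]]
            xb = images[idx][:, None]
            yb = masks[idx][:, None]
            logits = model.forward(xb, train=True)
            loss, grad = nn.bce_with_logits(logits, yb, return_grad=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss}"
                )
            ep_losses.append(loss)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            pred = binarize_logits(logits)
            inter += int((pred * (yb > 0.5)).sum())
            psum += int(pred.sum())
            tsum += int((yb > 0.5).sum())
        train_iou = _micro_iou(inter, psum, tsum)
        val_loss, val_iou = _evaluate(model, images[val_idx], masks[val_idx],
                                      train_cfg.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(ep_losses)),
                "val_loss": val_loss,
                "train_iou": train_iou,
                "val_iou": val_iou,
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {rows[-1]['train_loss']:.4f}  "
                f"val_loss {val_loss:.4f}  val_iou {val_iou:.4f}"
            )
        if val_iou > best[0]:
            best = (val_iou, epoch, model.get_state())

    model.set_state(best[2])
    return SegTrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best[1],
        best_val_iou=best[0],
        net_config=net_cfg,
        train_config=train_cfg,
        seed=seed,
        train_indices=tr_idx,
        val_indices=val_idx,
    )


def _evaluate(
    model: ResUNet, images: np.ndarray, masks: np.ndarray, batch_size: int
) -> tuple[float, float]:
    losses = []
    inter = psum = tsum = 0
    for start in range(0, len(images), batch_size):
        xb = images[start : start + batch_size][:, None]
        yb = masks[start : start + batch_size][:, None]
        logits = model.forward(xb, train=False)
        losses.append(nn.bce_with_logits(logits, yb) * xb.shape[0])
        pred = binarize_logits(logits)
        inter += int((pred * (yb > 0.5)).sum())
        psum += int(pred.sum())
        tsum += int((yb > 0.5).sum())
    return float(np.sum(losses) / len(images)), _micro_iou(inter, psum, tsum)


def predict_mask(model: ResUNet, img: np.ndarray) -> np.ndarray:
    """Segment one frame: forward pass in evaluation mode, threshold at 0."""
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D gray image")
    logits = model.forward(img[None, None], train=False)
    return binarize_logits(logits[0, 0])


def save_checkpoint(result: SegTrainResult, path: str | Path) -> Path:
    """Save weights (.npz) with a JSON sidecar of config, seed and metrics."""
    path = Path(path)
    np.savez(path, *result.model.get_state())
    sidecar = {
        "kind": "segmenter",
        "net_config": asdict(result.net_config),
        "train_config": asdict(result.train_config),
        "seed": result.seed,
        "best_epoch": result.best_epoch,
        "best_val_iou": result.best_val_iou,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def load_checkpoint(path: str | Path) -> tuple[ResUNet, dict]:
    """Rebuild a segmenter from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    model = ResUNet(SegNetConfig(**sidecar["net_config"]))
    with np.load(path) as npz:
        model.set_state([npz[k] for k in npz.files])
    return model, sidecar
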