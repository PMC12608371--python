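"""Six-class residual stage classifier, Grad-CAM, and feature embedding.

The classifier follows the standard 18-layer residual plan: a 7x7/2 stem
convolution, 3x3/2 max pooling, four groups of two basic residual blocks
with channel widths (w, 2w, 4w, 8w) and stride-2 entries, global average
pooling, and a linear head to six stage logits.  The first convolution
takes a single channel, because the frames are grayscale, and the model
is always trained from scratch.  Stage probabilities are the softmax of
the logits; the width ``w`` defaults to 64 (average-pool feature length
512) and is configurable so that desk-scale synthetic experiments can
run a reduced network.

Grad-CAM: because the network ends in global average pooling followed by
a single linear layer, the gradient of a class score with respect to the
last convolutional feature maps is spatially constant and equal to the
corresponding row of the head weights divided by the map area.  The
gradient-weighted sum of feature maps therefore has the closed form
``ReLU(sum_k W[c, k] * A_k)``, which is what this module computes before
min-max normalisation and upsampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import nn
from .stages import N_STAGES
from .stats_eval import multiclass_macro_metrics

__all__ = [
    "ClsNetConfig",
    "ClsTrainConfig",
    "BasicBlock",
    "ResNetClassifier",
    "build_classifier",
    "softmax_probs",
    "train_classifier",
    "kfold_cv",
    "predict_probs",
    "gradcam",
    "extract_features",
    "ClsTrainResult",
    "CVResult",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ClsNetConfig:
    """Architecture hyper-parameters of the residual classifier."""

    in_channels: int = 1
    num_classes: int = N_STAGES
    base_width: int = 64
    input_size: int = 256

    @property
    def feature_length(self) -> int:
        return self.base_width * 8


@dataclass
class ClsTrainConfig:
    """Training protocol: Adam from scratch, lr halved every 10 epochs.

    The holdout protocol uses a 70:30 stratified train/validation split;
    cross-validation uses 80:20 per fold.  The Adam learning rate is not
    part of the published protocol and defaults to the Adam convention of
    0.001.  ``images_per_class`` documents the design point of the study
    dataset (400 per stage) and is consumed by the synthetic generator.
    """

    epochs: int = 80
    batch_size: int = 32
    learning_rate: float = 0.001
    lr_step_epochs: int = 10
    lr_gamma: float = 0.5
    val_fraction: float = 0.30
    weight_decay: float = 1e-4
    augment_flips: bool = True
    pretrained: bool = False
    images_per_class: int = 400

    def __post_init__(self) -> None:
        if self.pretrained:
            raise ValueError("the classifier is always trained from scratch")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")


class BasicBlock(nn.Layer):
    """Two 3x3 convolutions with BN/ReLU and an additive shortcut.

    The shortcut is a strided 1x1 projection when the block changes
    resolution or width, otherwise the identity.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.main = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
            nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng),
            nn.BatchNorm2d(out_ch),
        )
        self.shortcut = (
            None
            if (in_ch == out_ch and stride == 1)
            else nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng),
                nn.BatchNorm2d(out_ch),
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
        return gx + (g if self.shortcut is None else self.shortcut.backward(g))


class ResNetClassifier(nn.Layer):
    """18-layer residual classifier adapted to 1-channel input, 6 classes."""

    def __init__(self, cfg: ClsNetConfig | None = None, seed: int = 0):
        self.cfg = cfg = cfg or ClsNetConfig()
        rng = np.random.default_rng(seed)
        w = cfg.base_width
        self.stem = nn.Sequential(
            nn.Conv2d(cfg.in_channels, w, 7, stride=2, padding=3, rng=rng),
            nn.BatchNorm2d(w),
            nn.ReLU(),
            nn.MaxPool2d(3, 2, padding=1),
        )
        self.blocks = nn.Sequential(
            BasicBlock(w, w, 1, rng),
            BasicBlock(w, w, 1, rng),
            BasicBlock(w, 2 * w, 2, rng),
            BasicBlock(2 * w, 2 * w, 1, rng),
            BasicBlock(2 * w, 4 * w, 2, rng),
            BasicBlock(4 * w, 4 * w, 1, rng),
            BasicBlock(4 * w, 8 * w, 2, rng),
            BasicBlock(8 * w, 8 * w, 1, rng),
        )
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(8 * w, cfg.num_classes, rng=rng)
        self._last_maps = None

    def _children(self):
        return [self.stem, self.blocks, self.pool, self.fc]

    def params(self):
        return [p for c in self._children() for p in c.params()]

    def state_arrays(self):
        return [a for c in self._children() for a in c.state_arrays()]

    def _check_input(self, x):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        return x

    def forward_maps(self, x, train: bool = False) -> np.ndarray:
        """Feature maps of the last convolutional block (pre-pooling)."""
        x = self._check_input(x)
        x = self.stem.forward(x, train)
        return self.blocks.forward(x, train)

    def forward_features(self, x, train: bool = False) -> np.ndarray:
        """Global-average-pool feature vectors, length ``8 * base_width``."""
        return self.pool.forward(self.forward_maps(x, train), train)

    def forward(self, x, train: bool = False) -> np.ndarray:
        return self.fc.forward(self.forward_features(x, train), train)

    def backward(self, gy):
        g = self.fc.backward(gy)
        g = self.pool.backward(g)
        g = self.blocks.backward(g)
        return self.stem.backward(g)


def build_classifier(cfg: ClsNetConfig | None = None, seed: int = 0) -> ResNetClassifier:
    """Construct the residual stage classifier."""
    return ResNetClassifier(cfg, seed=seed)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Stage probabilities: stable softmax over the last axis."""
    return nn.softmax(logits, axis=-1)


@dataclass
class ClsTrainResult:
    model: ResNetClassifier
    history: pd.DataFrame
    best_epoch: int
    best_val_accuracy: float
    confusion: np.ndarray = field(repr=False, default=None)
    net_config: ClsNetConfig = None
    train_config: ClsTrainConfig = None
    seed: int = 0
    train_indices: np.ndarray = field(repr=False, default=None)
    val_indices: np.ndarray = field(repr=False, default=None)


def _stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    tr, va = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(max(n_val, 1), len(idx) - 1)
        va.extend(idx[:n_val])
        tr.extend(idx[n_val:])
    return np.array(sorted(tr)), np.array(sorted(va))


def _eval_classifier(model, images, labels, batch_size):
    """Validation loss, accuracy and confusion matrix in eval mode."""
    k = model.cfg.num_classes
    cm = np.zeros((k, k), dtype=np.int64)
    losses = []
    for s in range(0, len(images), batch_size):
        xb, yb = images[s : s + batch_size], labels[s : s + batch_size]
        logits = model.forward(xb, train=False)
        losses.append(nn.cross_entropy(logits, yb) * len(yb))
        pred = logits.argmax(axis=1)
        np.add.at(cm, (yb, pred), 1)
    acc = float(np.trace(cm) / cm.sum())
    return float(np.sum(losses) / len(images)), acc, cm


def train_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    train_cfg: ClsTrainConfig | None = None,
    net_cfg: ClsNetConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> ClsTrainResult:
    """Train the stage classifier with cross-entropy and a step LR schedule.

    Uses a seeded stratified train/validation split (70:30 by default),
    records per-epoch validation accuracy and macro-averaged
    precision/recall/F1, and restores the epoch with the highest
    validation accuracy before returning.
    """
    train_cfg = train_cfg or ClsTrainConfig()
    net_cfg = net_cfg or ClsNetConfig()
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels, dtype=np.int64)
    if images.ndim != 3 or len(labels) != len(images):
        raise ValueError("expected (N, H, W) images with matching labels")
    rng = np.random.default_rng(seed)
    tr_idx, va_idx = _stratified_split(labels, train_cfg.val_fraction, rng)
    present = np.unique(labels[tr_idx])
    if len(present) < net_cfg.num_classes:
        missing = sorted(set(range(net_cfg.num_classes)) - set(present.tolist()))
        raise ValueError(f"classes missing from training split: {missing}")

    model = ResNetClassifier(net_cfg, seed=int(rng.integers(2**31)))
    opt = nn.Adam(
        model.params(),
        lr=train_cfg.learning_rate,
        weight_decay=train_cfg.weight_decay,
    )
    sched = nn.StepLR(opt, train_cfg.lr_step_epochs, train_cfg.lr_gamma)

    rows = []
    best = (-1.0, -1, None, None)
    for epoch in range(train_cfg.epochs):
        sched.at_epoch(epoch)
        perm = rng.permutation(len(tr_idx))
        ep_losses = []
        for s in range(0, len(tr_idx), train_cfg.batch_size):
            idx = tr_idx[perm[s : s + train_cfg.batch_size]]
            xb = images[idx]
            if train_cfg.augment_flips:
                # embryo orientation is unconstrained at acquisition, so
                # mirrored views are equally valid members of each stage
                xb = xb.copy()
                flip_lr = rng.random(len(xb)) < 0.5
                flip_ud = rng.random(len(xb)) < 0.5
                xb[flip_lr] = xb[flip_lr, :, ::-1]
                xb[flip_ud] = xb[flip_ud, ::-1, :]
            logits = model.forward(xb, train=True)
            loss, grad = nn.cross_entropy(logits, labels[idx], return_grad=True)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            ep_losses.append(loss)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
        val_loss, val_acc, cm = _eval_classifier(
            model, images[va_idx], labels[va_idx], train_cfg.batch_size
        )
        macro = multiclass_macro_metrics(cm)
        rows.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": float(np.mean(ep_losses)),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "val_precision_macro": macro["precision"],
                "val_recall_macro": macro["recall"],
                "val_f1_macro": macro["f1"],
            }
        )
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {opt.lr:.5f}  "
                f"loss {rows[-1]['train_loss']:.4f}  val_acc {val_acc:.4f}"
            )
        if val_acc > best[0]:
            best = (val_acc, epoch, model.get_state(), cm)

    model.set_state(best[2])
    return ClsTrainResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best[1],
        best_val_accuracy=best[0],
        confusion=best[3],
        net_config=net_cfg,
        train_config=train_cfg,
        seed=seed,
        train_indices=tr_idx,
        val_indices=va_idx,
    )


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    fold_assignments: np.ndarray = field(repr=False, default=None)


def kfold_cv(
    images: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    train_cfg: ClsTrainConfig | None = None,
    net_cfg: ClsNetConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the classifier.

    Each fold trains a fresh model on (k-1)/k of the data (80% for k=5)
    and evaluates accuracy on the held-out fold; reports the fold
    accuracies and their mean +- sample standard deviation.
    """
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels)
    if (counts < k).any():
        small = np.flatnonzero(counts < k).tolist()
        raise ValueError(f"classes with fewer than k={k} images: {small}")
    train_cfg = train_cfg or ClsTrainConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    assignment = np.empty(len(labels), dtype=np.int64)
    rng = np.random.default_rng(seed)
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[va] = fold
        # train on the fold's training portion with an internal split only
        # for curve bookkeeping; accuracy is measured on the held-out fold
        sub_cfg = ClsTrainConfig(**{**asdict(train_cfg), "val_fraction": 0.125})
        res = train_classifier(
            images[tr], labels[tr], sub_cfg, net_cfg, seed=int(rng.integers(2**31))
        )
        _, acc, _ = _eval_classifier(
            res.model, np.asarray(images, dtype=np.float32)[va], labels[va],
            train_cfg.batch_size,
        )
        accs.append(acc)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if k > 1 else 0.0,
        fold_assignments=assignment,
    )


def predict_probs(model: ResNetClassifier, img: np.ndarray) -> np.ndarray:
    """Stage probabilities for one frame (softmax of the logits, eval mode)."""
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D gray image")
    logits = model.forward(img, train=False)
    return softmax_probs(logits)[0]


def gradcam(model: ResNetClassifier, img: np.ndarray, target_class: int) -> np.ndarray:
    """Class-activation heat map for one frame, normalised to [0, 1].

    ReLU of the head-weighted sum of the last convolutional feature maps
    (exact Grad-CAM for a GAP + linear head), min-max normalised and
    bilinearly upsampled to the input size.
    """
    if not (0 <= target_class < model.cfg.num_classes):
        raise ValueError(f"invalid class index {target_class}")
    img = np.asarray(img, dtype=np.float32)
    maps = model.forward_maps(img, train=False)[0]  # (C, h, w)
    weights = model.fc.W.data[target_class]  # (C,)
    cam = np.maximum(np.tensordot(weights, maps, axes=(0, 0)), 0.0)
    lo, hi = float(cam.min()), float(cam.max())
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    size = model.cfg.input_size
    return np.clip(
        _sk_resize(cam, (size, size), order=1, anti_aliasing=False), 0.0, 1.0
    )


def extract_features(
    model: ResNetClassifier,
    images: np.ndarray,
    seed: int = 0,
    batch_size: int = 32,
    n_neighbors: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Average-pool feature vectors plus a seeded 2-D UMAP embedding.

    The embedding uses the Euclidean metric; ``n_neighbors`` is clipped
    to the sample count for small inputs.
    """
    import umap

    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if len(images) == 0:
        raise ValueError("no images given")
    feats = np.concatenate(
        [
            model.forward_features(images[s : s + batch_size], train=False)
            for s in range(0, len(images), batch_size)
        ]
    )
    nn_eff = min(n_neighbors, max(2, len(images) - 1))
    reducer = umap.UMAP(
        n_components=2, metric="euclidean", random_state=seed, n_neighbors=nn_eff
    )
    embedding = reducer.fit_transform(feats)
    return feats, np.asarray(embedding, dtype=np.float64)


def save_checkpoint(result: ClsTrainResult, path: str | Path) -> Path:
    """Save classifier weights (.npz) with a JSON sidecar."""
    path = Path(path)
    np.savez(path, *result.model.get_state())
    sidecar = {
        "kind": "classifier",
        "net_config": asdict(result.net_config),
        "train_config": asdict(result.train_config),
        "seed": result.seed,
        "best_epoch": result.best_epoch,
        "best_val_accuracy": result.best_val_accuracy,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def load_checkpoint(path: str | Path) -> tuple[ResNetClassifier, dict]:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    model = ResNetClassifier(ClsNetConfig(**sidecar["net_config"]))
    with np.load(path) as npz:
        model.set_state([npz[k] for k in npz.files])
    return model, sidecar
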