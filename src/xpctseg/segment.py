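"""Two-step U-Net segmentation: binary foreground extraction, then
multiclass layer labelling of the background-zeroed image.

The network is the standard encoder–decoder with skip connections:
``depth`` pooling levels of double 3x3 convolutions, channel count doubling
per level, nearest-neighbour upsampling with skip concatenation on the way
up, and a 1x1 output head producing per-pixel class scores. Training uses
per-pixel categorical cross-entropy, RMSProp (batch size 1) with L2 weight
decay, and a reduce-on-plateau learning-rate schedule: when the best
validation loss fails to improve by more than a threshold for a set number
of consecutive epochs, the rate is divided by a fixed factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .dataset import AnnotatedPair, AugmentationParams, augment
from .phantom import LabelVolume, VolumeImage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class UNetConfig:
    """Topology of the encoder–decoder network."""

    depth: int = 4
    base_channels: int = 16
    in_channels: int = 1
    out_classes: int = 2
    skip_connections: bool = True

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.out_classes not in (2, 6):
            raise ValueError("out_classes must be 2 (binary) or 6 (background + 5 layers)")
        if not self.skip_connections:
            raise ValueError("skip connections are required by this architecture")


@dataclass
class TrainConfig:
    """Optimisation settings for one training step of the pipeline.

    ``momentum`` is the RMSProp squared-gradient smoothing constant; the
    learning rate drops by ``lr_reduce_factor`` whenever the best validation
    loss has not improved by more than ``lr_threshold`` for
    ``lr_patience_epochs`` consecutive epochs. ``min_lr`` > 0 enables early
    stopping once the schedule has driven the rate below it.
    """

    lr_initial: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-8
    lr_reduce_factor: float = 10.0
    lr_patience_epochs: int = 2
    lr_threshold: float = 1e-4
    batch_size: int = 1
    epochs: int = 20
    min_lr: float = 0.0
    seed: int = 0
    augmentation: AugmentationParams | None = None
    loss: str = "categorical_cross_entropy"
    optimizer: str = "rmsprop"

    def __post_init__(self):
        if self.lr_reduce_factor <= 1:
            raise ValueError("lr_reduce_factor must be > 1")
        for name in ("lr_initial", "lr_patience_epochs", "lr_threshold",
                     "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    train_dice: float
    val_dice: float
    lr: float


@dataclass
class TrainingLog:
    """Per-epoch loss/Dice/learning-rate history."""

    records: list[EpochRecord] = field(default_factory=list)

    def as_dicts(self) -> list[dict]:
        return [asdict(r) for r in self.records]


class UNet:
    """Encoder–decoder segmentation network (see module docstring)."""

    def __init__(self, cfg: UNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b, d = cfg.base_channels, cfg.depth
        ch = [b * 2 ** i for i in range(d + 1)]
        self.enc = []
        c_in = cfg.in_channels
        for i in range(d):
            self.enc.append(nn.DoubleConv(c_in, ch[i], rng))
            c_in = ch[i]
        self.pools = [nn.MaxPool2() for _ in range(d)]
        self.bottleneck = nn.DoubleConv(ch[d - 1], ch[d], rng)
        self.ups = [nn.Upsample2() for _ in range(d)]
        self.dec = [nn.DoubleConv(ch[i + 1] + ch[i], ch[i], rng)
                    for i in reversed(range(d))]
        self.head = nn.Conv1x1(ch[0], cfg.out_classes, rng)

    def parameters(self) -> list[nn.Parameter]:
        params = []
        for block in (*self.enc, self.bottleneck, *self.dec, self.head):
            params.extend(block.params())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(in_channels, H, W) → (out_classes, H, W) class scores.
        H and W must be divisible by 2**depth (see ``pad_to_depth``)."""
        h, w = x.shape[-2:]
        div = 2 ** self.cfg.depth
        if h % div or w % div:
            raise ValueError(f"input {h}x{w} not divisible by 2^depth={div}; "
                             "pad first (pad_to_depth)")
        skips = []
        x = np.ascontiguousarray(x, dtype=nn.F32)
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_channels.append((skip.shape[0], x.shape[0]))
            x = np.concatenate([skip, x], axis=0)
            x = dec.forward(x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for up, dec, (c_skip, _) in zip(reversed(self.ups), reversed(self.dec),
                                        reversed(self._skip_channels)):
            d = dec.backward(dx)
            dskips.append(d[:c_skip])
            dx = up.backward(d[c_skip:])
        dx = self.bottleneck.backward(dx)
        # dskips were collected shallowest-first; the encoder unwinds deepest-first
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dx = pool.backward(dx)
            dx = block.backward(dx + dskip)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0


def build_model(cfg: UNetConfig, seed: int = 0) -> UNet:
    """Construct a U-Net with deterministic, seed-controlled weights."""
    return UNet(cfg, seed=seed)


def normalize_image(image: np.ndarray) -> np.ndarray:
    """Per-image min–max normalisation to [0, 1] (constant images → 0)."""
    image = image.astype(np.float32)
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-12:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def pad_to_depth(image: np.ndarray, depth: int):
    """Reflect-pad H, W up to the next multiple of 2**depth.
    Returns (padded, (H, W)) so predictions can be cropped back."""
    div = 2 ** depth
    h, w = image.shape[-2:]
    ph, pw = (-h) % div, (-w) % div
    if ph or pw:
        pad = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
        image = np.pad(image, pad, mode="reflect")
    return image, (h, w)


def _dice_foreground(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    """Mean one-vs-rest Dice over foreground classes (quick train-time metric)."""
    scores = []
    for c in range(1, n_classes):
        p, t = pred == c, truth == c
        denom = p.sum() + t.sum()
        scores.append(1.0 if denom == 0 else 2.0 * np.logical_and(p, t).sum() / denom)
    return float(np.mean(scores))


def _prepare(pair: AnnotatedPair, depth: int):
    image = normalize_image(pair.image)
    img, orig = pad_to_depth(image, depth)
    msk, _ = pad_to_depth(pair.mask, depth)
    return img[None], msk.astype(np.int64), orig


def train(model: UNet, train_pairs: list[AnnotatedPair],
          val_pairs: list[AnnotatedPair], cfg: TrainConfig):
    """Train with batch size 1 and the reduce-on-plateau schedule.

    Training images are augmented on the fly (validation images never);
    everything is reproducible from ``cfg.seed`` — shuffling, augmentation
    draws, and (via ``build_model``) initial weights.

    Returns (model, TrainingLog).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.RMSProp(model.parameters(), lr=cfg.lr_initial, rho=cfg.momentum,
                     weight_decay=cfg.weight_decay)
    n_classes = model.cfg.out_classes
    log_ = TrainingLog()
    best_val = np.inf
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        losses, dices = [], []
        for i in order:
            pair = train_pairs[i]
            if cfg.augmentation is not None:
                pair = augment(pair, cfg.augmentation, rng)
            x, target, _ = _prepare(pair, model.cfg.depth)
            logits = model.forward(x)
            loss, dlogits, _ = nn.softmax_cross_entropy(logits, target)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; reduce the "
                    f"learning rate (current {opt.lr:g})")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            dices.append(_dice_foreground(logits.argmax(0), target, n_classes))

        val_losses, val_dices = [], []
        for pair in val_pairs:
            x, target, _ = _prepare(pair, model.cfg.depth)
            logits = model.forward(x)
            loss, _, _ = nn.softmax_cross_entropy(logits, target)
            val_losses.append(loss)
            val_dices.append(_dice_foreground(logits.argmax(0), target, n_classes))
        val_loss = float(np.mean(val_losses))

        log_.records.append(EpochRecord(
            epoch=epoch, train_loss=float(np.mean(losses)), val_loss=val_loss,
            train_dice=float(np.mean(dices)), val_dice=float(np.mean(val_dices)),
            lr=opt.lr))
        log.info("epoch %d: train loss %.4f dice %.3f | val loss %.4f dice %.3f"
                 " | lr %.2g", epoch, log_.records[-1].train_loss,
                 log_.records[-1].train_dice, val_loss,
                 log_.records[-1].val_dice, opt.lr)

        if best_val - val_loss > cfg.lr_threshold:
            best_val = val_loss
            stale = 0
        else:
            stale += 1
            if stale >= cfg.lr_patience_epochs:
                opt.lr /= cfg.lr_reduce_factor
                stale = 0
                log.info("plateau: reducing learning rate to %.2g", opt.lr)
                if cfg.min_lr > 0 and opt.lr < cfg.min_lr:
                    log.info("learning rate below min_lr; stopping early")
                    break
    return model, log_


def _predict_volume(model: UNet, volume: VolumeImage) -> LabelVolume:
    out = np.zeros(volume.data.shape, dtype=np.uint8)
    for z in range(volume.data.shape[0]):
        img, (h, w) = pad_to_depth(normalize_image(volume.data[z]), model.cfg.depth)
        logits = model.forward(img[None])
        out[z] = logits.argmax(0)[:h, :w].astype(np.uint8)
    return LabelVolume(out)


def predict_binary(model: UNet, volume: VolumeImage) -> LabelVolume:
    """Slice-wise argmax prediction with a 2-class model → {0,1} masks."""
    if model.cfg.out_classes != 2:
        raise ValueError("predict_binary needs a 2-class model")
    return _predict_volume(model, volume)


def predict_multiclass(model: UNet, masked_volume: VolumeImage) -> LabelVolume:
    """Slice-wise argmax prediction with a 6-output model → labels {0..5}.
    Argmax ties break toward the lowest class index."""
    if model.cfg.out_classes != 6:
        raise ValueError("predict_multiclass needs a 6-class model")
    return _predict_volume(model, masked_volume)


def apply_mask(volume: VolumeImage, mask: LabelVolume) -> VolumeImage:
    """Zero out background voxels (mask 0); foreground passes through."""
    if volume.data.shape != mask.labels.shape:
        raise ValueError("volume and mask shapes must match")
    return VolumeImage(volume.data * (mask.labels > 0), volume.pixel_size,
                       dict(volume.meta))


def compose_two_step(step1_mask: LabelVolume, step2_labels: LabelVolume) -> LabelVolume:
    """Final labels of the two-step procedure: multiclass labels where the
    binary mask is foreground, 0 elsewhere (hard composition invariant)."""
    if step1_mask.labels.shape != step2_labels.labels.shape:
        raise ValueError("mask and label shapes must match")
    return LabelVolume(np.where(step1_mask.labels > 0, step2_labels.labels, 0)
                       .astype(np.uint8))


def save_model(path: str | Path, model: UNet, train_cfg: TrainConfig | None = None) -> None:
    """Checkpoint weights plus the architecture (and training) config."""
    path = Path(path)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {"unet": asdict(model.cfg)}
    if train_cfg is not None:
        meta["train"] = asdict(train_cfg)
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    with open(path.with_suffix(".yaml")) as fh:
        meta = yaml.safe_load(fh)
    model = UNet(UNetConfig(**meta["unet"]))
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.parameters()):
            p.data[...] = data[f"p{i}"]
    return model
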