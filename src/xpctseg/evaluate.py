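"""Segmentation evaluation: one-vs-rest confusion counts and Dice per
class, run-level reports, training-curve plots, and a global-threshold
(Otsu) baseline for comparison with the learned segmentation.

Dice is 2·TP/(2·TP + FP + FN) = 2|A∩B|/(|A|+|B|); 1 means perfect
agreement, 0 disjoint masks. A class empty in both prediction and truth is
scored 1 by convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from skimage.filters import threshold_otsu

from .phantom import LabelVolume, VolumeImage
from .segment import TrainingLog


@dataclass(frozen=True)
class ClassDice:
    """One-vs-rest confusion counts and Dice for a single class."""

    tp: int
    fp: int
    fn: int
    tn: int
    dice: float

    @property
    def n_pixels(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiceReport:
    """Per-class Dice with confusion counts.

    ``mean_dice`` is the unweighted mean over foreground classes;
    ``pooled_dice`` pools foreground confusion counts before forming the
    ratio (micro average) — the two coincide for a single foreground class.
    """

    per_class: dict[int, ClassDice]
    mean_dice: float
    pooled_dice: float
    n_pixels: int

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_pixels": self.n_pixels,
            "mean_dice": self.mean_dice,
            "pooled_dice": self.pooled_dice,
            "per_class": {c: {"tp": e.tp, "fp": e.fp, "fn": e.fn, "tn": e.tn,
                              "dice": e.dice} for c, e in self.per_class.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["class", "tp", "fp", "fn", "tn", "dice"])
            for c, e in sorted(self.per_class.items()):
                writer.writerow([c, e.tp, e.fp, e.fn, e.tn, e.dice])


def _labels(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelVolume) else np.asarray(x)


def dice_score(pred, truth, class_id: int) -> ClassDice:
    """One-vs-rest Dice of ``class_id``; empty-vs-empty is defined as 1."""
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes must match")
    pm, tm = p == class_id, t == class_id
    tp = int(np.logical_and(pm, tm).sum())
    fp = int(pm.sum()) - tp
    fn = int(tm.sum()) - tp
    tn = p.size - tp - fp - fn
    denom = 2 * tp + fp + fn
    dice = 1.0 if denom == 0 else 2.0 * tp / denom
    return ClassDice(tp, fp, fn, tn, dice)


def evaluate_run(pred, truth, classes: list[int] | None = None,
                 include_background: bool = False) -> DiceReport:
    """Full per-class report over a prediction/truth volume pair.

    ``classes`` defaults to every label present in either volume;
    ``mean_dice`` averages over foreground classes (background excluded
    unless requested).
    """
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes must match")
    if classes is None:
        classes = sorted(set(np.unique(p)) | set(np.unique(t)))
    per_class = {int(c): dice_score(p, t, int(c)) for c in classes}
    fg = [c for c in per_class if include_background or c != 0]
    if not fg:
        fg = list(per_class)
    mean_dice = float(np.mean([per_class[c].dice for c in fg]))
    tp = sum(per_class[c].tp for c in fg)
    fp = sum(per_class[c].fp for c in fg)
    fn = sum(per_class[c].fn for c in fg)
    pooled = 1.0 if 2 * tp + fp + fn == 0 else 2.0 * tp / (2 * tp + fp + fn)
    return DiceReport(per_class, mean_dice, pooled, p.size)


def otsu_baseline(volume: VolumeImage | np.ndarray) -> LabelVolume:
    """Binary foreground mask by maximising between-class variance over a
    256-bin histogram of the whole volume (global threshold)."""
    data = volume.data if isinstance(volume, VolumeImage) else np.asarray(volume)
    if np.ptp(data) == 0:
        raise ValueError("Otsu threshold undefined for a constant volume")
    t = threshold_otsu(data, nbins=256)
    return LabelVolume((data > t).astype(np.uint8))


def plot_training_curves(log: TrainingLog, path: str | Path) -> None:
    """Loss and Dice curves over epochs (train vs validation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    epochs = [r.epoch for r in log.records]
    fig, (ax_d, ax_l) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_d.plot(epochs, [r.train_dice for r in log.records], label="train")
    ax_d.plot(epochs, [r.val_dice for r in log.records], label="validation")
    ax_d.set_xlabel("epoch"); ax_d.set_ylabel("Dice"); ax_d.legend()
    ax_l.plot(epochs, [r.train_loss for r in log.records], label="train")
    ax_l.plot(epochs, [r.val_loss for r in log.records], label="validation")
    ax_l.set_xlabel("epoch"); ax_l.set_ylabel("cross-entropy loss"); ax_l.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
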