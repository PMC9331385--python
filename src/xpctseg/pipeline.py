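"""End-to-end phantom pipeline: generate → project → retrieve → reconstruct
→ split → two-step train → evaluate.

This is the desk-scale analogue of the full experimental workflow, run
entirely on the synthetic laminar phantom so it completes on one CPU.
Problem sizes default to a 64-slice 128x128 phantom, 180° projections at
2x angular oversampling, and a depth-3 / 8-channel U-Net.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import evaluate as ev
from . import recon, segment
from .dataset import AnnotatedPair, AugmentationParams, split_dataset
from .phantom import LabelVolume, PhantomSpec, VolumeImage, generate_phantom, \
    simulate_projections
from .preprocess import PhaseRetrievalParams, flat_dark_correct, phase_retrieve

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Study conditions for one synthetic end-to-end run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_angles: int = 256
    geometry: str = "standard_180"
    alpha: float = 0.05
    fbp_filter: str = "ramp"
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    unet_depth: int = 3
    unet_base_channels: int = 8
    binary_epochs: int = 20
    multiclass_epochs: int = 80
    lr_initial: float = 1e-3
    min_lr_fraction: float = 1e-3  # early stop once LR < lr_initial * this
    seed: int = 0


@dataclass
class PipelineResult:
    """Everything the evaluation and acceptance reporting needs."""

    recon_volume: VolumeImage
    truth: LabelVolume
    binary_pred: LabelVolume
    final_pred: LabelVolume
    test_indices: np.ndarray
    binary_report: ev.DiceReport
    multiclass_report: ev.DiceReport
    otsu_report: ev.DiceReport
    binary_log: segment.TrainingLog
    multiclass_log: segment.TrainingLog

    @property
    def binary_test_dice(self) -> float:
        return self.binary_report.per_class[1].dice

    @property
    def multiclass_test_dice(self) -> float:
        return self.multiclass_report.mean_dice


def reconstruct_phantom(cfg: PipelineConfig):
    """Phantom → simulated frames → corrected/retrieved projections → FBP.

    Returns (reconstructed volume, truth labels)."""
    spec = cfg.phantom
    truth, density = generate_phantom(spec)
    projections, flat, dark = simulate_projections(
        density, cfg.n_angles, geometry=cfg.geometry,
        fringe_strength=spec.fringe_strength, noise_sigma=spec.noise_sigma,
        seed=spec.seed + 1)
    params = PhaseRetrievalParams(alpha=cfg.alpha, pixel_size_um=spec.voxel_size)
    retrieved = np.empty_like(projections.data)
    for a in range(projections.data.shape[0]):
        corr = flat_dark_correct(projections.data[a], flat, dark)
        retrieved[a] = phase_retrieve(corr, params, apply_prefactor=False)
    retrieved_vol = VolumeImage(retrieved, projections.pixel_size,
                                dict(projections.meta))
    log.info("projections corrected and phase-retrieved; reconstructing")
    vol = recon.reconstruct_volume(retrieved_vol, filter_name=cfg.fbp_filter)
    return vol, truth


def _pairs_from_volume(volume: VolumeImage, labels: np.ndarray) -> list[AnnotatedPair]:
    return [AnnotatedPair(volume.data[z], labels[z])
            for z in range(volume.data.shape[0])]


def run_two_step(cfg: PipelineConfig) -> PipelineResult:
    """Run the complete two-step segmentation study on one phantom.

    Step 1 trains the 2-class network on foreground-vs-background masks and
    predicts a binary mask for every slice; step 2 zeroes the background of
    every slice with the *predicted* masks, trains the 6-output network on
    the 5-layer labels, and composes the final labelling (background wins
    wherever step 1 said background). All reported Dice values are measured
    on the held-out test split.
    """
    vol, truth = reconstruct_phantom(cfg)
    labels = truth.labels

    aug = AugmentationParams(seed=cfg.seed)
    u_cfg = lambda k: segment.UNetConfig(depth=cfg.unet_depth,
                                         base_channels=cfg.unet_base_channels,
                                         out_classes=k)
    min_lr = cfg.lr_initial * cfg.min_lr_fraction

    # ---- step 1: binary foreground extraction -------------------------
    binary_pairs = _pairs_from_volume(vol, (labels > 0).astype(np.uint8))
    train_p, val_p, test_p = split_dataset(binary_pairs, cfg.fractions,
                                           seed=cfg.seed)
    split_tags = np.array([p.split_tag for p in binary_pairs])
    test_idx = np.flatnonzero(split_tags == "test")

    model1 = segment.build_model(u_cfg(2), seed=cfg.seed)
    t_cfg1 = segment.TrainConfig(epochs=cfg.binary_epochs, seed=cfg.seed,
                                 lr_initial=cfg.lr_initial, min_lr=min_lr,
                                 augmentation=aug)
    model1, log1 = segment.train(model1, train_p, val_p, t_cfg1)
    binary_pred = segment.predict_binary(model1, vol)

    binary_report = ev.evaluate_run(binary_pred.labels[test_idx],
                                    (labels > 0).astype(np.uint8)[test_idx],
                                    classes=[0, 1])

    # ---- step 2: multiclass layer labelling on the masked volume ------
    masked = segment.apply_mask(vol, binary_pred)
    mc_pairs = _pairs_from_volume(masked, labels)
    # same seed ⇒ identical slice partition as step 1
    train_m, val_m, test_m = split_dataset(mc_pairs, cfg.fractions, seed=cfg.seed)

    model2 = segment.build_model(u_cfg(6), seed=cfg.seed + 1)
    t_cfg2 = segment.TrainConfig(epochs=cfg.multiclass_epochs, seed=cfg.seed + 1,
                                 lr_initial=cfg.lr_initial, min_lr=min_lr,
                                 augmentation=aug)
    model2, log2 = segment.train(model2, train_m, val_m, t_cfg2)
    mc_pred = segment.predict_multiclass(model2, masked)
    final_pred = segment.compose_two_step(binary_pred, mc_pred)

    multiclass_report = ev.evaluate_run(final_pred.labels[test_idx],
                                        labels[test_idx],
                                        classes=list(range(6)))

    # ---- thresholding baseline (binary, same test slices) -------------
    otsu_mask = ev.otsu_baseline(vol)
    otsu_report = ev.evaluate_run(otsu_mask.labels[test_idx],
                                  (labels > 0).astype(np.uint8)[test_idx],
                                  classes=[0, 1])

    return PipelineResult(vol, truth, binary_pred, final_pred, test_idx,
                          binary_report, multiclass_report, otsu_report,
                          log1, log2)
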