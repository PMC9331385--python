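"""Dataset assembly for the two-step segmentation: thick-slice (slab)
annotation support, train/val/test splitting, resizing and augmentation.

Thick-slice annotation replaces k consecutive thin tomographic slices by
their pointwise maximum projection, which makes laminar boundaries easier
to delineate by hand; the slab mask is then propagated back to all k
constituent slices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import rescale

from .phantom import VolumeImage


@dataclass
class ThickSliceStack:
    """k consecutive slices and their maximum-projection composite."""

    slices: np.ndarray  # (k, H, W)
    smax: np.ndarray  # (H, W)
    z_start: int

    @property
    def k(self) -> int:
        return self.slices.shape[0]


@dataclass
class AnnotatedPair:
    """A grayscale slice with its integer mask ({0,1} for the binary step,
    {0..5} for the multiclass step) and an optional split tag."""

    image: np.ndarray
    mask: np.ndarray
    split_tag: str | None = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must share one shape")


@dataclass
class AugmentationParams:
    """On-the-fly training augmentation: mirroring (each axis, p=0.5),
    rotation uniform in ±rotation_range degrees, and additive Gaussian
    image noise (masks stay untouched by noise)."""

    mirror: bool = True
    rotation_range: float = 90.0
    noise_sigma: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.rotation_range < 0 or self.noise_sigma < 0:
            raise ValueError("rotation_range and noise_sigma must be >= 0")


def stack_thick_slices(volume: VolumeImage | np.ndarray, k: int = 10) -> list[ThickSliceStack]:
    """Group every k consecutive slices (stride k, trailing remainder
    dropped) and compute each group's pointwise maximum composite."""
    if k < 1:
        raise ValueError("k must be >= 1")
    data = volume.data if isinstance(volume, VolumeImage) else np.asarray(volume)
    if data.shape[0] < k:
        raise ValueError(f"volume depth {data.shape[0]} < k={k}")
    stacks = []
    for start in range(0, data.shape[0] - k + 1, k):
        group = data[start:start + k]
        stacks.append(ThickSliceStack(group, group.max(axis=0), start))
    return stacks


def unstack_mask(stack: ThickSliceStack, thick_mask: np.ndarray) -> list[np.ndarray]:
    """Propagate a slab mask back to the k constituent slices
    (extrapolation = replication along z)."""
    thick_mask = np.asarray(thick_mask)
    if thick_mask.shape != stack.smax.shape:
        raise ValueError("thick mask shape must match the slab composite")
    return [thick_mask.copy() for _ in range(stack.k)]


def split_dataset(pairs: list[AnnotatedPair],
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0):
    """Random disjoint train/val/test partition.

    Sizes are floor(n·fraction) for each subset with the remainder assigned
    to train, e.g. 300 pairs at (0.8, 0.1, 0.1) → 240/30/30. Tags each pair.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(pairs)
    if n < 3:
        raise ValueError("need at least 3 pairs to split")
    counts = [int(np.floor(n * f)) for f in fractions]
    counts[0] += n - sum(counts)
    perm = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum(counts)
    subsets = (perm[:bounds[0]], perm[bounds[0]:bounds[1]], perm[bounds[1]:bounds[2]])
    out = []
    for tag, idx in zip(("train", "val", "test"), subsets):
        subset = []
        for i in idx:
            pairs[i].split_tag = tag
            subset.append(pairs[i])
        out.append(subset)
    return tuple(out)


def resize_pair(pair: AnnotatedPair, scale: float = 0.5) -> AnnotatedPair:
    """Downscale a pair: bilinear for the image, nearest-neighbour for the
    mask (label-preserving)."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if scale == 1:
        return replace(pair, image=pair.image.copy(), mask=pair.mask.copy())
    image = rescale(pair.image.astype(np.float32), scale, order=1,
                    anti_aliasing=True, preserve_range=True).astype(np.float32)
    mask = rescale(pair.mask, scale, order=0, anti_aliasing=False,
                   preserve_range=True).astype(pair.mask.dtype)
    return AnnotatedPair(image, mask, pair.split_tag)


def augment(pair: AnnotatedPair, params: AugmentationParams,
            rng: np.random.Generator | None = None) -> AnnotatedPair:
    """Apply one random geometric+noise augmentation.

    The same mirror/rotation is applied to image and mask (mask via
    nearest-neighbour with fill label 0); noise goes on the image only.
    Pass a persistent ``rng`` to draw a fresh transform per call; otherwise
    one is created from ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    image, mask = pair.image.astype(np.float32), pair.mask
    if params.mirror:
        if rng.random() < 0.5:
            image, mask = image[::-1], mask[::-1]
        if rng.random() < 0.5:
            image, mask = image[:, ::-1], mask[:, ::-1]
    if params.rotation_range > 0:
        angle = rng.uniform(-params.rotation_range, params.rotation_range)
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                              mode="constant", cval=0)
    if params.noise_sigma > 0:
        image = image + rng.normal(0.0, params.noise_sigma,
                                   size=image.shape).astype(np.float32)
    return AnnotatedPair(np.ascontiguousarray(image, dtype=np.float32),
                         np.ascontiguousarray(mask), pair.split_tag)
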