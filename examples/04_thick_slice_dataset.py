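"""Thick-slice (slab) annotation workflow and dataset assembly.

Ten consecutive thin slices are replaced by their pointwise maximum so a
human can annotate one composite instead of ten; the slab mask is then
propagated back to every constituent slice. Pairs are split 0.8/0.1/0.1
into train/validation/test.
"""

import numpy as np

from xpctseg import (AnnotatedPair, PhantomSpec, augment, AugmentationParams,
                     generate_phantom, resize_pair, split_dataset,
                     stack_thick_slices, unstack_mask)

spec = PhantomSpec(volume_shape=(60, 64, 64), seed=5)
labels, density = generate_phantom(spec)

stacks = stack_thick_slices(density, k=10)
print(f"{density.data.shape[0]} slices -> {len(stacks)} slabs of k=10")
print("slab composite >= every constituent slice:",
      all(np.all(s.smax[None] >= s.slices) for s in stacks))

# annotate each slab from the ground-truth labels, then propagate back
label_stacks = stack_thick_slices(labels.labels, k=10)
per_slice_masks = []
for s, m in zip(stacks, label_stacks):
    per_slice_masks.extend(unstack_mask(s, m.smax.astype(np.uint8)))
print(f"unstacking returned {len(per_slice_masks)} per-slice masks")

pairs = [AnnotatedPair(density.data[z], per_slice_masks[z])
         for z in range(len(per_slice_masks))]
train, val, test = split_dataset(pairs, (0.8, 0.1, 0.1), seed=17)
print(f"split: {len(train)}/{len(val)}/{len(test)} train/val/test")

small = resize_pair(train[0], 0.5)
print(f"resized pair: image {small.image.shape}, labels preserved: "
      f"{sorted(np.unique(small.mask))}")
aug = augment(small, AugmentationParams(seed=1))
print(f"augmented pair keeps alignment: image {aug.image.shape}, "
      f"mask {aug.mask.shape}")
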