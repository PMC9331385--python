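"""Train the two-step segmentation on a small phantom and score it.

Step 1 separates specimen from background (2 classes); step 2 labels the
5 tissue layers inside the predicted foreground (6 outputs). Dice is
reported on the held-out test split, next to a global Otsu-threshold
baseline. This example uses a reduced phantom and epoch budget so it runs
in a couple of minutes; see scripts/acceptance.py for the full study.
"""

from xpctseg import PhantomSpec, PipelineConfig, run_two_step

cfg = PipelineConfig(
    phantom=PhantomSpec(volume_shape=(32, 96, 96), seed=11),
    n_angles=192,
    binary_epochs=8,
    multiclass_epochs=16,
    seed=11,
)
result = run_two_step(cfg)

print(f"binary step  — test foreground Dice: {result.binary_test_dice:.3f}")
print(f"multiclass   — mean test Dice over 5 layers: "
      f"{result.multiclass_test_dice:.3f}")
for c, entry in sorted(result.multiclass_report.per_class.items()):
    if c:
        print(f"    layer {c}: Dice {entry.dice:.3f}")
print(f"Otsu baseline — binary Dice: {result.otsu_report.per_class[1].dice:.3f} "
      "(global thresholding cannot separate paraffin from the darkest layer)")
print(f"binary epochs run: {len(result.binary_log.records)}, "
      f"multiclass: {len(result.multiclass_log.records)} (plateau early stop)")
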