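# xpctseg

Layer-wise semantic segmentation of propagation-based X-ray phase-contrast
tomography (XPCT) volumes of laminar soft tissue — built for the study
design used on the human olfactory bulb (OB), whose nested cell-type
layers (olfactory-nerve/glomerular side outermost, granule-cell side
innermost) have indistinct boundaries that defeat manual delineation and
global thresholding alike.

The package implements the complete processing chain on synthetic data,
so every stage can be developed, tested and benchmarked without any
experimental download:

1. **phantom** — a seeded generator of paraffin-embedded laminar phantoms
   (5 nested layers, glomerulus-like 100–200 µm inclusions, drifting
   elliptical cross-section) plus a parallel-beam projection simulator
   with flat/dark frames, first-order phase-contrast fringes and detector
   noise; standard 180° and offset-axis 360° half-acquisition geometries.
2. **preprocess** — flat/dark correction `(raw − dark)/(flat − dark)`,
   single-distance phase retrieval
   `T = (2/Dλ)·F⁻¹[F(I/I₀ − 1)/(kx² + ky² + α)]` (linearised
   transport-of-intensity with zero-frequency regularisation α), and 2×2
   binning.
3. **recon** — stitching of 180°-separated half-acquisition pairs into an
   extended-width sinogram, and filtered back projection
   (ramp/Shepp-Logan/Hann).
4. **dataset** — thick-slice (slab) annotation: `Smax = max_z{A₁…A₁₀}`
   composites for annotation, mask propagation back to all k slices,
   0.8/0.1/0.1 train/val/test splitting, 50% resizing, and augmentation
   (mirroring, ±90° rotation, σ = 10⁻⁴ Gaussian noise).
5. **segment** — a U-Net (encoder–decoder with skip connections, NumPy
   engine, CPU) trained with per-pixel categorical cross-entropy, RMSProp
   (momentum constant 0.9, weight decay 10⁻⁸, batch 1) and a
   reduce-on-plateau schedule (factor 10, patience 2 epochs, threshold
   10⁻⁴); two steps: binary foreground extraction (20 epochs), then
   5-layer labelling of the background-zeroed image (≤80 epochs).
6. **evaluate** — one-vs-rest confusion counts and
   `Dice = 2TP/(2TP+FP+FN)` per class, mean/pooled reports, training-curve
   plots, and a global Otsu-threshold baseline.

## Worked example

`examples/` contains one short script per capability. The end-to-end one
(reduced sizes, a couple of minutes on one CPU):

```sh
$ python examples/05_two_step_segmentation.py
binary step  — test foreground Dice: 0.977
multiclass   — mean test Dice over 5 layers: 0.746
    layer 1: Dice 0.925
    layer 2: Dice 0.861
    layer 3: Dice 0.937
    layer 4: Dice 0.930
    layer 5: Dice 0.076
Otsu baseline — binary Dice: 0.680 (global thresholding cannot separate paraffin from the darkest layer)
binary epochs run: 8, multiclass: 16 (plateau early stop)
```

Reading: after 8 epochs the binary network separates specimen from
paraffin/air with Dice 0.977 on held-out slices, while the best global
threshold only reaches 0.680 — the phantom's paraffin density deliberately
overlaps its darkest tissue layer, so thresholding must sacrifice one or
the other. The abbreviated multiclass run (16 epochs at 96×96) labels four
of the five layers well; the innermost core has not converged yet at this
budget — the full-scale study below trains it to ≥0.99.

The same study at full scale (64×128×128 phantom, 20/≤80 epochs) is what
`scripts/acceptance.py` runs; a representative result is binary test Dice
≈ 0.996 and mean 5-layer test Dice ≈ 0.993 in about 8 CPU-minutes.

A thin CLI mirrors the stages (`xpctseg generate/project/preprocess/recon/
dataset/train/predict/evaluate/pipeline`); see `xpctseg --help`.

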