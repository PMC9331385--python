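# Methods

`xpctseg` implements, end to end and on synthetic data, a pipeline for
layer-wise semantic segmentation of propagation-based X-ray phase-contrast
tomography (XPCT) volumes of laminar soft tissue such as the human
olfactory bulb: projection preprocessing and single-distance phase
retrieval, filtered back projection, thick-slice dataset assembly, a
two-step convolutional segmentation, and Dice evaluation. This note
records the models, the defaults and why they were chosen, and what the
synthetic experiments do and do not demonstrate.

## The imaging model

**Forward simulation.** The phantom is a cylindrical paraffin block
containing a laminar body of `n_layers` nested, slightly elliptical layers
whose centre drifts along the rotation axis (human laminar tissue lacks
strict circular organisation). Projections are parallel-beam line
integrals (slice-wise Radon transform via scikit-image). Near-field phase
contrast is simulated to first order as edge enhancement: the measured
signal is `R + f·∇²R`, where `R` is the line-integral image and `f` the
`fringe_strength`. Raw frames follow `raw = dark + (flat − dark)·signal`
plus white Gaussian noise, so flat/dark correction recovers the signal
exactly. A full Fresnel wave-optics propagator is deliberately out of
scope: the retrieval filter below is itself the linearised inverse of this
first-order model, so simulation and inversion are self-consistent at desk
scale.

**Phase retrieval.** The single-distance, linearised
transport-of-intensity inversion is a Fourier filter applied to the
relative modulation g = I/I₀ − 1:

    T = (2 / Dλ) · F⁻¹[ F(g) / (kx² + ky² + α) ]

with D the propagation distance, λ the wavelength (λ[m] = 1.2398·10⁻⁹ /
E[keV], default 25 keV, D = 0.5 m), and α ≥ 0 a dimensionless
regularisation of the zero-frequency divergence. Frequencies are the
angular grid 2π·fftfreq/pixel_size (rad/µm). Conventions chosen where the
formulation is open:

- the scalar prefactor 2/(Dλ) sits outside the filter; only the filter
  *shape* affects segmentation, and the pipeline runs with the prefactor
  off (`apply_prefactor=False`) since images are min–max normalised later;
- the DC term is regularised solely by α; α = 0 is allowed only for
  zero-mean input and otherwise raises;
- odd-sized inputs are reflect-padded to even size and cropped back, to
  avoid wrap-around fringes at the borders;
- α has no published value; the pipeline default α = 0.05 rad²/µm² puts
  the Lorentzian cutoff √α ≈ 0.22 rad/µm just below the Nyquist frequency
  of the 13 µm phantom grid — strong suppression of the Laplacian fringes
  with mild (≈1 px) blur. It is a config value, not a constant.

**Reconstruction.** Standard parallel-beam FBP (scikit-image `iradon`;
ramp/Shepp-Logan/Hann filters, linear interpolation, output masked to the
inscribed circle). For 360° half-acquisition scans, 180°-separated
projection pairs are detector-mirrored about the offset rotation axis and
blended into one extended-width sinogram; blend weights ramp toward each
view's own detector edge, and the axis must lie on the half-pixel grid
(2·offset integral). The stitched axis is centred, matching `iradon`'s
assumption. Automatic axis finding is out of scope; the offset is
metadata.

## The phantom as study conditions

Defaults (one 64×128×128 volume at 13 µm voxels) are fixed once and shared
by tests and the acceptance study:

- layer radius fractions (1.0, 0.8, 0.62, 0.45, 0.28) of a laminar body
  occupying 70% of the half field of view, inside a paraffin cylinder at
  95%;
- per-class densities: paraffin 0.35; layers, outermost→innermost, 0.55,
  0.85, 0.40, 0.70, 1.00 (air 0). The paraffin level deliberately overlaps
  the darkest layer within reconstruction noise: paraffin embedding and
  dehydrated soft tissue have similar X-ray density, which is exactly why
  global thresholding underperforms a learned segmentation and why the
  comparison against the Otsu baseline is meaningful rather than a
  formality;
- glomerulus-like spherical inclusions, 100–200 µm diameter, scattered in
  layer 2 at 100 per mm³, brighter or darker than their layer by ±0.12
  with balanced sign. Labels follow the layer, not the inclusion. The
  13 µm voxel (rather than the 2.6 µm binned experimental pitch) keeps
  these inclusions cell-scale relative to the 128-px body; at 2.6 µm they
  would span half the bulb;
- centre drift 1.3 µm/slice (±3 px over the volume) and axis ratio 0.92;
- acquisition: 256 angles over 180° (2× angular oversampling of the image
  width), fringe strength 0.05, detector noise σ = 0.01;
- all randomness flows from one integer seed through
  `numpy.random.Generator`; identical seeds give bit-identical phantoms.
  Inclusion spheres are drawn per-sphere from a layer-specific stream so
  that raising the density only ever adds spheres.

What the phantom does **not** emulate: vasculature and capillary networks,
polychromatic beam and beam hardening, ring artefacts, detector point
spread, wave-optics fringes beyond first order, and true anatomical layer
geometry (layer radii are knobs, not anatomy). Passing the synthetic study
therefore shows the pipeline's machinery is correct and that the two-step
design works when layers differ in mean density at realistic noise; it
does not certify performance on experimental scans.

## Dataset assembly

Thick-slice (slab) annotation replaces k = 10 consecutive slices by their
pointwise maximum projection (`dim(Smax) = dim(Aᵢ)` is asserted), and the
slab mask is propagated back by replication to all k slices — the simplest
reading of "extrapolation" and the only one that needs no interpolation
rule. Slabs are non-overlapping (stride k, trailing remainder dropped).
The random split is floor(n·fraction) per subset with the remainder to
train: 300 pairs at (0.8, 0.1, 0.1) give 240/30/30. Resizing is bilinear
for images, nearest-neighbour for masks. Training-time augmentation:
mirror each axis with p = 0.5, rotation uniform in ±90° (nearest-neighbour
for masks, fill label 0), Gaussian image noise σ = 10⁻⁴ on [0,1]-normalised
images; one persistent generator drives all draws so runs are reproducible.

## Two-step segmentation

**Network.** A standard U-Net: `depth` levels of double 3×3
convolution + ReLU, 2×2 max pooling, channel count doubling per level,
nearest-neighbour 2× upsampling with skip concatenation, 1×1 output head;
softmax over classes per pixel. Inputs are min–max normalised per image
and reflect-padded to a multiple of 2^depth. The engine is a small NumPy
implementation (im2col convolution on BLAS, explicit backward passes)
written for single-sample CPU training; exact channel counts are not
prescribed anywhere, so the class default is depth 4 / 16 base channels
and the desk-scale pipeline uses depth 3 / 8 base channels (≈122k
parameters), which one CPU trains in minutes.

**Training.** Per-pixel categorical cross-entropy; RMSProp with
squared-gradient smoothing constant 0.9 ("momentum" in the common RMSProp
parlance; an optional heavy-ball velocity term exists and defaults off),
L2 weight decay 10⁻⁸, batch size 1; 20 epochs for the binary step and up
to 80 for the multiclass step. Learning rate starts at 10⁻³ (no published
value; chosen as the conventional RMSProp default that converged without
oscillation on separable data) and is divided by 10 whenever the best
validation loss fails to improve by more than 10⁻⁴ for 2 consecutive
epochs. The pipeline stops a run early once the schedule has driven the
rate below 10⁻³ of its initial value — by then updates are numerically
idle, matching the plateau observed in long multiclass training.

**Two-step procedure.** Step 1 (2 classes) extracts specimen from
background; its predicted mask zeroes the background of every slice; step
2 (6 outputs) labels the 5 layers on the masked image. The final labelling
composes both: background wherever step 1 said background, step 2's label
elsewhere (a hard invariant, asserted in tests). Argmax ties break toward
the lower class index.

**Evaluation.** One-vs-rest confusion counts per class and
Dice = 2TP/(2TP+FP+FN); a class empty in both volumes scores 1. Reports
give the unweighted mean over foreground classes and the pooled (micro)
variant, since a headline "Dice" can mean either. The Otsu baseline
thresholds the whole reconstructed volume on a 256-bin histogram.

## Desk-scale study and numerical choices

The acceptance study (`scripts/acceptance.py`, also exercised by the
acceptance tests) runs the full chain on the default phantom: 64 slices
give 52/6/6 train/val/test pairs at native 128×128; the binary step
trains 20 epochs, the multiclass step up to 80 with the early stop above
(typically ~35–40). Reported numbers are the test-split foreground Dice
(binary) and the mean test-split Dice over the 5 layer classes
(multiclass), computed from the composed prediction. Test-time inference
is deterministic; training is bit-reproducible for a fixed seed and BLAS.

Degenerate inputs are defined rather than left to chance: constant images
normalise to zero; empty train/val sets, shape mismatches, non-monotone
layer radii, sub-voxel innermost layers, unknown FBP filters and
non-positive angle counts raise; a non-finite training loss aborts with
the current learning rate in the message.

## Known limitations

- The NumPy engine is single-image SGD on CPU; it is not meant for
  experimental 730×730×4000 volumes, though nothing in the API precludes
  swapping a faster backend behind `segment`.
- Half-acquisition stitching assumes an axis on the half-pixel grid and
  equispaced 360° angles; sub-pixel axis calibration is out of scope.
- The Radon/FBP pair inherits scikit-image's ~1–2% interpolation accuracy;
  tolerances in the tests reflect that floor.
- Per-image min–max normalisation is sensitive to slices with no
  structure: a specimen-free slice stretches pure noise to full range.
  Training sets should therefore include specimen-free slices (real scans
  have them at the volume ends; the synthetic study's background class
  plays the same role).
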