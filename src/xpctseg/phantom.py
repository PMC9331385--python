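"""Synthetic laminar-tissue tomography phantom.

Emulates the imaging situation of a paraffin-embedded olfactory-bulb-like
specimen: a cylindrical paraffin block containing a laminar body of nested
tissue layers (outermost nerve/glomerular side to innermost granule-cell
side), with cell-scale spherical inclusions such as glomeruli (100–200 µm
diameter) scattered in a chosen layer. The laminar body drifts and is
slightly elliptical across slices, so the lamination is not a perfect
circular cylinder — human bulbs lack strict circular organisation.

From the labelled "tissue density" volume the module simulates parallel-beam
projections with flat/dark frames, first-order phase-contrast edge fringes
(Laplacian edge enhancement) and Gaussian detector noise, in either a
standard 180° geometry or a 360° half-acquisition geometry with an offset
rotation axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import radon


@dataclass
class VolumeImage:
    """3D grayscale image, axes (z, y, x), z = tomographic rotation axis.

    ``meta`` carries acquisition context (geometry, angles, axis offset)
    when the volume is a projection stack.
    """

    data: np.ndarray
    pixel_size: float  # µm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")


@dataclass(frozen=True)
class LabelVolume:
    """Integer labels aligned to a VolumeImage: 0 = background (paraffin and
    air), 1..n_layers = tissue layers ordered outermost → innermost."""

    labels: np.ndarray

    def __post_init__(self):
        if self.labels.dtype.kind not in "iu":
            raise ValueError("labels must be an integer array")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise parameters of the synthetic specimen.

    ``layer_radii`` are strictly decreasing fractions of the laminar-body
    radius; ``contrast_levels`` has one entry per class (paraffin background
    first, then each layer outermost → innermost); ``inclusion_density`` is
    inclusions per mm³ for each layer. ``bulb_center_drift`` (µm per slice)
    translates the body across slices. Identical seeds give bit-identical
    phantoms.
    """

    volume_shape: tuple[int, int, int] = (64, 128, 128)
    voxel_size: float = 13.0  # µm
    n_layers: int = 5
    layer_radii: tuple[float, ...] = (1.0, 0.8, 0.62, 0.45, 0.28)
    bulb_center_drift: float = 1.3  # µm per slice
    inclusion_density: tuple[float, ...] = (0.0, 100.0, 0.0, 0.0, 0.0)  # per mm³
    inclusion_radius_range: tuple[float, float] = (50.0, 100.0)  # µm
    inclusion_contrast: float = 0.12
    contrast_levels: tuple[float, ...] = (0.35, 0.55, 0.85, 0.40, 0.70, 1.00)
    air_level: float = 0.0
    block_radius: float = 0.95  # fraction of half field of view
    bulb_radius: float = 0.70  # fraction of half field of view
    ellipticity: float = 0.92  # minor/major axis ratio of the laminar body
    noise_sigma: float = 0.01
    fringe_strength: float = 0.05
    seed: int = 0

    def __post_init__(self):
        r = np.asarray(self.layer_radii, dtype=float)
        if len(r) != self.n_layers:
            raise ValueError("layer_radii must have n_layers entries")
        if np.any(r <= 0) or np.any(r > 1) or np.any(np.diff(r) >= 0):
            raise ValueError("layer_radii must be strictly decreasing fractions in (0, 1]")
        if len(self.contrast_levels) != self.n_layers + 1:
            raise ValueError("contrast_levels must have n_layers + 1 entries")
        if len(self.inclusion_density) != self.n_layers:
            raise ValueError("inclusion_density must have n_layers entries")
        nz, ny, nx = self.volume_shape
        half = min(ny, nx) / 2.0
        if r[-1] * self.bulb_radius * half < 1.0:
            raise ValueError("volume too small to contain the innermost layer")


def generate_phantom(spec: PhantomSpec) -> tuple[LabelVolume, VolumeImage]:
    """Rasterise the phantom: aligned label volume and noiseless density volume.

    Per-class mean intensity of the density volume equals
    ``spec.contrast_levels`` (exactly, when ``inclusion_density`` is zero;
    inclusions perturb intensities ±``inclusion_contrast`` with balanced
    sign). Labels follow the layer geometry, not the inclusions.
    """
    nz, ny, nx = spec.volume_shape
    rng = np.random.default_rng(spec.seed)
    half = min(ny, nx) / 2.0
    r_block = spec.block_radius * half
    r_bulb = spec.bulb_radius * half
    radii_px = np.asarray(spec.layer_radii) * r_bulb

    drift_px_per_slice = spec.bulb_center_drift / spec.voxel_size
    theta = rng.uniform(0, 2 * np.pi)  # drift direction
    phi = rng.uniform(0, np.pi)  # ellipse orientation
    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0

    total_drift = abs(drift_px_per_slice) * nz / 2.0
    if radii_px[0] / spec.ellipticity + total_drift > r_block:
        raise ValueError("bulb drifts outside the paraffin block; reduce "
                         "bulb_center_drift or bulb_radius")

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    density = np.full((nz, ny, nx), spec.air_level, dtype=np.float32)

    cos_p, sin_p = np.cos(phi), np.sin(phi)
    for z in range(nz):
        dz = (z - (nz - 1) / 2.0) * drift_px_per_slice
        cy = cy0 + dz * np.sin(theta)
        cx = cx0 + dz * np.cos(theta)
        u = (xx - cx) * cos_p + (yy - cy) * sin_p
        v = -(xx - cx) * sin_p + (yy - cy) * cos_p
        r_ell = np.sqrt(u ** 2 + (v / spec.ellipticity) ** 2)
        r_cen = np.sqrt((xx - cx0) ** 2 + (yy - cy0) ** 2)
        block = r_cen <= r_block
        density[z][block] = spec.contrast_levels[0]
        for k in range(spec.n_layers):  # outermost first; inner assignments overwrite
            inside = r_ell <= radii_px[k]
            labels[z][inside] = k + 1
            density[z][inside] = spec.contrast_levels[k + 1]

    _add_inclusions(spec, labels, density)
    return LabelVolume(labels), VolumeImage(density, spec.voxel_size)


def _add_inclusions(spec: PhantomSpec, labels: np.ndarray,
                    density: np.ndarray) -> None:
    """Scatter bright/dark spheres into each layer at its stated density.

    Sphere count is deterministic (rounded expectation) so that inclusion
    voxel count is monotone in density under a fixed seed protocol.
    """
    nz, ny, nx = labels.shape
    voxel_mm3 = (spec.voxel_size * 1e-3) ** 3
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(np.float32)
    for k, dens in enumerate(spec.inclusion_density):
        if dens <= 0:
            continue
        layer_mask = labels == k + 1
        n_vox = int(layer_mask.sum())
        if n_vox == 0:
            continue
        n_spheres = int(round(dens * n_vox * voxel_mm3))
        if n_spheres == 0:
            continue
        coords = np.argwhere(layer_mask)
        # per-sphere sequential draws from a layer-specific stream: sphere i
        # is identical regardless of how many follow, so raising the density
        # only ever adds spheres (voxel-count monotonicity at fixed seed)
        layer_rng = np.random.default_rng((spec.seed, k))
        level = spec.contrast_levels[k + 1]
        for _ in range(n_spheres):
            cz, cy, cx = coords[layer_rng.integers(0, len(coords))]
            r_px = layer_rng.uniform(*spec.inclusion_radius_range) / spec.voxel_size
            s = 1.0 if layer_rng.random() < 0.5 else -1.0
            zlo, zhi = max(0, int(cz - r_px) - 1), min(nz, int(cz + r_px) + 2)
            ylo, yhi = max(0, int(cy - r_px) - 1), min(ny, int(cy + r_px) + 2)
            xlo, xhi = max(0, int(cx - r_px) - 1), min(nx, int(cx + r_px) + 2)
            sub = (slice(zlo, zhi), slice(ylo, yhi), slice(xlo, xhi))
            d2 = ((zz[sub] - cz) ** 2 + (yy[sub] - cy) ** 2 + (xx[sub] - cx) ** 2)
            sphere = (d2 <= r_px ** 2) & layer_mask[sub]
            density[sub][sphere] = level + s * spec.inclusion_contrast


def simulate_projections(volume: VolumeImage, n_angles: int,
                         geometry: str = "standard_180",
                         fringe_strength: float = 0.0,
                         noise_sigma: float = 0.0,
                         seed: int = 0,
                         flat: np.ndarray | None = None,
                         dark: np.ndarray | None = None,
                         detector_width: int | None = None,
                         axis_offset: float | None = None,
                         ) -> tuple[VolumeImage, np.ndarray, np.ndarray]:
    """Simulate raw detector frames from a density volume.

    Parallel-beam line integrals per angle (slice-wise Radon transform);
    phase-contrast fringing added to first order as
    ``fringe_strength × ∇²(projection)`` (Fresnel edge enhancement); frames
    then follow the detector model ``raw = dark + (flat − dark)·signal``
    plus Gaussian noise, so flat/dark correction recovers the signal.

    ``standard_180`` spans [0, 180°) with the axis detector-centred;
    ``full_360_half_acquisition`` spans [0, 360°) with the rotation axis
    offset from the detector centre so 180°-separated pairs extend the
    field of view. Returns (projections, flat, dark) where projections has
    axes (angle, z, detector).
    """
    if n_angles < 1:
        raise ValueError("n_angles must be >= 1")
    if geometry not in ("standard_180", "full_360_half_acquisition"):
        raise ValueError(f"unknown geometry {geometry!r}")
    data = volume.data
    nz, ny, nx = data.shape
    rng = np.random.default_rng(seed)

    if geometry == "standard_180":
        theta = np.linspace(0.0, 180.0, n_angles, endpoint=False)
        sinos = np.stack([
            radon(data[z].astype(np.float64), theta=theta, circle=True)
            for z in range(nz)
        ])  # (nz, det, n_angles)
        proj = sinos.transpose(2, 0, 1).astype(np.float32)  # (angle, z, det)
        offset = 0.0
    else:
        if n_angles % 2:
            raise ValueError("half-acquisition needs an even n_angles (180° pairs)")
        half = n_angles // 2
        theta = np.linspace(0.0, 180.0, half, endpoint=False)
        sinos = np.stack([
            radon(data[z].astype(np.float64), theta=theta, circle=True)
            for z in range(nz)
        ])
        full = sinos.transpose(2, 0, 1).astype(np.float32)  # (half, z, det)
        # opposite view: p(θ+180, s) = p(θ, −s); detector flip about (W−1)/2
        opposite = full[:, :, ::-1]
        w_full = full.shape[2]
        if detector_width is None:
            detector_width = 3 * w_full // 4
        # rightmost window of the full detector; axis ends up left of centre
        b = w_full - detector_width
        c_axis = (w_full - 1) / 2.0 - b
        offset = c_axis - (detector_width - 1) / 2.0
        if axis_offset is not None:
            offset = axis_offset
            b = int(round((w_full - 1) / 2.0 - (detector_width - 1) / 2.0 - offset))
            if b < 0 or b + detector_width > w_full:
                raise ValueError("axis_offset places detector outside simulated field")
        proj = np.concatenate([full, opposite], axis=0)[:, :, b:b + detector_width]

    if fringe_strength:
        for a in range(proj.shape[0]):
            proj[a] += fringe_strength * ndimage.laplace(proj[a])

    det_shape = proj.shape[1:]
    if flat is None:
        flat = np.ones(det_shape, dtype=np.float32)
    if dark is None:
        dark = np.zeros(det_shape, dtype=np.float32)
    raw = dark[None] + (flat - dark)[None] * proj
    if noise_sigma:
        raw = raw + rng.normal(0.0, noise_sigma, size=raw.shape).astype(np.float32)
    span = 180.0 if geometry == "standard_180" else 360.0
    meta = {
        "geometry": geometry,
        "axis_offset": float(offset),
        "angles_deg": np.linspace(0.0, span, n_angles, endpoint=False),
    }
    return VolumeImage(raw.astype(np.float32), volume.pixel_size, meta), flat, dark
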