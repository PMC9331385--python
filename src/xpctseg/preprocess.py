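"""Projection preprocessing: flat/dark correction, single-distance phase
retrieval, and 2x2 binning.

The phase-retrieval step is the linearised transport-of-intensity inversion
for a single propagation distance: in Fourier space the relative intensity
modulation (I/I0 − 1) is divided by (kx² + ky² + α), where α regularises the
zero-frequency divergence and trades fringe suppression against blurring.
The physical scale factor 2/(Dλ) is applied as a scalar prefactor; only the
filter shape matters to the downstream segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: hc in nm·keV: λ[m] = 1.2398e-9 / E[keV]
_HC_NM_KEV = 1.2398


@dataclass(frozen=True)
class PhaseRetrievalParams:
    """Physical constants of the retrieval filter.

    Give either ``energy_keV`` or ``wavelength_m`` (the other is derived).
    ``alpha`` is the dimensionless zero-frequency regulariser of the filter
    1/(kx² + ky² + α) with kx, ky in rad/µm; ``distance_m`` the
    sample–detector distance; ``pixel_size_um`` the detector pixel pitch.
    """

    energy_keV: float | None = None
    wavelength_m: float | None = None
    distance_m: float = 0.50
    alpha: float = 1e-2
    pixel_size_um: float = 1.28

    def __post_init__(self):
        if self.energy_keV is not None and self.wavelength_m is not None:
            raise ValueError("give exactly one of energy_keV / wavelength_m")
        if self.energy_keV is None and self.wavelength_m is None:
            object.__setattr__(self, "energy_keV", 25.0)
        if self.wavelength_m is None:
            if self.energy_keV <= 0:
                raise ValueError("energy must be positive")
            object.__setattr__(self, "wavelength_m",
                               _HC_NM_KEV * 1e-9 / self.energy_keV)
        elif self.energy_keV is None:
            object.__setattr__(self, "energy_keV",
                               _HC_NM_KEV * 1e-9 / self.wavelength_m)
        if self.distance_m <= 0:
            raise ValueError("distance must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def prefactor(self) -> float:
        """Scalar 2/(Dλ) applied after the Fourier filter."""
        return 2.0 / (self.distance_m * self.wavelength_m)


@dataclass
class CorrectedProjection:
    """Flat/dark-corrected transmission image I/I0."""

    data: np.ndarray
    flat_corrected: bool = True
    dark_corrected: bool = True


def flat_dark_correct(raw: np.ndarray, flat: np.ndarray,
                      dark: np.ndarray, eps: float = 1e-6) -> CorrectedProjection:
    """Normalise a raw frame: (raw − dark) / (flat − dark).

    The denominator is clamped below at ``eps``; pixels where flat ≤ dark
    are clamped with a logged warning rather than raising.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.shape != np.shape(flat) or raw.shape != np.shape(dark):
        raise ValueError("raw, flat and dark must share one shape")
    denom = np.asarray(flat, dtype=np.float64) - np.asarray(dark, dtype=np.float64)
    n_bad = int(np.count_nonzero(denom < eps))
    if n_bad:
        log.warning("flat-dark difference non-positive at %d pixels; clamped", n_bad)
        denom = np.maximum(denom, eps)
    return CorrectedProjection((raw - dark) / denom)


def phase_retrieve(proj: CorrectedProjection | np.ndarray,
                   params: PhaseRetrievalParams,
                   apply_prefactor: bool = True) -> np.ndarray:
    """Single-distance regularised TIE phase retrieval of one projection.

    Computes ``prefactor · F⁻¹[ F(I/I0 − 1) / (kx² + ky² + α) ]`` with the
    frequency grid in angular units 2π·fftfreq/pixel_size. Odd-sized inputs
    are reflect-padded to even size for the FFT and cropped back, which
    avoids wrap-around fringe artefacts at the boundary.
    """
    data = proj.data if isinstance(proj, CorrectedProjection) else np.asarray(proj)
    g = data.astype(np.float64) - 1.0
    h, w = g.shape
    ph, pw = h % 2, w % 2
    if ph or pw:
        g = np.pad(g, ((0, ph), (0, pw)), mode="reflect")
    ky = 2 * np.pi * np.fft.fftfreq(g.shape[0]) / params.pixel_size_um
    kx = 2 * np.pi * np.fft.fftfreq(g.shape[1]) / params.pixel_size_um
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    if params.alpha == 0:
        if abs(g.mean()) > 1e-12:
            raise ValueError("alpha=0 with non-zero mean input: the "
                             "zero-frequency regulariser alpha must be > 0")
        denom = k2.copy()
        denom[0, 0] = np.inf  # no DC content: define the DC gain as zero
    else:
        denom = k2 + params.alpha
    t = np.fft.ifft2(np.fft.fft2(g) / denom).real
    t = t[:h, :w]
    if apply_prefactor:
        t = t * params.prefactor
    return t


def bin2x2(image: np.ndarray) -> np.ndarray:
    """Mean-pool 2x2 blocks (signal-to-noise binning); odd trailing
    row/column dropped. Doubles the effective pixel size."""
    image = np.asarray(image)
    h, w = image.shape[-2:]
    h2, w2 = h // 2 * 2, w // 2 * 2
    trimmed = image[..., :h2, :w2].astype(np.float64)
    return trimmed.reshape(*image.shape[:-2], h2 // 2, 2, w2 // 2, 2).mean(axis=(-3, -1))


def bin2x2_volume(volume):
    """Slice-wise 2x2 binning of a VolumeImage; pixel size doubles
    (e.g. 1.28 µm → 2.56 ≈ 2.6 µm)."""
    from .phantom import VolumeImage

    return VolumeImage(bin2x2(volume.data).astype(np.float32),
                       2.0 * volume.pixel_size, dict(volume.meta))
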