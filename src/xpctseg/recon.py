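"""Tomographic reconstruction: half-acquisition stitching and filtered
back projection (parallel-beam).

In half-acquisition (extended field-of-view) mode the rotation axis is
offset from the detector centre and the scan covers 360°; each pair of
views 180° apart sees complementary halves of the object. Stitching mirrors
the opposing view and blends the overlap around the axis, producing a 180°
sinogram of roughly double width with the axis centred, which standard FBP
then reconstructs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon

from .phantom import VolumeImage

log = logging.getLogger(__name__)

FBP_FILTERS = {"ramp", "shepp-logan", "hann"}


@dataclass
class Sinogram:
    """(angles × detector) line-integral data for one slice.

    ``angles`` in radians, strictly increasing and equispaced;
    ``axis_offset`` is the rotation-axis position in pixels from the
    detector centre (at (W−1)/2).
    """

    data: np.ndarray
    angles: np.ndarray
    axis_offset: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.angles):
            raise ValueError("data must be (n_angles, detector) matching angles")
        if len(self.angles) < 1:
            raise ValueError("need at least one angle")
        if len(self.angles) > 1 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")


def half_acq_to_extended(sino360: Sinogram) -> Sinogram:
    """Stitch a 360° offset-axis sinogram into a 180° extended one.

    Opposing rows are detector-mirrored about the axis and composed on a
    common grid; where both views cover a column the values are blended
    with weights ramping down toward each view's own detector edge. The
    output axis is centred (axis_offset 0). Requires an even number of
    equispaced angles spanning 360° and 2·axis_offset integral (axis on
    the half-pixel grid).
    """
    n2, w = sino360.data.shape
    if n2 % 2:
        raise ValueError("360° sinogram must contain an even number of angles "
                         "(each view needs its 180° pair)")
    span = sino360.angles[-1] - sino360.angles[0]
    if not np.isclose(span, 2 * np.pi * (n2 - 1) / n2, rtol=1e-3):
        raise ValueError("angles must span 360° equispaced")
    o = sino360.axis_offset
    if abs(o) >= w:
        raise ValueError("axis offset must be smaller than the detector width")
    a = (w - 1) / 2.0 + o  # axis position in pixel coordinates
    if not np.isclose(2 * a, round(2 * a), atol=1e-9):
        raise ValueError("2*axis_offset must be integral")

    n = n2 // 2
    first, second = sino360.data[:n], sino360.data[n:]
    mirrored = second[:, ::-1]  # p(θ+180, s) = p(θ, −s)
    a2 = (w - 1) - a  # axis position within the mirrored rows

    m_ext = max(a, a2)
    w_ext = int(round(2 * m_ext)) + 1
    s = np.arange(w_ext) - m_ext  # signed distance from the axis

    u1 = s + a  # column of `first` sampling s
    u2 = s + a2  # column of `mirrored` sampling s
    i1 = np.rint(u1).astype(int)
    i2 = np.rint(u2).astype(int)
    ok1 = (np.abs(u1 - i1) < 1e-6) & (i1 >= 0) & (i1 < w)
    ok2 = (np.abs(u2 - i2) < 1e-6) & (i2 >= 0) & (i2 < w)
    # weight = distance to the view's own nearest detector edge (+½ so a
    # single-column overlap still has positive weight); ramps blend the seam
    w1 = np.where(ok1, np.minimum(u1, (w - 1) - u1) + 0.5, 0.0)
    w2 = np.where(ok2, np.minimum(u2, (w - 1) - u2) + 0.5, 0.0)
    total = w1 + w2
    if np.any(total == 0):
        raise ValueError("stitched grid has uncovered columns; check axis offset")

    out = np.zeros((n, w_ext), dtype=np.result_type(sino360.data, np.float32))
    out[:, ok1] += (w1[ok1] / total[ok1]) * first[:, i1[ok1]]
    out[:, ok2] += (w2[ok2] / total[ok2]) * mirrored[:, i2[ok2]]
    return Sinogram(out, sino360.angles[:n], axis_offset=0.0)


def fbp_reconstruct(sino: Sinogram, filter_name: str = "ramp",
                    output_size: int | None = None) -> np.ndarray:
    """Parallel-beam filtered back projection of a single sinogram.

    1D frequency filtering of each row followed by back-projection with
    linear interpolation; pixels outside the inscribed circle are zero.
    """
    if filter_name not in FBP_FILTERS:
        raise ValueError(f"unknown filter {filter_name!r}; options: "
                         f"{sorted(FBP_FILTERS)}")
    if len(sino.angles) < 2:
        raise ValueError("FBP needs at least 2 angles")
    if sino.axis_offset != 0:
        raise ValueError("FBP expects a centred rotation axis; stitch or "
                         "shift the sinogram first")
    theta = np.degrees(sino.angles)
    return iradon(sino.data.T, theta=theta, filter_name=filter_name,
                  interpolation="linear", circle=True,
                  output_size=output_size).astype(np.float32)


def reconstruct_volume(projections: VolumeImage, geometry: str | None = None,
                       filter_name: str = "ramp",
                       axis_offset: float | None = None,
                       output_size: int | None = None) -> VolumeImage:
    """Slice-wise reconstruction of a (angle, z, detector) projection stack.

    Applies half-acquisition stitching when the geometry (explicit or from
    the stack's metadata) is ``full_360_half_acquisition``, then FBP per
    slice.
    """
    geometry = geometry or projections.meta.get("geometry", "standard_180")
    if axis_offset is None:
        axis_offset = projections.meta.get("axis_offset", 0.0)
    angles_deg = projections.meta.get("angles_deg")
    n_angles, nz, _ = projections.data.shape
    if angles_deg is None:
        span = 360.0 if geometry == "full_360_half_acquisition" else 180.0
        angles_deg = np.linspace(0.0, span, n_angles, endpoint=False)
    angles = np.radians(angles_deg)

    slices = []
    for z in range(nz):
        sino = Sinogram(projections.data[:, z, :], angles, axis_offset=axis_offset)
        if geometry == "full_360_half_acquisition":
            sino = half_acq_to_extended(sino)
        slices.append(fbp_reconstruct(sino, filter_name, output_size=output_size))
        if z % 16 == 15 or z == nz - 1:
            log.info("reconstructed slice %d/%d", z + 1, nz)
    return VolumeImage(np.stack(slices), projections.pixel_size)
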