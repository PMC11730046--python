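"""Sliding-slab minimum-intensity projection and lung-window display.

MinIP assigns each output voxel the minimum attenuation inside a slab
centred on it along a viewing axis, which accentuates air-filled and
emphysematous structures. The lung-window transform maps an HU interval
(width 1500, level -500) linearly to display gray levels. The display
enhancements (unsharp-mask edge sharpening, symmetric contrast stretch)
mimic workstation rendering and are for ROI-placement guidance only:
they never feed HU measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .phantom import CTVolume

AXIS_NAMES = {"axial": 0, "z": 0, "coronal": 1, "y": 1, "sagittal": 2, "x": 2}


@dataclass
class SlabImage:
    """A slab projection on the same grid as its source volume."""

    voxels: np.ndarray
    slab_thickness: float   # mm
    projection_axis: int
    kind: str               # "minip" or "source"


@dataclass
class DisplayImage:
    """Windowed (and optionally enhanced) intensities in [0, 1]."""

    pixels: np.ndarray
    window_width: float
    window_level: float
    sharpen_amount: float = 0.0
    contrast_amount: float = 0.0


def _resolve_axis(axis) -> int:
    if isinstance(axis, str):
        try:
            return AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValidationError(f"unknown projection axis {axis!r}") from None
    return int(axis)


def minip_slab(volume: CTVolume | np.ndarray, slab_thickness: float = 10.0,
               axis="axial", spacing_mm: float | None = None) -> SlabImage:
    """Sliding-slab MinIP with a centred window, truncated at the edges.

    The window along ``axis`` spans ``n = round(thickness / spacing)`` voxels,
    covering ``floor(n/2)`` voxels below the centre and ``n - 1 - floor(n/2)``
    above; at the volume boundary the window simply shrinks (no padding
    value), so boundary voxels use smaller support.
    """
    ax = _resolve_axis(axis)
    if isinstance(volume, CTVolume):
        vox, step = volume.voxels, volume.spacing[ax]
    else:
        vox = np.asarray(volume, dtype=float)
        step = 1.0 if spacing_mm is None else spacing_mm
    n = int(round(slab_thickness / step))
    if n < 1:
        raise ValidationError(
            f"slab thickness {slab_thickness} mm is thinner than one voxel ({step} mm)")
    # mode="nearest" replicates the edge voxel, which is already inside every
    # truncated window, so the result equals the truncated-window minimum
    out = ndimage.minimum_filter1d(vox, size=n, axis=ax, mode="nearest")
    return SlabImage(voxels=out, slab_thickness=float(slab_thickness),
                     projection_axis=ax, kind="minip")


def window_lung(volume_or_slab, width: float = 1500.0, level: float = -500.0) -> DisplayImage:
    """Linear HU-to-display map: [level - w/2, level + w/2] -> [0, 1], clipped."""
    if width <= 0:
        raise ValidationError("window width must be positive")
    if isinstance(volume_or_slab, (CTVolume, SlabImage)):
        hu = volume_or_slab.voxels
    else:
        hu = np.asarray(volume_or_slab, dtype=float)
    lo = level - width / 2.0
    pixels = np.clip((hu - lo) / width, 0.0, 1.0)
    return DisplayImage(pixels=pixels, window_width=float(width), window_level=float(level))


def enhance(image: DisplayImage, sharpen_amount: float = 0.35,
            contrast_amount: float = 0.20, sharpen_radius: float = 1.0) -> DisplayImage:
    """Unsharp masking followed by a symmetric linear contrast stretch.

    ``sharpen_amount`` scales the high-pass residual of a Gaussian blur with
    ``sharpen_radius`` voxels; ``contrast_amount`` expands the intensity range
    symmetrically about its midpoint by that fraction (a constant image is
    unchanged). Output clipped to [0, 1]. Guidance only.
    """
    if not (0.0 <= sharpen_amount <= 1.0 and 0.0 <= contrast_amount <= 1.0):
        raise ValidationError("enhancement amounts must lie in [0, 1]")
    p = image.pixels
    if sharpen_amount > 0:
        p = p + sharpen_amount * (p - ndimage.gaussian_filter(p, sharpen_radius))
    mid = (p.min() + p.max()) / 2.0     # stretch about the image's own range
    p = mid + (1.0 + contrast_amount) * (p - mid)
    return DisplayImage(pixels=np.clip(p, 0.0, 1.0),
                        window_width=image.window_width,
                        window_level=image.window_level,
                        sharpen_amount=float(sharpen_amount),
                        contrast_amount=float(contrast_amount))
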