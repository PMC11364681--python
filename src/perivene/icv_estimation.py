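"""Intracranial-volume estimation.

This is a documented surrogate for running an external brain-extraction tool:
intensity threshold (fixed value or Otsu over nonzero voxels), largest
26-connected component, morphological closing with an anisotropy-aware ball,
and interior hole filling.  The mask is exposed for visual QC; there is no
automatic QC gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image_io import BinaryMask, ImageVolume, mask_volume_mm3

__all__ = ["IcvResult", "estimate_icv"]

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class IcvResult:
    icv_mm3: float
    icv_cm3: float
    mask: BinaryMask
    threshold_used: float
    threshold_mode: str
    closing_radius_mm: float


def _ball_structure(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Binary ellipsoidal structuring element spanning ``radius_mm`` in
    physical units on an anisotropic grid."""
    nr = [max(1, int(np.ceil(radius_mm / s))) for s in spacing]
    ax = [np.arange(-n, n + 1) * s for n, s in zip(nr, spacing)]
    d2 = (
        ax[0][:, None, None] ** 2
        + ax[1][None, :, None] ** 2
        + ax[2][None, None, :] ** 2
    )
    return d2 <= radius_mm**2


def estimate_icv(
    image: ImageVolume,
    threshold: float | str = "otsu",
    closing_radius_mm: float = 4.0,
) -> IcvResult:
    """Estimate intracranial volume from a head image.

    ``threshold`` is either a fixed intensity value or ``"otsu"`` (computed
    over nonzero voxels).  Deterministic.  Raises on an all-constant image or
    an empty post-threshold mask.
    """
    data = image.data
    if np.ptp(data) == 0:
        raise ValueError("image has zero intensity range")
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError("threshold must be a number or 'otsu'")
        nz = data[data != 0]
        if nz.size == 0 or np.ptp(nz) == 0:
            raise ValueError("cannot compute Otsu threshold: no intensity spread")
        thr = float(threshold_otsu(nz))
        mode = "otsu"
    else:
        thr = float(threshold)
        mode = "fixed"

    binary = data > thr
    if not binary.any():
        raise ValueError(f"no voxels above threshold {thr}")

    labels, n = ndimage.label(binary, structure=_STRUCT_3D)
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    largest = labels == (int(np.argmax(sizes)) + 1)

    if closing_radius_mm > 0:
        struct = _ball_structure(closing_radius_mm, image.spacing)
        pad = [s // 2 for s in struct.shape]
        padded = np.pad(largest, [(p, p) for p in pad])
        closed = ndimage.binary_closing(padded, structure=struct)
        largest = closed[pad[0] : -pad[0] or None, pad[1] : -pad[1] or None, pad[2] : -pad[2] or None]
    filled = ndimage.binary_fill_holes(largest)

    mask = BinaryMask(filled, image.spacing, image.affine.copy())
    mm3 = mask_volume_mm3(mask)
    return IcvResult(
        icv_mm3=mm3,
        icv_cm3=mm3 / 1000.0,
        mask=mask,
        threshold_used=thr,
        threshold_mode=mode,
        closing_radius_mm=float(closing_radius_mm),
    )
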