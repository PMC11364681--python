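"""Volumetry of the parasagittal dura within a band around the sinus.

High-signal voxels are kept only inside a 3D Euclidean band (default 10 mm)
measured from the outer edge of the superior sagittal sinus, on slices
strictly above the ventricle plane, after subtracting caller-supplied brain
and skull masks (the reproducible stand-in for the manual clean-up step).
No minimum-diameter filter is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask, ImageVolume, mask_volume_mm3
from .perivenous_segmentation import VolumeResult, restrict_above_plane, threshold_mask

__all__ = ["PSDSegConfig", "sss_band", "measure_psd_volume"]

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PSDSegConfig:
    intensity_threshold: float
    z_min: int
    band_width_mm: float = 10.0
    brain_mask: BinaryMask | None = None
    skull_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensity_threshold):
            raise ValueError("intensity threshold must be finite")
        if self.band_width_mm <= 0:
            raise ValueError("band_width_mm must be > 0")


def sss_band(sss_mask: BinaryMask, band_width_mm: float = 10.0) -> BinaryMask:
    """Voxels outside the sinus whose 3D Euclidean distance (physical units)
    to the sinus is at most ``band_width_mm``; sinus voxels themselves are 0."""
    if band_width_mm <= 0:
        raise ValueError("band_width_mm must be > 0")
    sss = sss_mask.as_bool()
    if not sss.any():
        raise ValueError("sss_mask is empty")
    dist = ndimage.distance_transform_edt(~sss, sampling=sss_mask.spacing)
    return sss_mask.like((dist <= band_width_mm) & ~sss)


def measure_psd_volume(
    image: ImageVolume, sss_mask: BinaryMask, config: PSDSegConfig
) -> VolumeResult:
    """Parasagittal-dura measurement chain.

    threshold -> intersect with the sinus band -> restrict to slices above
    the ventricle plane -> subtract brain and skull masks -> volume.
    """
    sss_mask.check_aligned(image)
    m = threshold_mask(image, config.intensity_threshold)
    band = sss_band(sss_mask, config.band_width_mm)
    m = m.like(m.as_bool() & band.as_bool())
    m = restrict_above_plane(m, config.z_min)

    # component bookkeeping: label before the mask subtraction, count
    # original components that keep at least one voxel afterwards
    labels, n_total = ndimage.label(m.as_bool(), structure=_STRUCT_3D)
    final = m.as_bool()
    for name in ("brain_mask", "skull_mask"):
        sub = getattr(config, name)
        if sub is not None:
            sub.check_aligned(image)
            final &= ~sub.as_bool()
    surviving = np.unique(labels[final])
    n_kept = int(np.count_nonzero(surviving))
    out = m.like(final)
    return VolumeResult(
        volume_mm3=mask_volume_mm3(out),
        mask=out,
        n_components_total=int(n_total),
        n_components_retained=n_kept,
        n_components_removed={"mask_subtraction": int(n_total - n_kept)},
        config={
            "intensity_threshold": config.intensity_threshold,
            "z_min": config.z_min,
            "band_width_mm": config.band_width_mm,
            "brain_mask": config.brain_mask is not None,
            "skull_mask": config.skull_mask is not None,
        },
    )
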