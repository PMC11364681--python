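"""Volumetry of the contrast-enhanced space around the diploic veins.

The measurement chain is: intensity threshold, subtraction of
operator-supplied exclusion masks (e.g. reticular intradiploic enhancement),
restriction to transverse slices strictly above the superior border of the
lateral ventricles, and removal of in-plane components whose maximum
inscribed-disc diameter falls below 2 mm.  Every stage only ever removes
voxels, so the measured volume is monotone non-increasing along the chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image_io import BinaryMask, ImageVolume, mask_volume_mm3

__all__ = [
    "DVSegConfig",
    "VolumeResult",
    "threshold_mask",
    "restrict_above_plane",
    "filter_by_inplane_diameter",
    "measure_dv_volume",
    "suggest_threshold_otsu",
]

_STRUCT_2D = np.ones((3, 3), dtype=bool)       # 8-connected in-plane
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)    # 26-connected


@dataclass
class DVSegConfig:
    """Configuration for the diploic perivenous-space measurement.

    ``intensity_threshold`` is the operator's predetermined signal cutoff
    (required; never inferred silently).  ``z_min`` is the axial index of the
    superior border of the lateral ventricles; only slices strictly above it
    are measured.  Components with in-plane inscribed-disc diameter below
    ``min_diameter_mm`` are discarded (inclusive at the threshold).
    """

    intensity_threshold: float
    z_min: int
    min_diameter_mm: float = 2.0
    exclusion_masks: list[BinaryMask] = field(default_factory=list)
    diameter_mode: str = "2d"  # "2d" (default, per transverse slice) or "3d"

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensity_threshold):
            raise ValueError("intensity threshold must be finite")
        if self.min_diameter_mm <= 0:
            raise ValueError("min_diameter_mm must be > 0")
        if self.diameter_mode not in ("2d", "3d"):
            raise ValueError("diameter_mode must be '2d' or '3d'")


@dataclass
class VolumeResult:
    """A measured volume with its final mask and component bookkeeping."""

    volume_mm3: float
    mask: BinaryMask
    n_components_total: int
    n_components_retained: int
    n_components_removed: dict[str, int]
    config: dict

    def __post_init__(self) -> None:
        removed = sum(self.n_components_removed.values())
        if self.n_components_retained + removed != self.n_components_total:
            raise ValueError("component bookkeeping inconsistent")

    def to_dict(self) -> dict:
        return {
            "volume_mm3": self.volume_mm3,
            "n_components_total": self.n_components_total,
            "n_components_retained": self.n_components_retained,
            "n_components_removed": dict(self.n_components_removed),
            "config": self.config,
        }


def threshold_mask(image: ImageVolume, threshold: float) -> BinaryMask:
    """Voxels with intensity strictly above ``threshold``."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return BinaryMask(image.data > threshold, image.spacing, image.affine.copy())


def restrict_above_plane(mask: BinaryMask, z_min: int) -> BinaryMask:
    """Keep voxels with axial index strictly greater than ``z_min``."""
    nz = mask.shape[2]
    if not -1 <= z_min < nz:
        raise ValueError(f"z_min={z_min} outside grid with {nz} slices")
    out = mask.data.copy()
    out[:, :, : z_min + 1] = 0
    return mask.like(out)


def _component_max_inscribed_diameters(
    mask2d: np.ndarray, sampling: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Label an 8-connected 2D mask and return, per label, twice the maximum
    of the in-plane (anisotropy-aware) Euclidean distance transform."""
    labels, n = ndimage.label(mask2d, structure=_STRUCT_2D)
    if n == 0:
        return labels, np.empty(0)
    edt = ndimage.distance_transform_edt(mask2d, sampling=sampling)
    max_r = ndimage.maximum(edt, labels=labels, index=np.arange(1, n + 1))
    return labels, 2.0 * np.atleast_1d(max_r)


def filter_by_inplane_diameter(
    mask: BinaryMask,
    min_diameter_mm: float = 2.0,
    mode: str = "2d",
    _counts: list | None = None,
) -> BinaryMask:
    """Drop components whose maximum inscribed-disc diameter is below
    ``min_diameter_mm``; retention is inclusive at exactly the threshold.

    In the default ``"2d"`` mode the diameter is evaluated per transverse
    slice on 8-connected components with the in-plane spacing; ``"3d"``
    evaluates 26-connected components against the full anisotropic EDT.
    """
    if min_diameter_mm <= 0:
        raise ValueError("min_diameter_mm must be > 0")
    data = mask.as_bool()
    tol = 1e-9
    kept = np.zeros_like(data)
    n_total = n_kept = 0
    if mode == "2d":
        sampling = mask.spacing[:2]
        for z in range(data.shape[2]):
            sl = data[:, :, z]
            if not sl.any():
                continue
            labels, diam = _component_max_inscribed_diameters(sl, sampling)
            ok = diam >= min_diameter_mm - tol
            n_total += diam.size
            n_kept += int(ok.sum())
            if ok.any():
                keep_ids = np.flatnonzero(ok) + 1
                kept[:, :, z] = np.isin(labels, keep_ids) & sl
    elif mode == "3d":
        labels, n = ndimage.label(data, structure=_STRUCT_3D)
        if n:
            edt = ndimage.distance_transform_edt(data, sampling=mask.spacing)
            max_r = np.atleast_1d(
                ndimage.maximum(edt, labels=labels, index=np.arange(1, n + 1))
            )
            diam = 2.0 * max_r
            ok = diam >= min_diameter_mm - tol
            n_total, n_kept = n, int(ok.sum())
            kept = np.isin(labels, np.flatnonzero(ok) + 1) & data
    else:
        raise ValueError("mode must be '2d' or '3d'")
    if _counts is not None:
        _counts[:] = [n_total, n_kept]
    return mask.like(kept)


def suggest_threshold_otsu(image: ImageVolume, compartment: BinaryMask) -> float:
    """Otsu threshold over the intensities of one compartment (e.g. the
    diploe).  A helper for choosing the predetermined cutoff; never applied
    implicitly by the measurement chain."""
    compartment.check_aligned(image)
    vals = image.data[compartment.as_bool()]
    if vals.size == 0:
        raise ValueError("compartment mask is empty")
    if np.ptp(vals) == 0:
        raise ValueError("compartment intensities are constant")
    return float(threshold_otsu(vals))


def measure_dv_volume(image: ImageVolume, config: DVSegConfig) -> VolumeResult:
    """Full diploic perivenous-space measurement chain.

    threshold -> subtract exclusion masks -> restrict to slices above the
    ventricle plane -> in-plane diameter filter -> volume.
    """
    m = threshold_mask(image, config.intensity_threshold)
    for excl in config.exclusion_masks:
        excl.check_aligned(m)
        m = m.like(m.as_bool() & ~excl.as_bool())
    m = restrict_above_plane(m, config.z_min)
    counts: list = []
    m = filter_by_inplane_diameter(
        m, config.min_diameter_mm, mode=config.diameter_mode, _counts=counts
    )
    n_total, n_kept = (counts or [0, 0])
    return VolumeResult(
        volume_mm3=mask_volume_mm3(m),
        mask=m,
        n_components_total=int(n_total),
        n_components_retained=int(n_kept),
        n_components_removed={"diameter_filter": int(n_total - n_kept)},
        config={
            "intensity_threshold": config.intensity_threshold,
            "z_min": config.z_min,
            "min_diameter_mm": config.min_diameter_mm,
            "n_exclusion_masks": len(config.exclusion_masks),
            "diameter_mode": config.diameter_mode,
        },
    )
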