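"""NIfTI image/mask containers and physical-volume bookkeeping.

Conventions
-----------
Volumes are 3D grids whose third axis is the transverse (axial) stack
direction, with the index increasing toward the vertex.  Files in other
orientations are reoriented to the closest RAS-canonical frame on load.
Voxel spacing is carried in millimetres; physical volumes are reported in
mm^3 (and cm^3 where noted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "read_nifti",
    "read_mask",
    "write_nifti",
    "mask_volume_mm3",
]


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    """Voxel spacing from the Euclidean norms of the affine's spatial columns."""
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with voxel spacing and voxel-to-world affine.

    Parameters
    ----------
    data :
        3D array of finite intensities (arbitrary signal units).
    spacing :
        ``(dx, dy, dz)`` voxel edge lengths in mm; all positive and finite.
    affine :
        4x4 invertible voxel-to-world transform in mm.  If omitted, a
        diagonal affine built from ``spacing`` is used.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity grid contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite mm values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class BinaryMask:
    """A {0,1} label grid aligned voxel-for-voxel with a paired :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={arr.ndim}")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        else:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
            arr = arr.astype(np.uint8)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.spacing
        ):
            raise ValueError(f"spacing must be three positive finite mm values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def like(self, data: np.ndarray) -> "BinaryMask":
        """A new mask with this mask's geometry and the given voxel data."""
        return BinaryMask(data=data, spacing=self.spacing, affine=self.affine.copy())

    def check_aligned(self, other: "ImageVolume | BinaryMask") -> None:
        if self.shape != other.shape:
            raise ValueError(f"shape mismatch: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"spacing mismatch: {self.spacing} vs {other.spacing}")


def read_nifti(path: str | Path) -> ImageVolume:
    """Load a 3D NIfTI-1 file, reoriented to the closest RAS-canonical frame.

    Spacing is derived from the affine column norms.  Raises
    ``FileNotFoundError`` for a missing path and ``ValueError`` for a
    non-3D payload.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got shape {data.shape}")
    affine = np.asarray(img.affine, dtype=float)
    return ImageVolume(data=data.astype(np.float64), spacing=_spacing_from_affine(affine), affine=affine)


def read_mask(path: str | Path) -> BinaryMask:
    """Load a NIfTI file as a binary mask; any nonzero voxel becomes 1."""
    vol = read_nifti(path)
    return BinaryMask(data=(vol.data != 0), spacing=vol.spacing, affine=vol.affine)


def write_nifti(volume: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1; masks are stored as unsigned 8-bit."""
    path = Path(path)
    if isinstance(volume, BinaryMask):
        data = volume.data.astype(np.uint8)
    elif isinstance(volume, ImageVolume):
        data = volume.data
    else:
        raise TypeError(f"cannot write object of type {type(volume)!r}")
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, str(path))
    except OSError as err:
        raise OSError(f"cannot write NIfTI to {path}: {err}") from err


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Physical volume of a mask: (number of 1-voxels) x dx x dy x dz."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3
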