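"""HU-valued voxel grids and their on-disk formats (MetaImage / NIfTI).

Conventions used throughout the package:

* ``values`` is indexed ``[i, j, k]`` along world axes ``(x, y, z)``.
* spacing is mm per axis; voxel *centre* of index ``(i,j,k)`` sits at
  ``origin + (index + 0.5) * spacing`` in a right-handed world frame.
* Masks share the exact grid (shape, spacing, origin) of their source image.

SimpleITK stores arrays ``[z, y, x]``; the readers/writers below transpose so
in-memory data always follows the package convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk


@dataclass
class VoxelImage:
    """3-D scalar volume (HU) with isotropic-friendly geometry metadata."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres for an (N,3) index array."""
        idx = np.asarray(indices, dtype=float)
        return self.origin + (idx + 0.5) * self.spacing

    def center_grid(self):
        """Per-axis 1-D arrays of voxel-centre world coordinates."""
        return [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        ]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world points."""
        p = np.asarray(points, dtype=float)
        return (p - self.origin) / self.spacing - 0.5


@dataclass
class Mask(VoxelImage):
    """Boolean volume geometrically aligned with its source image."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(bool)

    @staticmethod
    def like(image: VoxelImage, values: np.ndarray) -> "Mask":
        if values.shape != image.shape:
            raise ValueError("mask shape must match source image")
        return Mask(values, image.spacing.copy(), image.origin.copy())

    def count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self) -> float:
        return self.count() * self.voxel_volume()


def same_grid(a: VoxelImage, b: VoxelImage, tol: float = 1e-9) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


# ---------------------------------------------------------------------------
# I/O — MetaImage (.mha) and NIfTI (.nii / .nii.gz) via SimpleITK
# ---------------------------------------------------------------------------

def write_image(image: VoxelImage, path, dtype=np.int16) -> None:
    """Write as MetaImage or NIfTI (chosen by extension); HU as int16 by default."""
    arr = np.asarray(image.values)
    if dtype is not None:
        arr = np.clip(np.rint(arr), np.iinfo(dtype).min, np.iinfo(dtype).max).astype(dtype) \
            if np.issubdtype(dtype, np.integer) else arr.astype(dtype)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in image.spacing))
    img.SetOrigin(tuple(float(o) for o in image.origin))
    sitk.WriteImage(img, str(path))


def read_image(path) -> VoxelImage:
    img = sitk.ReadImage(str(Path(path)))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelImage(arr, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))


def write_mask(mask: Mask, path) -> None:
    write_image(VoxelImage(mask.values.astype(np.uint8), mask.spacing, mask.origin),
                path, dtype=np.uint8)


def read_mask(path) -> Mask:
    img = read_image(path)
    return Mask(img.values > 0, img.spacing, img.origin)
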