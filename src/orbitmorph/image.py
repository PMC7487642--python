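"""Voxel-grid containers and volume I/O.

Conventions
-----------
``VolumeImage.voxels`` is indexed ``[i, j, k]`` where axis ``i`` maps to
world x, ``j`` to y and ``k`` to z.  World coordinates are millimetres:
``world = origin + index * spacing`` (axis-aligned grids only, which is
all the phantoms and the cropped clinical exports use).  SimpleITK stores
arrays as ``[z, y, x]``; the I/O helpers transpose accordingly so that
NRRD/NIfTI files round-trip with correct spacing and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import EmptySegmentation

__all__ = [
    "VolumeImage",
    "SegmentationMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
]


@dataclass
class VolumeImage:
    """Axis-aligned scalar voxel grid with spacing/origin in mm."""

    voxels: np.ndarray
    spacing: np.ndarray  # mm per axis, shape (3,)
    origin: np.ndarray  # world mm of voxel (0, 0, 0) centre

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        if min(self.voxels.shape) < 8:
            raise ValueError("volume must be at least 8 voxels per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm."""
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pos: np.ndarray) -> np.ndarray:
        """Map world mm to fractional voxel indices."""
        return (np.asarray(pos, dtype=float) - self.origin) / self.spacing


@dataclass
class SegmentationMask:
    """Binary voxel set on the lattice of a :class:`VolumeImage`."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self) -> None:
        if not self.voxels.any():
            raise EmptySegmentation("segmentation mask is empty")

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def _to_sitk(voxels: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, np.array(img.GetSpacing()), np.array(img.GetOrigin())


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    """Write a volume as NRRD or NIfTI (by file extension)."""
    sitk.WriteImage(_to_sitk(vol.voxels.astype(np.float32), vol.spacing, vol.origin), str(path))


def read_volume(path: str | Path) -> VolumeImage:
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return VolumeImage(arr, spacing, origin)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(mask.voxels.astype(np.uint8), mask.spacing, mask.origin), str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return SegmentationMask(arr > 0, spacing, origin)
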