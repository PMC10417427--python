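"""Image and label carriers.

All volumes in this package are 3D arrays in ``(x, y, z)`` axis order with
``z`` the slice axis, paired with a physical voxel spacing in millimetres.
NIfTI I/O goes through nibabel with a diagonal affine built from the spacing,
so a write/read round-trip reproduces both the voxel array and the spacing
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "LabelVolume", "read_volume", "read_labels"]


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing!r}")
    return spacing


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical voxel spacing (mm), axes (x, y, z)."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("VolumeGrid values must be finite")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.values.copy(), self.spacing)

    def save(self, path) -> Path:
        return _save_nifti(self.values.astype(np.float32, copy=False), self.spacing, path)


@dataclass
class LabelVolume:
    """An integer label volume aligned voxel-for-voxel with a VolumeGrid.

    0 is background; positive labels are foreground objects.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.round(self.values)):
                raise ValueError("label values must be integers")
            self.values = self.values.astype(np.int32)
        if self.values.min() < 0:
            raise ValueError("label values must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def binary(self) -> np.ndarray:
        return self.values > 0

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.values.copy(), self.spacing)

    def save(self, path) -> Path:
        return _save_nifti(self.values.astype(np.int16, copy=False), self.spacing, path)


def _save_nifti(arr: np.ndarray, spacing, path) -> Path:
    path = Path(path)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return arr, spacing


def read_volume(path) -> VolumeGrid:
    arr, spacing = _load_nifti(path)
    return VolumeGrid(arr.astype(np.float32), spacing)


def read_labels(path) -> LabelVolume:
    arr, spacing = _load_nifti(path)
    return LabelVolume(np.rint(arr).astype(np.int32), spacing)


def check_aligned(a, b) -> None:
    """Raise if two grids differ in shape or spacing."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")
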