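"""Core grid types: intensity volumes and integer label maps on a shared lattice.

Volumes are plain 3D numpy arrays plus voxel spacing and a NIfTI affine.
The affine is RAS+ built from the spacing with the origin at voxel (0,0,0)
unless one is supplied (e.g. when loading from disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "LabelMap", "load_volume", "load_labelmap"]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3D intensity grid with voxel spacing (mm) and a NIfTI affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))
        return path


@dataclass
class LabelMap:
    """An integer label grid on the same lattice as an :class:`ImageVolume`.

    Value 0 is background; positive values identify structures.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise ValueError("label map values must be integers")
            self.data = rounded.astype(np.int32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.int16), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))
        return path


def _load(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def load_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI intensity volume."""
    data, spacing, affine = _load(path)
    return ImageVolume(data=data.astype(np.float64), spacing=spacing, affine=affine)


def load_labelmap(path: str | Path) -> LabelMap:
    """Read a NIfTI integer label map."""
    data, spacing, affine = _load(path)
    return LabelMap(data=data, spacing=spacing, affine=affine)
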