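"""Label-based ROI voxel extraction.

Pulls out the intensities and 0-based voxel coordinates of each labeled
structure from an intensity volume, preserving the volume's spacing. If
the label map lives on a different grid it is resampled to the volume's
grid with nearest-neighbor interpolation (labels stay integer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, MissingLabelError
from .volumes import ImageVolume, LabelMap

__all__ = ["ROIVoxelSet", "list_labels", "extract_roi_voxels", "roi_to_volume"]


@dataclass
class ROIVoxelSet:
    """All voxels of one labeled structure.

    ``coords`` are 0-based voxel indices (i, j, k) in the volume's native
    array order; physical positions follow from the NIfTI affine.
    """

    label: int
    intensities: np.ndarray  # (Np,)
    coords: np.ndarray  # (Np, 3) int
    spacing: tuple[float, float, float]
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 3)
        if len(self.intensities) != len(self.coords):
            raise ValueError("intensities and coords must have equal length")
        if len(self.intensities) == 0:
            raise ValueError("an ROI must contain at least one voxel")
        if (self.coords < 0).any() or (self.coords >= np.asarray(self.grid_shape)).any():
            raise GeometryError("ROI coordinates fall outside the volume grid")

    @property
    def n_voxels(self) -> int:
        return len(self.intensities)

    @property
    def mask_bbox(self) -> tuple[tuple[int, int], ...]:
        """Tight bounding box: per-axis (min, max) inclusive voxel indices."""
        lo = self.coords.min(axis=0)
        hi = self.coords.max(axis=0)
        return tuple((int(a), int(b)) for a, b in zip(lo, hi))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def bbox_arrays(self, pad: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """Intensity array and boolean mask cropped to the (padded) bbox."""
        lo = self.coords.min(axis=0) - pad
        shape = self.coords.max(axis=0) - lo + 1 + pad
        mask = np.zeros(tuple(shape), dtype=bool)
        arr = np.zeros(tuple(shape), dtype=float)
        idx = tuple((self.coords - lo).T)
        mask[idx] = True
        arr[idx] = self.intensities
        return arr, mask


def list_labels(labelmap: LabelMap) -> list[int]:
    """Distinct nonzero label values, ascending."""
    values = np.unique(labelmap.data)
    return [int(v) for v in values if v != 0]


def _resample_nearest(labelmap: LabelMap, volume: ImageVolume) -> np.ndarray:
    """Resample the label map onto the volume grid via the two affines."""
    try:
        # voxel(vol) -> world -> voxel(labelmap)
        transform = np.linalg.inv(labelmap.affine) @ volume.affine
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular affine
        raise GeometryError("label map affine is singular") from exc
    ii, jj, kk = np.indices(volume.shape)
    vox = np.stack([ii, jj, kk, np.ones_like(ii)]).reshape(4, -1)
    src = (transform @ vox)[:3]
    out = map_coordinates(labelmap.data, src, order=0, mode="constant", cval=0)
    return out.reshape(volume.shape).astype(labelmap.data.dtype)


def extract_roi_voxels(
    volume: ImageVolume, labelmap: LabelMap, label: int
) -> ROIVoxelSet:
    """Extract exactly the voxels where ``labelmap == label``.

    Spacing is copied from the volume. Raises :class:`MissingLabelError`
    if the label does not occur, :class:`GeometryError` if the grids
    cannot be reconciled.
    """
    if labelmap.shape == volume.shape:
        label_data = labelmap.data
    else:
        label_data = _resample_nearest(labelmap, volume)
        if label_data.shape != volume.shape:  # pragma: no cover - defensive
            raise GeometryError("label map could not be resampled to the volume grid")

    mask = label_data == label
    if not mask.any():
        raise MissingLabelError(f"label {label} not present in the label map")
    coords = np.argwhere(mask)
    return ROIVoxelSet(
        label=int(label),
        intensities=volume.data[mask],
        coords=coords,
        spacing=volume.spacing,
        grid_shape=volume.shape,
    )


def roi_to_volume(roi: ROIVoxelSet) -> ImageVolume:
    """Write the ROI back into an empty grid (background 0)."""
    data = np.zeros(roi.grid_shape, dtype=float)
    data[tuple(roi.coords.T)] = roi.intensities
    return ImageVolume(data=data, spacing=roi.spacing)
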