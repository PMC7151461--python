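"""Gray-level discretization: equal-width bins over the ROI's own range."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..roi import ROIVoxelSet
from .config import EngineConfig

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Integer gray levels 1..ng per ROI voxel plus the level histogram."""

    gray_levels: np.ndarray  # (Np,) int, values in 1..ng
    ng: int  # number of discrete levels (1 for a constant ROI)
    histogram_p: np.ndarray  # (ng,) probabilities, sums to 1
    source: ROIVoxelSet

    def __post_init__(self) -> None:
        if self.gray_levels.min() < 1 or self.gray_levels.max() > self.ng:
            raise ValueError("gray levels must lie in 1..ng")
        if abs(self.histogram_p.sum() - 1.0) > 1e-12:
            raise ValueError("histogram must sum to 1")

    def level_array(self, pad: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """Gray-level array on the padded bbox grid (0 outside the mask)."""
        lo = self.source.coords.min(axis=0) - pad
        shape = self.source.coords.max(axis=0) - lo + 1 + pad
        levels = np.zeros(tuple(shape), dtype=np.int32)
        idx = tuple((self.source.coords - lo).T)
        levels[idx] = self.gray_levels
        return levels, levels > 0


def discretize(roi: ROIVoxelSet, config: EngineConfig) -> DiscretizedROI:
    """Map intensities to levels 1..Ng with equal-width bins over [min, max].

    A constant ROI maps wholly to level 1 with an effective level count of 1.
    """
    x = roi.intensities
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        levels = np.ones(len(x), dtype=np.int32)
        return DiscretizedROI(
            gray_levels=levels, ng=1, histogram_p=np.array([1.0]), source=roi
        )
    ng = config.n_bins
    width = (hi - lo) / ng
    levels = np.floor((x - lo) / width).astype(np.int32) + 1
    np.clip(levels, 1, ng, out=levels)  # x == max falls in the top bin
    p = np.bincount(levels, minlength=ng + 1)[1:].astype(float)
    p /= p.sum()
    return DiscretizedROI(gray_levels=levels, ng=ng, histogram_p=p, source=roi)
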