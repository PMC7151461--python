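"""First-order statistical features (17)."""

from __future__ import annotations

import numpy as np

from ..roi import ROIVoxelSet
from .config import EngineConfig
from .discretize import discretize

__all__ = ["first_order_features"]


def first_order_features(roi: ROIVoxelSet, config: EngineConfig) -> dict[str, float]:
    """Compute the 17 first-order features of the manifest.

    Moment-based features (Skewness, Kurtosis, Variance) use population
    normalization; Entropy is computed on the discretized histogram with
    log2 and the configured epsilon. Degenerate (constant) ROIs yield
    Skewness = Kurtosis = 0.
    """
    x = roi.intensities
    c = config.energy_offset
    np_ = len(x)
    mean = float(x.mean())
    m2 = float(np.mean((x - mean) ** 2))
    m3 = float(np.mean((x - mean) ** 3))
    m4 = float(np.mean((x - mean) ** 4))

    energy = float(np.sum((x + c) ** 2))
    p10, p25, p50, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))

    d = discretize(roi, config)
    p = d.histogram_p
    entropy = float(-np.sum(p * np.log2(p + config.epsilon)))

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if len(robust) else 0.0

    return {
        "Energy": energy,
        "TotalEnergy": roi.voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Percentile10": p10,
        "Percentile90": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(energy / np_)),
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Variance": m2,
    }
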