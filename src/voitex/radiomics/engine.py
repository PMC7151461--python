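"""Feature extraction driver: one ROI in, 107 named values out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..roi import ROIVoxelSet
from . import manifest
from .config import EngineConfig
from .discretize import discretize
from .firstorder import first_order_features
from .shape import shape2d_features, shape3d_features
from .texture import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["FeatureRecord", "extract_all"]


@dataclass
class FeatureRecord:
    """All 107 features of one ROI, keyed by family-prefixed name."""

    roi_label: int
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = manifest.qualified_names()
        missing = set(expected) - set(self.values)
        extra = set(self.values) - set(expected)
        if missing or extra:
            raise ValueError(
                f"feature record must carry exactly the 107 manifest features "
                f"(missing={sorted(missing)[:3]}..., extra={sorted(extra)[:3]}...)"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad}")
        # canonical ordering
        self.values = {name: float(self.values[name]) for name in expected}

    def family_values(self, family: str) -> dict[str, float]:
        prefix = family + "_"
        return {k: v for k, v in self.values.items() if k.startswith(prefix)}


def extract_all(roi: ROIVoxelSet, config: EngineConfig | None = None) -> FeatureRecord:
    """Compute the full 107-feature set for one ROI voxel set."""
    config = config or EngineConfig()
    d = discretize(roi, config)

    families = {
        "firstorder": first_order_features(roi, config),
        "shape2d": shape2d_features(roi),
        "shape3d": shape3d_features(roi),
        "glcm": glcm_features(d, config),
        "glrlm": glrlm_features(d, config),
        "glszm": glszm_features(d, config),
        "ngtdm": ngtdm_features(d, config),
        "gldm": gldm_features(d, config),
    }
    values = {
        f"{fam}_{name}": vals[name]
        for fam, vals in families.items()
        for name in manifest.FAMILIES[fam]
    }
    return FeatureRecord(roi_label=roi.label, values=values)
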