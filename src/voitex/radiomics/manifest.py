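"""The 107-feature manifest: eight families with fixed cardinalities.

Family sizes are a hard contract: 17 first-order, 10 shape-2D, 10
shape-3D, 24 GLCM, 12 GLRLM, 12 GLSZM, 12 NGTDM, 10 GLDM = 107.

Members follow the standard radiomics (IBSI-style) definitions and
ordering, truncated or extended per family to hit the required counts:

* first-order: the 19-feature standard list minus StandardDeviation
  (redundant with Variance) and Uniformity -> 17.
* shape-3D: the standard list truncated to 10 (axis/diameter variants
  beyond LeastAxisLength dropped).
* GLRLM / GLSZM: standard 16-feature lists reduced to 12, always keeping
  the anchored features (GLN, GLV, RunEntropy, LRHGLE; SAHGLE).
* NGTDM: the standard 5 extended by 7 documented derivatives of the
  (p_i, s_i) tables.
* GLDM: standard list truncated to 10, keeping SDE and DN.

Feature names are prefixed with their family key, e.g.
``firstorder_Skewness``, ``glcm_Idm``.
"""

from __future__ import annotations

FAMILIES: dict[str, list[str]] = {
    "firstorder": [
        "Energy",
        "TotalEnergy",
        "Entropy",
        "Minimum",
        "Percentile10",
        "Percentile90",
        "Maximum",
        "Mean",
        "Median",
        "InterquartileRange",
        "Range",
        "MeanAbsoluteDeviation",
        "RobustMeanAbsoluteDeviation",
        "RootMeanSquared",
        "Skewness",
        "Kurtosis",
        "Variance",
    ],
    "shape2d": [
        "MeshSurface",
        "PixelSurface",
        "Perimeter",
        "PerimeterSurfaceRatio",
        "Sphericity",
        "SphericalDisproportion",
        "MaximumDiameter",
        "MajorAxisLength",
        "MinorAxisLength",
        "Elongation",
    ],
    "shape3d": [
        "MeshVolume",
        "VoxelVolume",
        "SurfaceArea",
        "SurfaceVolumeRatio",
        "Sphericity",
        "Maximum3DDiameter",
        "MajorAxisLength",
        "MinorAxisLength",
        "LeastAxisLength",
        "Elongation",
    ],
    "glcm": [
        "Autocorrelation",
        "ClusterProminence",
        "ClusterShade",
        "ClusterTendency",
        "Contrast",
        "Correlation",
        "DifferenceAverage",
        "DifferenceEntropy",
        "DifferenceVariance",
        "Id",
        "Idm",
        "Idmn",
        "Idn",
        "Imc1",
        "Imc2",
        "InverseVariance",
        "JointAverage",
        "JointEnergy",
        "JointEntropy",
        "MCC",
        "MaximumProbability",
        "SumAverage",
        "SumEntropy",
        "SumSquares",
    ],
    "glrlm": [
        "ShortRunEmphasis",
        "LongRunEmphasis",
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized",
        "RunPercentage",
        "GrayLevelVariance",
        "RunVariance",
        "RunEntropy",
        "HighGrayLevelRunEmphasis",
        "LongRunHighGrayLevelEmphasis",
    ],
    "glszm": [
        "SmallAreaEmphasis",
        "LargeAreaEmphasis",
        "GrayLevelNonUniformity",
        "GrayLevelNonUniformityNormalized",
        "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized",
        "ZonePercentage",
        "GrayLevelVariance",
        "ZoneVariance",
        "ZoneEntropy",
        "HighGrayLevelZoneEmphasis",
        "SmallAreaHighGrayLevelEmphasis",
    ],
    "ngtdm": [
        "Coarseness",
        "Contrast",
        "Busyness",
        "Complexity",
        "Strength",
        "TotalDifference",
        "MeanDifference",
        "DifferenceEntropy",
        "GrayLevelVariance",
        "GrayLevelEntropy",
        "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis",
    ],
    "gldm": [
        "SmallDependenceEmphasis",
        "LargeDependenceEmphasis",
        "GrayLevelNonUniformity",
        "DependenceNonUniformity",
        "DependenceNonUniformityNormalized",
        "GrayLevelVariance",
        "DependenceVariance",
        "DependenceEntropy",
        "LowGrayLevelEmphasis",
        "HighGrayLevelEmphasis",
    ],
}

#: Required family cardinalities.
FAMILY_COUNTS = {
    "firstorder": 17,
    "shape2d": 10,
    "shape3d": 10,
    "glcm": 24,
    "glrlm": 12,
    "glszm": 12,
    "ngtdm": 12,
    "gldm": 10,
}

TOTAL_FEATURES = 107


def qualified_names() -> list[str]:
    """All 107 feature names, family-prefixed, in canonical order."""
    return [f"{fam}_{name}" for fam, names in FAMILIES.items() for name in names]


def family_of(qualified: str) -> str:
    fam = qualified.split("_", 1)[0]
    if fam not in FAMILIES:
        raise KeyError(f"unknown feature family for {qualified!r}")
    return fam


def _check() -> None:
    for fam, names in FAMILIES.items():
        if len(names) != FAMILY_COUNTS[fam]:
            raise AssertionError(
                f"{fam}: manifest has {len(names)} features, requires {FAMILY_COUNTS[fam]}"
            )
        if len(set(names)) != len(names):
            raise AssertionError(f"{fam}: duplicate feature names")
    if sum(FAMILY_COUNTS.values()) != TOTAL_FEATURES:
        raise AssertionError("family counts do not total 107")


_check()
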