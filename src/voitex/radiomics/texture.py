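"""Texture features computed from the five matrix kinds.

GLCM and GLRLM features are computed per direction and then averaged
over the 13 lattice directions (features averaged, not matrices);
GLSZM, NGTDM and GLDM are direction-free.
"""

from __future__ import annotations

import numpy as np

from .config import EngineConfig
from .discretize import DiscretizedROI
from .matrices import (
    DIRECTIONS_13,
    TextureMatrix,
    glcm_matrix,
    gldm_matrix,
    glrlm_matrix,
    glszm_matrix,
    ngtdm_table,
)

__all__ = [
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
    "glcm_features_from_matrix",
    "glrlm_features_from_matrix",
    "glszm_features_from_matrix",
    "ngtdm_features_from_table",
    "gldm_features_from_matrix",
]


def _entropy(p: np.ndarray, eps: float) -> float:
    return float(-np.sum(p * np.log2(p + eps)))


def _average(per_direction: list[dict[str, float]]) -> dict[str, float]:
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


# ---------------------------------------------------------------- GLCM


def glcm_features_from_matrix(p: np.ndarray, eps: float) -> dict[str, float]:
    """The 24 GLCM features for one normalized symmetric co-occurrence matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    # marginals over i+j (2..2Ng) and |i-j| (0..Ng-1)
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, (ii + jj).ravel(), p.ravel())
    p_sum = p_sum[2:]
    ks = np.arange(2, 2 * ng + 1)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    kd = np.arange(ng)

    autocorr = float(np.sum(p * ii * jj))
    cluster = ii + jj - mu_x - mu_y
    diff_avg = float(np.sum(kd * p_diff))

    hxy = _entropy(p.ravel(), eps)
    pxpy = np.outer(px, py)
    hxy1 = float(-np.sum(p * np.log2(pxpy + eps)))
    hxy2 = float(-np.sum(pxpy * np.log2(pxpy + eps)))
    hx = _entropy(px, eps)
    hy = _entropy(py, eps)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    if sig_x > 0 and sig_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sig_x * sig_y)
    else:
        correlation = 1.0

    # MCC: second-largest eigenvalue of the transition-style matrix Q
    keep = px > 0
    if keep.sum() > 1:
        a = p[np.ix_(keep, keep)] / px[keep][:, None]
        b = p[np.ix_(keep, keep)] / py[keep][:, None]
        q = a @ b.T
        eig = np.sort(np.abs(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(0.0, min(1.0, eig[1]))))
    else:
        mcc = 1.0

    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum(cluster**4 * p)),
        "ClusterShade": float(np.sum(cluster**3 * p)),
        "ClusterTendency": float(np.sum(cluster**2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff, eps),
        "DifferenceVariance": float(np.sum((kd - diff_avg) ** 2 * p_diff)),
        "Id": float(np.sum(p_diff / (1.0 + kd))),
        "Idm": float(np.sum(p_diff / (1.0 + kd**2))),
        "Idmn": float(np.sum(p_diff / (1.0 + (kd / ng) ** 2))),
        "Idn": float(np.sum(p_diff / (1.0 + kd / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p_diff[1:] / kd[1:] ** 2)) if ng > 1 else 0.0,
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(ks * p_sum)),
        "SumEntropy": _entropy(p_sum, eps),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
    }


def glcm_features(d: DiscretizedROI, config: EngineConfig) -> dict[str, float]:
    per_dir = []
    for off in DIRECTIONS_13:
        tm = glcm_matrix(d, off, distance=config.glcm_distance)
        if tm is not None:
            per_dir.append(glcm_features_from_matrix(tm.matrix, config.epsilon))
    if not per_dir:
        # Np == 1: analytic limit of a single-cell matrix
        per_dir = [glcm_features_from_matrix(np.array([[1.0]]), config.epsilon)]
    return _average(per_dir)


# ---------------------------------------------------------------- GLRLM


def glrlm_features_from_matrix(
    matrix: np.ndarray, n_voxels: int, eps: float
) -> dict[str, float]:
    """The 12 GLRLM features for one direction's run-length matrix."""
    nr = matrix.sum()
    i = np.arange(1, matrix.shape[0] + 1)
    j = np.arange(1, matrix.shape[1] + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    row = matrix.sum(axis=1)
    col = matrix.sum(axis=0)
    p = matrix / nr
    mu_g = float(np.sum(p * ii))
    mu_r = float(np.sum(p * jj))

    return {
        "ShortRunEmphasis": float(np.sum(matrix / jj**2) / nr),
        "LongRunEmphasis": float(np.sum(matrix * jj**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(row**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / nr**2),
        "RunLengthNonUniformity": float(np.sum(col**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(col**2) / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_g) ** 2)),
        "RunVariance": float(np.sum(p * (jj - mu_r) ** 2)),
        "RunEntropy": _entropy(p.ravel(), eps),
        "HighGrayLevelRunEmphasis": float(np.sum(matrix * ii**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(matrix * ii**2 * jj**2) / nr),
    }


def glrlm_features(d: DiscretizedROI, config: EngineConfig) -> dict[str, float]:
    n_vox = d.source.n_voxels
    per_dir = [
        glrlm_features_from_matrix(glrlm_matrix(d, off).matrix, n_vox, config.epsilon)
        for off in DIRECTIONS_13
    ]
    return _average(per_dir)


# ---------------------------------------------------------------- GLSZM


def glszm_features_from_matrix(
    matrix: np.ndarray, n_voxels: int, eps: float
) -> dict[str, float]:
    """The 12 GLSZM features for the zone matrix."""
    nz = matrix.sum()
    i = np.arange(1, matrix.shape[0] + 1)
    j = np.arange(1, matrix.shape[1] + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    row = matrix.sum(axis=1)
    col = matrix.sum(axis=0)
    p = matrix / nz
    mu_g = float(np.sum(p * ii))
    mu_z = float(np.sum(p * jj))

    return {
        "SmallAreaEmphasis": float(np.sum(matrix / jj**2) / nz),
        "LargeAreaEmphasis": float(np.sum(matrix * jj**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / nz**2),
        "SizeZoneNonUniformity": float(np.sum(col**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_g) ** 2)),
        "ZoneVariance": float(np.sum(p * (jj - mu_z) ** 2)),
        "ZoneEntropy": _entropy(p.ravel(), eps),
        "HighGrayLevelZoneEmphasis": float(np.sum(matrix * ii**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(matrix * ii**2 / jj**2) / nz),
    }


def glszm_features(d: DiscretizedROI, config: EngineConfig) -> dict[str, float]:
    tm = glszm_matrix(d)
    return glszm_features_from_matrix(tm.matrix, d.source.n_voxels, config.epsilon)


# ---------------------------------------------------------------- NGTDM


def ngtdm_features_from_table(
    table: np.ndarray, config: EngineConfig
) -> dict[str, float]:
    """The 12 NGTDM features from the (p_i, s_i, n_i) table.

    Coarseness = 1 / sum(p_i s_i), capped when the denominator vanishes.
    """
    eps = config.epsilon
    p, s, n = table[:, 0], table[:, 1], table[:, 2]
    nvp = n.sum()
    i = np.arange(1, len(p) + 1, dtype=float)
    nz = p > 0
    ngp = int(nz.sum())

    ps = float(np.sum(p * s))
    coarseness = config.coarseness_cap if ps == 0 else float(1.0 / ps)

    if ngp > 1 and nvp > 0:
        iv, jv = np.meshgrid(i[nz], i[nz], indexing="ij")
        pi, pj = np.meshgrid(p[nz], p[nz], indexing="ij")
        si, sj = np.meshgrid(s[nz], s[nz], indexing="ij")
        contrast = float(
            np.sum(pi * pj * (iv - jv) ** 2) / (ngp * (ngp - 1)) * (s.sum() / nvp)
        )
        busy_den = float(np.sum(np.abs(iv * pi - jv * pj)))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(np.abs(iv - jv) * (pi * si + pj * sj) / (pi + pj)) / nvp
        )
        strength = float(np.sum((pi + pj) * (iv - jv) ** 2) / s.sum()) if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    s_total = s.sum()
    q = s / s_total if s_total > 0 else s
    mu = float(np.sum(p * i))
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
        "TotalDifference": float(s_total),
        "MeanDifference": ps,
        "DifferenceEntropy": _entropy(q, eps) if s_total > 0 else 0.0,
        "GrayLevelVariance": float(np.sum(p * (i - mu) ** 2)),
        "GrayLevelEntropy": _entropy(p[nz], eps) if ngp else 0.0,
        "LowGrayLevelEmphasis": float(np.sum(p / i**2)),
        "HighGrayLevelEmphasis": float(np.sum(p * i**2)),
    }


def ngtdm_features(d: DiscretizedROI, config: EngineConfig) -> dict[str, float]:
    return ngtdm_features_from_table(ngtdm_table(d).matrix, config)


# ---------------------------------------------------------------- GLDM


def gldm_features_from_matrix(matrix: np.ndarray, eps: float) -> dict[str, float]:
    """The 10 GLDM features; column j is dependence j-1."""
    nz = matrix.sum()
    i = np.arange(1, matrix.shape[0] + 1)
    j = np.arange(1, matrix.shape[1] + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    row = matrix.sum(axis=1)
    col = matrix.sum(axis=0)
    p = matrix / nz
    mu_g = float(np.sum(p * ii))
    mu_d = float(np.sum(p * jj))

    return {
        "SmallDependenceEmphasis": float(np.sum(matrix / jj**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(matrix * jj**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "DependenceNonUniformity": float(np.sum(col**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_g) ** 2)),
        "DependenceVariance": float(np.sum(p * (jj - mu_d) ** 2)),
        "DependenceEntropy": _entropy(p.ravel(), eps),
        "LowGrayLevelEmphasis": float(np.sum(matrix / ii**2) / nz),
        "HighGrayLevelEmphasis": float(np.sum(matrix * ii**2) / nz),
    }


def gldm_features(d: DiscretizedROI, config: EngineConfig) -> dict[str, float]:
    tm = gldm_matrix(d, alpha=config.gldm_alpha)
    return gldm_features_from_matrix(tm.matrix, config.epsilon)
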