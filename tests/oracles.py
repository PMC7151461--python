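"""Independent brute-force oracles for the texture engine tests.

Everything here is deliberately naive (double loops, BFS flood fill,
literal formula transcriptions) and shares no code with the package
implementation.
"""

from __future__ import annotations

import math

import numpy as np


def _in_bounds(p, shape) -> bool:
    return all(0 <= c < n for c, n in zip(p, shape))


def _neighbors26(p):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) != (0, 0, 0):
                    yield (p[0] + di, p[1] + dj, p[2] + dk)


def oracle_glcm_counts(levels: np.ndarray, offset, distance: int, ng: int) -> np.ndarray:
    """Symmetric co-occurrence counts by O(N^2)-style pair enumeration."""
    shape = levels.shape
    off = tuple(o * distance for o in offset)
    counts = np.zeros((ng, ng))
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        q = tuple(a + b for a, b in zip(p, off))
        if _in_bounds(q, shape) and levels[q] > 0:
            counts[levels[p] - 1, levels[q] - 1] += 1
            counts[levels[q] - 1, levels[p] - 1] += 1
    return counts


def oracle_glrlm(levels: np.ndarray, direction, ng: int) -> np.ndarray:
    """Run-length counts by explicit line scanning."""
    shape = levels.shape
    runs = []
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        prev = tuple(a - b for a, b in zip(p, direction))
        if _in_bounds(prev, shape) and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = tuple(a + b for a, b in zip(p, direction))
        while _in_bounds(q, shape) and levels[q] == levels[p]:
            length += 1
            q = tuple(a + b for a, b in zip(q, direction))
        runs.append((levels[p], length))
    max_len = max(length for _, length in runs)
    matrix = np.zeros((ng, max_len))
    for level, length in runs:
        matrix[level - 1, length - 1] += 1
    return matrix


def oracle_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Zone counts via BFS flood fill over 26-connected equal levels."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.ndindex(shape):
        if levels[start] == 0 or seen[start]:
            continue
        level = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for q in _neighbors26(p):
                if _in_bounds(q, shape) and not seen[q] and levels[q] == level:
                    seen[q] = True
                    stack.append(q)
        zones.append((level, size))
    max_size = max(s for _, s in zones)
    matrix = np.zeros((ng, max_size))
    for level, size in zones:
        matrix[level - 1, size - 1] += 1
    return matrix


def oracle_ngtdm(levels: np.ndarray, ng: int) -> np.ndarray:
    """(p_i, s_i, n_i) table via per-voxel neighborhood loops."""
    shape = levels.shape
    s = np.zeros(ng)
    n = np.zeros(ng)
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        nb = [
            levels[q]
            for q in _neighbors26(p)
            if _in_bounds(q, shape) and levels[q] > 0
        ]
        if not nb:
            continue
        s[levels[p] - 1] += abs(levels[p] - sum(nb) / len(nb))
        n[levels[p] - 1] += 1
    total = n.sum()
    prob = n / total if total else n
    return np.column_stack([prob, s, n])


def oracle_gldm(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts via per-voxel neighbor loops (column j = dep j-1)."""
    shape = levels.shape
    entries = []
    for p in np.ndindex(shape):
        if levels[p] == 0:
            continue
        dep = sum(
            1
            for q in _neighbors26(p)
            if _in_bounds(q, shape)
            and levels[q] > 0
            and abs(int(levels[q]) - int(levels[p])) <= alpha
        )
        entries.append((levels[p], dep))
    max_dep = max(d for _, d in entries)
    matrix = np.zeros((ng, max_dep + 1))
    for level, dep in entries:
        matrix[level - 1, dep] += 1
    return matrix


# ---------------------------------------------------------------- literal formulas

EPS = 2.22e-16


def literal_glcm_anchored(p: np.ndarray) -> dict[str, float]:
    """Autocorrelation, ClusterProminence, DifferenceEntropy, Idm as
    literal loop transcriptions of the printed formulas."""
    ng = p.shape[0]
    mu_x = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    mu_y = sum((j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    autocorr = sum((i + 1) * (j + 1) * p[i, j] for i in range(ng) for j in range(ng))
    cp = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 4 * p[i, j]
        for i in range(ng)
        for j in range(ng)
    )
    p_diff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            p_diff[abs(i - j)] += p[i, j]
    de = -sum(p_diff[k] * math.log2(p_diff[k] + EPS) for k in range(ng))
    idm = sum(p_diff[k] / (1 + k**2) for k in range(ng))
    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": cp,
        "DifferenceEntropy": de,
        "Idm": idm,
    }


def literal_glrlm_anchored(matrix: np.ndarray) -> dict[str, float]:
    """GLN, GLV, RunEntropy, LRHGLE from one run-length matrix."""
    ng, nr_max = matrix.shape
    nr = matrix.sum()
    gln = sum(sum(matrix[i, j] for j in range(nr_max)) ** 2 for i in range(ng)) / nr
    mu = sum((i + 1) * matrix[i, j] / nr for i in range(ng) for j in range(nr_max))
    glv = sum(
        matrix[i, j] / nr * (i + 1 - mu) ** 2 for i in range(ng) for j in range(nr_max)
    )
    re = -sum(
        matrix[i, j] / nr * math.log2(matrix[i, j] / nr + EPS)
        for i in range(ng)
        for j in range(nr_max)
    )
    lrhgle = (
        sum(
            matrix[i, j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng)
            for j in range(nr_max)
        )
        / nr
    )
    return {
        "GrayLevelNonUniformity": gln,
        "GrayLevelVariance": glv,
        "RunEntropy": re,
        "LongRunHighGrayLevelEmphasis": lrhgle,
    }


def literal_sahgle(matrix: np.ndarray) -> float:
    ng, ns = matrix.shape
    nz = matrix.sum()
    return (
        sum(
            matrix[i, j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng)
            for j in range(ns)
        )
        / nz
    )


def literal_coarseness(table: np.ndarray, cap: float = 1e6) -> float:
    denom = sum(table[i, 0] * table[i, 1] for i in range(table.shape[0]))
    return cap if denom == 0 else 1.0 / denom


def literal_gldm_anchored(matrix: np.ndarray) -> dict[str, float]:
    """SmallDependenceEmphasis and DependenceNonUniformity."""
    ng, nd = matrix.shape
    nz = matrix.sum()
    sde = sum(
        matrix[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nd)
    ) / nz
    dn = sum(sum(matrix[i, j] for i in range(ng)) ** 2 for j in range(nd)) / nz
    return {"SmallDependenceEmphasis": sde, "DependenceNonUniformity": dn}
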