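"""Texture-matrix construction: GLCM, GLRLM, GLSZM, NGTDM, GLDM.

All builders work on the discretized ROI's bounding-box level array
(level 0 marks voxels outside the mask).  The 26-neighborhood of a voxel
decomposes into 13 direction pairs; GLCM and GLRLM are built per
direction, GLSZM/NGTDM/GLDM are direction-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = [
    "DIRECTIONS_13",
    "TextureMatrix",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_table",
    "gldm_matrix",
]


def _canonical_directions() -> tuple[tuple[int, int, int], ...]:
    """The 13 independent offsets of the 26-neighborhood (one per +/- pair)."""
    dirs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                if di > 0 or (di == 0 and dj > 0) or (di == 0 and dj == 0 and dk > 0):
                    dirs.append((di, dj, dk))
    return tuple(dirs)


DIRECTIONS_13 = _canonical_directions()
assert len(DIRECTIONS_13) == 13

_FULL_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TextureMatrix:
    """A texture matrix with its kind, direction (if any) and normalizer."""

    kind: str  # GLCM | GLRLM | GLSZM | NGTDM | GLDM
    matrix: np.ndarray
    direction: tuple[int, int, int] | None = None
    n_total: float | None = None  # Nz / Nr(theta) / pair count, per kind


def _paired_slices(shape, offset):
    """Index slices (src, dst) selecting voxel pairs at the given offset."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_matrix(
    d: DiscretizedROI, offset: tuple[int, int, int], distance: int = 1
) -> TextureMatrix | None:
    """Symmetric, normalized gray-level co-occurrence matrix for one offset.

    Only voxel pairs with both ends inside the ROI mask are counted; each
    pair contributes in both orders. Returns ``None`` when the offset
    yields no valid pair (the direction is then skipped in aggregation).
    """
    levels, mask = d.level_array(pad=0)
    off = tuple(int(o) * distance for o in offset)
    src, dst = _paired_slices(levels.shape, off)
    a = levels[src]
    b = levels[dst]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        return None
    a = a[valid] - 1
    b = b[valid] - 1
    ng = d.ng
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(float)
    counts = counts + counts.T  # count both orders -> symmetric
    n_pairs = counts.sum()
    return TextureMatrix(
        kind="GLCM", matrix=counts / n_pairs, direction=offset, n_total=n_pairs
    )


def glrlm_matrix(d: DiscretizedROI, direction: tuple[int, int, int]) -> TextureMatrix:
    """Gray-level run-length matrix P(i, j | theta) for one direction.

    A run is a maximal colinear sequence of mask voxels sharing a gray
    level. Column j counts runs of length j (1-based); entries are raw
    counts, total Nr(theta).
    """
    levels, mask = d.level_array(pad=0)
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum((n * abs(o)) ** 2 for n, o in zip(shape, direction))))) + 1
    matrix = np.zeros((d.ng, max(max_len, 1)), dtype=float)

    off = np.asarray(direction)
    in_bounds = lambda p: all(0 <= c < n for c, n in zip(p, shape))  # noqa: E731

    # a voxel continues a run if its predecessor along -direction matches
    src, dst = _paired_slices(shape, tuple(direction))
    continuation = np.zeros(shape, dtype=bool)
    continuation[dst] = (levels[src] == levels[dst]) & (levels[src] > 0) & (levels[dst] > 0)
    run_starts = np.argwhere(mask & ~continuation)

    for p in run_starts:
        level = levels[tuple(p)]
        length = 1
        q = p + off
        while in_bounds(q) and mask[tuple(q)] and levels[tuple(q)] == level:
            length += 1
            q = q + off
        matrix[level - 1, length - 1] += 1

    # trim trailing all-zero run-length columns
    nonzero_cols = np.nonzero(matrix.sum(axis=0))[0]
    last = nonzero_cols[-1] + 1 if len(nonzero_cols) else 1
    matrix = matrix[:, :last]
    return TextureMatrix(
        kind="GLRLM", matrix=matrix, direction=direction, n_total=float(matrix.sum())
    )


def glszm_matrix(d: DiscretizedROI) -> TextureMatrix:
    """Gray-level size-zone matrix over 26-connected equal-level zones."""
    levels, mask = d.level_array(pad=0)
    zones: list[tuple[int, int]] = []  # (level, size)
    for level in range(1, d.ng + 1):
        where = levels == level
        if not where.any():
            continue
        labeled, n_zones = ndimage.label(where, structure=_FULL_CONNECTIVITY)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    matrix = np.zeros((d.ng, max_size), dtype=float)
    for level, size in zones:
        matrix[level - 1, size - 1] += 1
    return TextureMatrix(kind="GLSZM", matrix=matrix, n_total=float(matrix.sum()))


def _neighbor_sums(levels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel sum of neighbor levels and neighbor count over the mask."""
    lv = np.where(mask, levels, 0).astype(float)
    mk = mask.astype(float)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nb_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(mk, kernel, mode="constant", cval=0.0)
    return nb_sum, np.rint(nb_cnt)


def ngtdm_table(d: DiscretizedROI) -> TextureMatrix:
    """Neighboring gray-tone difference table.

    Row i holds (p_i, s_i, n_i): level probability, summed absolute
    difference from the 26-neighborhood mean, and voxel count. Voxels
    with no in-mask neighbor contribute to neither p nor s.
    """
    levels, mask = d.level_array(pad=0)
    nb_sum, nb_cnt = _neighbor_sums(levels, mask)
    valid = mask & (nb_cnt > 0)
    ng = d.ng
    s = np.zeros(ng)
    n = np.zeros(ng)
    lv = levels[valid]
    diff = np.abs(lv - nb_sum[valid] / nb_cnt[valid])
    np.add.at(s, lv - 1, diff)
    np.add.at(n, lv - 1, 1.0)
    total = n.sum()
    p = n / total if total > 0 else n
    table = np.column_stack([p, s, n])
    return TextureMatrix(kind="NGTDM", matrix=table, n_total=float(total))


def gldm_matrix(d: DiscretizedROI, alpha: int = 0) -> TextureMatrix:
    """Gray-level dependence matrix.

    A neighbor is dependent when its level differs by at most ``alpha``;
    column j of the matrix corresponds to dependence j-1 (so a voxel with
    no dependent neighbor lands in column 1). Entries are raw counts,
    total Nz = number of mask voxels.
    """
    levels, mask = d.level_array(pad=0)
    dep = np.zeros(levels.shape, dtype=np.int32)
    for off in DIRECTIONS_13:
        for sign in (1, -1):
            vec = tuple(sign * o for o in off)
            src, dst = _paired_slices(levels.shape, vec)
            a, b = levels[src], levels[dst]
            hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
            dep[src] += hit.astype(np.int32)
    lv = levels[mask]
    dp = dep[mask]
    matrix = np.zeros((d.ng, int(dp.max()) + 1), dtype=float)
    np.add.at(matrix, (lv - 1, dp), 1.0)
    return TextureMatrix(kind="GLDM", matrix=matrix, n_total=float(matrix.sum()))
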