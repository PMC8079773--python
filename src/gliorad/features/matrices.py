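"""Texture matrix construction from a discretized volume.

All matrices are built in 3D with 26-connectivity:

* co-occurrence (GLCM): voxel pairs at Chebyshev distance 1 along the 13
  unique direction vectors, accumulated by summation over directions and
  symmetrized ("merged"), with the per-direction symmetric matrices also
  kept for the direction-averaged feature variant;
* run length (GLRLM): maximal runs of equal grey level along the same 13
  directions, merged and per-direction;
* size zone (GLSZM): 26-connected components of equal grey level;
* distance zone (GLDZM): the same zones, tabulated against the minimum
  city-block distance of the zone to the VOI border (grid border and
  out-of-mask voxels both count as border; minimum distance is 1);
* grey-tone difference (NGTDM): per-level sums of the absolute
  difference between a voxel's level and the mean level of its in-mask
  26-neighborhood;
* grey-level dependence (NGLDM): dependence count of a voxel = 1 (the
  voxel itself) + the number of in-mask 26-neighbors with exactly the
  same grey level (coarseness parameter alpha = 0).

Neighborhoods and pairs are restricted to in-mask voxels throughout;
missing neighbors are simply ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedVolume

#: the 13 unique 26-connectivity direction vectors (first nonzero positive)
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and next(x for x in d if x != 0) > 0
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class TextureMatrices:
    """The texture matrices of one discretized VOI plus their parameters."""

    glcm: np.ndarray  # G x G, merged over directions, symmetric
    glcm_by_direction: tuple[np.ndarray, ...]
    glrlm: np.ndarray  # G x max run length, merged
    glrlm_by_direction: tuple[np.ndarray, ...]
    glszm: np.ndarray  # G x max zone size
    gldzm: np.ndarray  # G x max zone distance
    ngtdm_s: np.ndarray  # per-level sum of |level - neighborhood mean|
    ngtdm_n: np.ndarray  # per-level voxel counts tallied for the NGTDM
    ngldm: np.ndarray  # G x max dependence count
    n_voxels: int
    n_levels: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.glcm, self.glcm.T):
            raise ValueError("merged co-occurrence matrix is not symmetric")
        sizes = np.arange(1, self.glszm.shape[1] + 1)
        if self.glszm.sum() and int((self.glszm * sizes).sum()) != self.n_voxels:
            raise ValueError("size-zone matrix inconsistent with the voxel count")
        for m in (self.glcm, self.glrlm, self.glszm, self.gldzm, self.ngldm):
            if (m < 0).any():
                raise ValueError("texture matrix has negative entries")


def _pair_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Views a, b of ``arr`` such that b is a shifted by offset d."""
    sl_a, sl_b = [], []
    for ax, step in enumerate(d):
        n = arr.shape[ax]
        if step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        elif step == -1:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _glcm_direction(levels: np.ndarray, mask: np.ndarray, G: int, d) -> np.ndarray:
    a, b = _pair_views(levels, d)
    ma, mb = _pair_views(mask, d)
    valid = ma & mb
    counts = np.zeros((G, G), dtype=np.int64)
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    return counts + counts.T  # symmetrize


def _glrlm_direction(levels: np.ndarray, mask: np.ndarray, G: int, d) -> np.ndarray:
    shape = levels.shape
    # a voxel starts a run if its predecessor along d is out of grid,
    # out of mask, or a different level
    prev_same = np.zeros(shape, dtype=bool)
    a, b = _pair_views(levels, d)
    ma, mb = _pair_views(mask, d)
    # b is "a shifted by d": the predecessor of voxel at the b-view
    # position is the a-view position
    same = ma & mb & (a == b)
    _, sl_b = _pair_slices(shape, d)
    prev_same[sl_b] = same
    starts = np.argwhere(mask & ~prev_same)
    runs: dict[tuple[int, int], int] = {}
    di, dj, dk = d
    ni, nj, nk = shape
    for i, j, k in starts:
        g = levels[i, j, k]
        length = 1
        ci, cj, ck = i + di, j + dj, k + dk
        while (
            0 <= ci < ni
            and 0 <= cj < nj
            and 0 <= ck < nk
            and mask[ci, cj, ck]
            and levels[ci, cj, ck] == g
        ):
            length += 1
            ci, cj, ck = ci + di, cj + dj, ck + dk
        key = (int(g), length)
        runs[key] = runs.get(key, 0) + 1
    if not runs:
        return np.zeros((G, 1), dtype=np.int64)
    rmax = max(r for _, r in runs)
    out = np.zeros((G, rmax), dtype=np.int64)
    for (g, r), c in runs.items():
        out[g - 1, r - 1] = c
    return out


def _pair_slices(shape, d):
    sl_a, sl_b = [], []
    for ax, step in enumerate(d):
        n = shape[ax]
        if step == 1:
            sl_a.append(slice(0, n - 1))
            sl_b.append(slice(1, n))
        elif step == -1:
            sl_a.append(slice(1, n))
            sl_b.append(slice(0, n - 1))
        else:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
    return tuple(sl_a), tuple(sl_b)


def _merge_ragged(mats: list[np.ndarray], G: int) -> np.ndarray:
    width = max((m.shape[1] for m in mats), default=1)
    out = np.zeros((G, width), dtype=np.int64)
    for m in mats:
        out[:, : m.shape[1]] += m
    return out


def _zones(levels: np.ndarray, mask: np.ndarray, G: int):
    """26-connected equal-level zones: list of (level, size, min border distance)."""
    # city-block distance to outside-mask, grid border counting as outside
    padded = np.pad(mask, 1)
    dist = ndimage.distance_transform_cdt(padded, metric="taxicab")
    dist = dist[1:-1, 1:-1, 1:-1]
    zones = []
    for g in range(1, G + 1):
        lab, n = ndimage.label((levels == g) & mask, structure=_STRUCT_26)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        mind = ndimage.minimum(dist, lab, index=range(1, n + 1))
        for s, dmin in zip(np.atleast_1d(sizes), np.atleast_1d(mind)):
            zones.append((g, int(s), int(dmin)))
    return zones


def _neighbor_stats(levels: np.ndarray, mask: np.ndarray):
    """In-mask 26-neighborhood sums/counts and equal-level neighbor counts."""
    lv = np.where(mask, levels, 0).astype(np.float64)
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    nsum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    ncnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    # equal-level neighbor counts
    eq = np.zeros(levels.shape, dtype=np.int64)
    for d in DIRECTIONS:
        sl_a, sl_b = _pair_slices(levels.shape, d)
        same = mask[sl_a] & mask[sl_b] & (levels[sl_a] == levels[sl_b])
        eq[sl_a] += same
        eq[sl_b] += same
    return nsum, np.rint(ncnt).astype(np.int64), eq


def compute_texture_matrices(dv: DiscretizedVolume) -> TextureMatrices:
    """Build all texture matrices for one discretized VOI."""
    levels, mask, G = dv.levels, dv.mask, dv.n_levels
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("discretized volume has an empty mask")

    glcm_dirs = tuple(_glcm_direction(levels, mask, G, d) for d in DIRECTIONS)
    glcm = np.sum(glcm_dirs, axis=0)

    glrlm_dirs = tuple(_glrlm_direction(levels, mask, G, d) for d in DIRECTIONS)
    glrlm = _merge_ragged(list(glrlm_dirs), G)

    zones = _zones(levels, mask, G)
    smax = max(s for _, s, _ in zones)
    dmax = max(d for _, _, d in zones)
    glszm = np.zeros((G, smax), dtype=np.int64)
    gldzm = np.zeros((G, dmax), dtype=np.int64)
    for g, s, dz in zones:
        glszm[g - 1, s - 1] += 1
        gldzm[g - 1, dz - 1] += 1

    nsum, ncnt, eq = _neighbor_stats(levels, mask)
    ngtdm_s = np.zeros(G)
    ngtdm_n = np.zeros(G, dtype=np.int64)
    tally = mask & (ncnt > 0)
    means = np.zeros(levels.shape)
    means[tally] = nsum[tally] / ncnt[tally]
    diffs = np.abs(levels.astype(np.float64) - means)
    for g in range(1, G + 1):
        sel = tally & (levels == g)
        ngtdm_n[g - 1] = int(sel.sum())
        ngtdm_s[g - 1] = float(diffs[sel].sum())

    dep = np.where(mask, eq + 1, 0)  # dependence count includes the voxel itself
    jmax = int(dep.max())
    ngldm = np.zeros((G, jmax), dtype=np.int64)
    np.add.at(ngldm, (levels[mask] - 1, dep[mask] - 1), 1)

    return TextureMatrices(
        glcm=glcm,
        glcm_by_direction=glcm_dirs,
        glrlm=glrlm,
        glrlm_by_direction=glrlm_dirs,
        glszm=glszm,
        gldzm=gldzm,
        ngtdm_s=ngtdm_s,
        ngtdm_n=ngtdm_n,
        ngldm=ngldm,
        n_voxels=n_vox,
        n_levels=G,
        params={
            "connectivity": 26,
            "glcm_distance": 1,
            "ngldm_alpha": 0,
            "n_directions": len(DIRECTIONS),
            "provenance": dict(dv.provenance),
        },
    )
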