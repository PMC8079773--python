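"""Resampling, intensity normalization and grey-level discretization.

Two normalization/discretization schemes are supported, mirroring the
two ways multi-scanner T1 intensities can be made comparable:

* **fixed bin number** — the in-VOI intensity range is divided into a
  fixed number of equal bins (default 32).  This makes all downstream
  texture features invariant to any affine intensity transform of the
  raw image, at the cost of discarding the absolute intensity scale.
* **linear two-point rescaling + fixed bin size** — an affine map is
  solved so that the mean intensity of two reference tissues (normal
  white matter, vitreous body of one eye) hits prescribed anchor
  values; texture is then discretized with a constant bin width
  (default 50 intensity units), preserving absolute range information.

Shape analysis uses a 1 mm cubic resample of the mask; intensity and
texture analysis use a 3 mm cubic resample, both by trilinear
interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import VoiMask, VoxelGrid

#: grey level assigned to voxels outside the mask; excluded from all statistics
OUTSIDE_LEVEL = 0

SHAPE_RESAMPLE_MM = 1.0
TEXTURE_RESAMPLE_MM = 3.0


class DegenerateIntensityWarning(UserWarning):
    """The in-mask intensity range is degenerate (constant region)."""


@dataclass(frozen=True)
class NormalizationSpec:
    """Parameters of one normalization/discretization scheme."""

    method: str = "fixed_bin_number"  # or "linear_two_point"
    n_bins: int = 32
    bin_size: float = 50.0
    anchor_wm: float = 300.0
    anchor_vitreous: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("fixed_bin_number", "linear_two_point"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.anchor_wm == self.anchor_vitreous:
            raise ValueError("reference anchors must be distinct")


@dataclass(frozen=True)
class DiscretizedVolume:
    """Integer grey-level lattice (1..G inside the mask, 0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int32)
        mask = np.asarray(self.mask, dtype=bool)
        if levels.shape != mask.shape:
            raise ValueError("levels and mask shapes differ")
        inside = levels[mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("grey levels outside 1..G inside the mask")
        out = levels.copy()
        out[~mask] = OUTSIDE_LEVEL
        object.__setattr__(self, "levels", out)
        object.__setattr__(self, "mask", mask)


def _resample_values(values: np.ndarray, spacing, target_mm: float, order: int = 1) -> np.ndarray:
    # new voxel centres share the old origin and step target_mm along each axis
    new_shape = tuple(
        int(np.floor((n - 1) * s / target_mm)) + 1 for n, s in zip(values.shape, spacing)
    )
    coords = np.meshgrid(
        *[np.arange(m) * target_mm / s for m, s in zip(new_shape, spacing)],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        values.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )


def resample_trilinear(grid: VoxelGrid, target_mm: float) -> VoxelGrid:
    """Resample to a cubic voxel size by trilinear interpolation."""
    if target_mm <= 0:
        raise ValueError("target voxel size must be positive")
    extent = [(n - 1) * s for n, s in zip(grid.shape, grid.spacing)]
    if any(e < target_mm for e in extent):
        raise ValueError(
            f"target voxel size {target_mm} mm exceeds the volume extent {extent} mm"
        )
    out = _resample_values(grid.values, grid.spacing, target_mm)
    return VoxelGrid(out, (target_mm,) * 3, grid.origin)


def resample_mask_trilinear(mask: VoiMask, target_mm: float) -> VoiMask:
    """Resample a mask with the same transform, then threshold at 0.5."""
    if target_mm <= 0:
        raise ValueError("target voxel size must be positive")
    frac = _resample_values(mask.values.astype(np.float64), mask.spacing, target_mm)
    return VoiMask(frac >= 0.5, (target_mm,) * 3, mask.role, mask.origin)


def discretize_fixed_bin_number(
    grid: VoxelGrid, mask: VoiMask, n_bins: int = 32
) -> DiscretizedVolume:
    """Discretize in-mask intensities into ``n_bins`` equal-width levels.

    level = 1 + floor(n_bins * (I - I_min) / (I_max - I_min)), with the
    in-mask maximum mapped to ``n_bins``.
    """
    grid.require_aligned(mask, "grid/mask")
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    inside = grid.values[m].astype(np.float64)
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(grid.shape, dtype=np.int32)
    if hi == lo:
        warnings.warn(
            "degenerate intensity range inside the mask; all voxels assigned level 1",
            DegenerateIntensityWarning,
            stacklevel=2,
        )
        levels[m] = 1
    else:
        lv = 1 + np.floor(n_bins * (grid.values[m].astype(np.float64) - lo) / (hi - lo))
        levels[m] = np.minimum(lv, n_bins).astype(np.int32)
    return DiscretizedVolume(
        levels,
        m,
        n_bins,
        provenance={"method": "fixed_bin_number", "n_bins": n_bins},
    )


def normalize_linear_two_point(
    grid: VoxelGrid,
    wm_mask: VoiMask,
    vitreous_mask: VoiMask,
    spec: NormalizationSpec,
) -> VoxelGrid:
    """Affine intensity rescaling anchored at two reference tissues.

    Solves I' = a*I + b so that the mean over the white-matter mask maps
    to ``spec.anchor_wm`` and the mean over the vitreous mask to
    ``spec.anchor_vitreous``, and applies the map to the whole volume.
    """
    grid.require_aligned(wm_mask, "grid/white-matter mask")
    grid.require_aligned(vitreous_mask, "grid/vitreous mask")
    mean_wm = float(grid.values[wm_mask.values].mean())
    mean_vit = float(grid.values[vitreous_mask.values].mean())
    if np.isclose(mean_wm, mean_vit):
        raise ValueError(
            f"reference tissue means coincide ({mean_wm:.4g}); the two-point "
            "linear rescaling is degenerate"
        )
    a = (spec.anchor_wm - spec.anchor_vitreous) / (mean_wm - mean_vit)
    b = spec.anchor_wm - a * mean_wm
    return VoxelGrid(a * grid.values.astype(np.float64) + b, grid.spacing, grid.origin)


def discretize_fixed_bin_size(
    grid: VoxelGrid, mask: VoiMask, bin_size: float = 50.0
) -> DiscretizedVolume:
    """Discretize in-mask intensities with a constant bin width.

    level = 1 + floor((I - I_min) / bin_size) over in-mask intensities,
    anchored at the in-mask minimum; G is the maximum occupied level.
    """
    grid.require_aligned(mask, "grid/mask")
    m = mask.values
    if not m.any():
        raise ValueError("mask is empty")
    inside = grid.values[m].astype(np.float64)
    if not np.all(np.isfinite(inside)):
        raise ValueError("non-finite intensities inside the mask")
    lo = float(inside.min())
    lv = (1 + np.floor((inside - lo) / bin_size)).astype(np.int32)
    levels = np.zeros(grid.shape, dtype=np.int32)
    levels[m] = lv
    return DiscretizedVolume(
        levels,
        m,
        int(lv.max()),
        provenance={"method": "fixed_bin_size", "bin_size": bin_size, "min": lo},
    )


def discretize(grid: VoxelGrid, mask: VoiMask, spec: NormalizationSpec) -> DiscretizedVolume:
    """Dispatch to the scheme named in the spec (grid already normalized)."""
    if spec.method == "fixed_bin_number":
        return discretize_fixed_bin_number(grid, mask, spec.n_bins)
    return discretize_fixed_bin_size(grid, mask, spec.bin_size)
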