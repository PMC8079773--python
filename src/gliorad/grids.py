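"""Voxel lattices and binary volumes of interest.

A :class:`VoxelGrid` is the unit every image operation consumes and
produces: a 3D scalar intensity lattice with per-axis spacing (mm) and a
world-space origin (mm).  Voxel centre ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing``.  Only axis-aligned lattices are
supported; oblique orientations must be resampled externally.

A :class:`VoiMask` is a binary lattice aligned to a grid, tagged with the
anatomical role it plays in the analysis (tumoral, peritumoral rim,
reference tissues, exclusion region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: spacing/origin agreement (mm) below which two lattices count as aligned.
#: Absorbs file-format float noise while rejecting genuine mismatch.
ALIGNMENT_TOL_MM = 1e-3

#: Roles a binary volume of interest can play in the pipeline.
MASK_ROLES = ("tumoral", "peritumoral", "wm_reference", "vitreous_reference", "exclusion")


class GridAlignmentError(ValueError):
    """Two lattices that should share shape/spacing/origin do not."""


@dataclass(frozen=True)
class VoxelGrid:
    """3D scalar intensity lattice with per-axis spacing and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float32)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {values.ndim}D data")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values (mm), got {self.spacing}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite intensities")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def aligned_with(self, other: "VoxelGrid | VoiMask", tol: float = ALIGNMENT_TOL_MM) -> bool:
        """Symmetric lattice-compatibility check (shape, spacing, origin)."""
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_aligned(self, other: "VoxelGrid | VoiMask", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} are not aligned: "
                f"shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )


@dataclass(frozen=True)
class VoiMask:
    """Binary lattice aligned to a :class:`VoxelGrid`, with a role tag."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    role: str
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {values.ndim}D data")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask is not binary: found values {uniq[:10]}")
        values = values.astype(bool)
        if self.role not in MASK_ROLES:
            raise ValueError(f"unknown mask role {self.role!r}; expected one of {MASK_ROLES}")
        if self.role != "exclusion" and not values.any():
            raise ValueError(f"mask with role {self.role!r} is empty")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values (mm), got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def aligned_with(self, other: "VoxelGrid | VoiMask", tol: float = ALIGNMENT_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_aligned(self, other: "VoxelGrid | VoiMask", what: str = "masks") -> None:
        if not self.aligned_with(other):
            raise GridAlignmentError(
                f"{what} are not aligned: "
                f"shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, "
                f"origin {self.origin} vs {other.origin}"
            )

    def with_values(self, values: np.ndarray, role: str | None = None) -> "VoiMask":
        return VoiMask(values, self.spacing, role or self.role, self.origin)
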