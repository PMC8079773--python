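"""Morphological (shape) features of a binary VOI at 1 mm cubic spacing.

Mesh-based quantities (volume, surface area) come from a marching-cubes
triangulation of the mask; axis lengths are 4 * sqrt(eigenvalue) of the
covariance matrix of voxel-centre coordinates (principal component
analysis of the voxel cloud).  Degenerate geometries (single voxel,
coplanar voxel sets) yield flagged conventional values rather than NaN.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from ..grids import VoiMask

#: template order of the 24 shape features (unprefixed)
_NAMES = (
    "voxel_count",
    "voxel_volume",
    "mesh_volume",
    "surface_area",
    "surface_to_volume_ratio",
    "compactness_1",
    "compactness_2",
    "spherical_disproportion",
    "sphericity",
    "asphericity",
    "maximum_3d_diameter",
    "major_axis_length",
    "minor_axis_length",
    "least_axis_length",
    "elongation",
    "flatness",
    "equivalent_spherical_diameter",
    "volume_density_aabb",
    "area_density_aabb",
    "volume_density_aee",
    "area_density_aee",
    "convex_hull_volume",
    "volume_density_convex_hull",
    "area_density_convex_hull",
)


#: anti-aliasing sigma (voxels) for the surface mesh; a lightly smoothed
#: level set removes the staircase bias of a binary marching-cubes surface
MESH_SMOOTHING_SIGMA = 0.8


def _mesh(mask: np.ndarray, spacing):
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 3), MESH_SMOOTHING_SIGMA)
    if padded.max() <= 0.5:  # tiny mask: smoothing washes out the level set
        padded = np.pad(mask.astype(np.float64), 3)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - 3 * np.asarray(spacing)  # undo padding offset
    area = measure.mesh_surface_area(verts, faces)
    tri = verts[faces]
    # signed volume via the divergence theorem
    vol = float(np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return vol, float(area), verts


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    # Thomsen approximation, exact for spheres, <1.1% error elsewhere
    p = 1.6075
    if min(a, b, c) <= 0:
        return 0.0
    return float(4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p))


def compute_shape(mask: VoiMask):
    """The 24 morphological features. Returns ``(values, flags)``.

    Expects a cubic-1-mm resampled mask; any cubic spacing is accepted
    and honored, anisotropic spacing is rejected.
    """
    sp = mask.spacing
    if not (abs(sp[0] - sp[1]) < 1e-9 and abs(sp[1] - sp[2]) < 1e-9):
        raise ValueError(f"shape analysis requires cubic spacing, got {sp}")
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    flags: set[str] = set()
    out = dict.fromkeys(_NAMES, 0.0)

    n = int(m.sum())
    vvol = float(np.prod(sp))
    out["voxel_count"] = float(n)
    out["voxel_volume"] = n * vvol

    mesh_vol, area, verts = _mesh(m, sp)
    out["mesh_volume"] = mesh_vol
    out["surface_area"] = area
    V, A = mesh_vol, area
    out["surface_to_volume_ratio"] = A / V
    out["compactness_1"] = V / (np.sqrt(np.pi) * A**1.5)
    out["compactness_2"] = 36 * np.pi * V**2 / A**3
    out["spherical_disproportion"] = A / (36 * np.pi * V**2) ** (1 / 3)
    out["sphericity"] = (36 * np.pi * V**2) ** (1 / 3) / A
    out["asphericity"] = (A**3 / (36 * np.pi * V**2)) ** (1 / 3) - 1
    out["equivalent_spherical_diameter"] = (6 * V / np.pi) ** (1 / 3)

    coords = np.argwhere(m).astype(np.float64) * np.asarray(sp)
    try:
        hull = ConvexHull(coords)
        hv, ha = float(hull.volume), float(hull.area)
        pts = coords[hull.vertices]
        d = pts[:, None, :] - pts[None, :, :]
        out["maximum_3d_diameter"] = float(np.sqrt((d**2).sum(-1)).max())
        out["convex_hull_volume"] = hv
        out["volume_density_convex_hull"] = V / hv if hv > 0 else 0.0
        out["area_density_convex_hull"] = A / ha if ha > 0 else 0.0
    except QhullError:
        # fewer than 4 non-coplanar voxels
        d = coords[:, None, :] - coords[None, :, :]
        out["maximum_3d_diameter"] = float(np.sqrt((d**2).sum(-1)).max())
        flags.update(("convex_hull_volume", "volume_density_convex_hull", "area_density_convex_hull"))

    if n > 1:
        cov = np.cov(coords, rowvar=False, ddof=0)
        eig = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
        major, minor, least = (4.0 * np.sqrt(e) for e in eig)
        out["major_axis_length"] = major
        out["minor_axis_length"] = minor
        out["least_axis_length"] = least
        if eig[0] > 0:
            out["elongation"] = float(np.sqrt(eig[1] / eig[0]))
            out["flatness"] = float(np.sqrt(eig[2] / eig[0]))
        else:
            flags.update(("elongation", "flatness"))
        a, b, c = 2 * np.sqrt(eig)
        v_aee = 4 * np.pi * a * b * c / 3
        if v_aee > 0:
            out["volume_density_aee"] = V / v_aee
            out["area_density_aee"] = A / _ellipsoid_area(a, b, c)
        else:
            flags.update(("volume_density_aee", "area_density_aee"))
    else:
        flags.update(
            (
                "major_axis_length",
                "minor_axis_length",
                "least_axis_length",
                "elongation",
                "flatness",
                "volume_density_aee",
                "area_density_aee",
            )
        )

    idx = np.argwhere(m)
    extent = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(sp)
    v_aabb = float(np.prod(extent))
    a_aabb = 2 * float(
        extent[0] * extent[1] + extent[0] * extent[2] + extent[1] * extent[2]
    )
    out["volume_density_aabb"] = V / v_aabb
    out["area_density_aabb"] = A / a_aabb

    return {"shape_" + k: float(v) for k, v in out.items()}, {"shape_" + k for k in flags}
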