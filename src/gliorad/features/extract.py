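"""Per-VOI extraction of the full 180-feature set.

Shape features are computed on a 1 mm cubic resample of the mask;
intensity and texture features on a 3 mm cubic resample of the image
after the configured intensity normalization:

* ``fixed_bin_number`` — intensities are reduced to 32 equal bins over
  the in-VOI range; intensity statistics operate on the bin levels, so
  every downstream value is invariant to affine transforms of the raw
  intensities;
* ``linear_two_point`` — the volume is affinely rescaled to pin the
  white-matter and vitreous reference means at their anchors, then
  discretized with a fixed bin size for texture.

Wavelet-filtered features are deliberately not part of the set: the
analyzed regions are too small for a meaningful multi-resolution
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids import VoiMask, VoxelGrid
from ..preprocess import (
    SHAPE_RESAMPLE_MM,
    TEXTURE_RESAMPLE_MM,
    NormalizationSpec,
    discretize_fixed_bin_number,
    discretize_fixed_bin_size,
    normalize_linear_two_point,
    resample_mask_trilinear,
    resample_trilinear,
)
from .intensity import compute_intensity
from .matrices import compute_texture_matrices
from .names import ALL_FEATURES, feature_families
from .shape import compute_shape
from .texture import compute_texture_features


class ExtractionError(RuntimeError):
    """A stage of the extraction pipeline failed; the stage is named."""


@dataclass(frozen=True)
class FeatureVector:
    """Ordered feature-name -> value map for one VOI of one scan."""

    values: dict[str, float]
    voi: str  # tumoral / peritumoral
    provenance: dict = field(default_factory=dict)
    degenerate: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != ALL_FEATURES:
            missing = set(ALL_FEATURES) - set(self.values)
            extra = set(self.values) - set(ALL_FEATURES)
            raise ValueError(
                f"feature census violated: {len(self.values)} features, "
                f"missing {sorted(missing)[:5]}, unexpected {sorted(extra)[:5]}"
            )
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    @property
    def families(self) -> dict[str, str]:
        return feature_families()

    def family_counts(self) -> dict[str, int]:
        fam = self.families
        counts = {"shape": 0, "intensity": 0, "texture": 0}
        for name in self.values:
            counts[fam[name]] += 1
        return counts


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ExtractionError:
                raise
            except Exception as err:
                raise ExtractionError(f"stage {name!r} failed: {err}") from err

        return wrapper

    return deco


@_stage("shape")
def _shape_block(mask: VoiMask):
    mask_1mm = resample_mask_trilinear(mask, SHAPE_RESAMPLE_MM)
    if mask_1mm.voxel_count == 0:
        raise ValueError("mask vanished at the 1 mm shape resample")
    return compute_shape(mask_1mm)


def extract_voi(
    grid: VoxelGrid,
    mask: VoiMask,
    spec: NormalizationSpec,
    wm_mask: VoiMask | None = None,
    vitreous_mask: VoiMask | None = None,
) -> FeatureVector:
    """Extract all 180 features for a single VOI."""
    grid.require_aligned(mask, "image/VOI mask")
    shape_vals, shape_flags = _shape_block(mask)

    try:
        grid3 = resample_trilinear(grid, TEXTURE_RESAMPLE_MM)
        mask3 = resample_mask_trilinear(mask, TEXTURE_RESAMPLE_MM)
        if mask3.voxel_count == 0:
            raise ValueError("mask vanished at the 3 mm texture resample")
        if spec.method == "linear_two_point":
            if wm_mask is None or vitreous_mask is None:
                raise ValueError("linear_two_point normalization needs both reference masks")
            wm3 = resample_mask_trilinear(wm_mask, TEXTURE_RESAMPLE_MM)
            vit3 = resample_mask_trilinear(vitreous_mask, TEXTURE_RESAMPLE_MM)
            norm3 = normalize_linear_two_point(grid3, wm3, vit3, spec)
            dv = discretize_fixed_bin_size(norm3, mask3, spec.bin_size)
            intensity_grid = norm3
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dv = discretize_fixed_bin_number(grid3, mask3, spec.n_bins)
            # operate on bin levels so intensity statistics inherit the
            # affine invariance of the discretization
            intensity_grid = VoxelGrid(
                dv.levels.astype(np.float32), grid3.spacing, grid3.origin
            )
    except ExtractionError:
        raise
    except Exception as err:
        raise ExtractionError(f"stage 'normalization' failed: {err}") from err

    try:
        int_vals, int_flags = compute_intensity(intensity_grid, mask3, dv)
    except Exception as err:
        raise ExtractionError(f"stage 'intensity' failed: {err}") from err

    try:
        tm = compute_texture_matrices(dv)
        tex_vals, tex_flags = compute_texture_features(tm)
    except Exception as err:
        raise ExtractionError(f"stage 'texture' failed: {err}") from err

    values = {}
    for name in ALL_FEATURES:
        if name in shape_vals:
            values[name] = shape_vals[name]
        elif name in int_vals:
            values[name] = int_vals[name]
        else:
            values[name] = tex_vals[name]
    return FeatureVector(
        values=values,
        voi=mask.role,
        provenance={
            "normalization": spec.method,
            "n_bins": spec.n_bins,
            "bin_size": spec.bin_size,
            "shape_resample_mm": SHAPE_RESAMPLE_MM,
            "texture_resample_mm": TEXTURE_RESAMPLE_MM,
            **dv.provenance,
        },
        degenerate=frozenset(shape_flags | int_flags | tex_flags),
    )


def extract_all(
    grid: VoxelGrid,
    masks: dict[str, VoiMask],
    spec: NormalizationSpec,
) -> dict[str, FeatureVector]:
    """Extract features for the tumoral and peritumoral VOIs of one scan.

    ``masks`` maps roles to masks and must contain ``tumoral`` and
    ``peritumoral``; the two reference-tissue masks are required for
    the linear two-point normalization.
    """
    out: dict[str, FeatureVector] = {}
    for voi in ("tumoral", "peritumoral"):
        if voi not in masks:
            raise ExtractionError(f"stage 'input' failed: missing {voi!r} mask")
        out[voi] = extract_voi(
            grid,
            masks[voi],
            spec,
            wm_mask=masks.get("wm_reference"),
            vitreous_mask=masks.get("vitreous_reference"),
        )
    return out
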