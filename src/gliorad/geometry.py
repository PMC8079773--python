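"""Construction of the analysis volumes of interest.

The tumoral VOI is the contrast-enhancing tumor including cystic or
necrotic areas; blood residuals along a resection cavity are removed by
subtracting the hyperintense pre-contrast volume.  The peritumoral VOI
is an isotropic rim (default 15 mm, measured in world space between
voxel centres with anisotropy-aware Euclidean distance) around the
tumor, minus the tumor itself and any exclusion regions (resection
cavity, ventricle, subarachnoid space, bone).

Volumes are reported in ml (1 ml = 1000 mm^3).  Tumors smaller than
0.2 ml are flagged for exclusion from the analysis; the comparison is
strict, so a mask of exactly 0.2 ml is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import VoiMask

#: rim width around the tumor, mm
DEFAULT_RIM_MM = 15.0
#: tumors strictly smaller than this are excluded from the analysis, ml
MIN_TUMOR_VOLUME_ML = 0.2


class EmptyVoiError(ValueError):
    """A VOI construction step produced an empty region."""


@dataclass(frozen=True)
class VoiPair:
    """Aligned tumoral and peritumoral masks with their volumes (ml)."""

    tumoral: VoiMask
    peritumoral: VoiMask
    tumoral_ml: float
    peritumoral_ml: float

    def __post_init__(self) -> None:
        self.tumoral.require_aligned(self.peritumoral, "tumoral/peritumoral masks")
        if np.any(self.tumoral.values & self.peritumoral.values):
            raise ValueError("tumoral and peritumoral masks overlap")
        if self.tumoral_ml <= 0 or self.peritumoral_ml <= 0:
            raise ValueError("VOI volumes must be positive")


def subtract_precontrast(post_mask: VoiMask, pre_hyperintense_mask: VoiMask) -> VoiMask:
    """Remove pre-contrast hyperintense voxels (blood residuals) from the tumor mask."""
    post_mask.require_aligned(pre_hyperintense_mask, "post/pre-contrast masks")
    result = post_mask.values & ~pre_hyperintense_mask.values
    if not result.any():
        raise EmptyVoiError(
            "pre-contrast subtraction left an empty tumor mask: the enhancing "
            "volume is fully explained by pre-contrast hyperintensity"
        )
    return post_mask.with_values(result)


def make_peritumoral_rim(
    tumor: VoiMask,
    exclusions: list[VoiMask] | None = None,
    distance_mm: float = DEFAULT_RIM_MM,
) -> VoiMask:
    """Build the peritumoral rim around a tumor mask.

    The rim contains every voxel whose centre lies within ``distance_mm``
    (Euclidean, in mm, honoring anisotropic spacing) of some tumor voxel
    centre, minus the tumor itself and minus all exclusion masks.
    """
    if distance_mm <= 0:
        raise ValueError(f"rim distance must be positive, got {distance_mm}")
    exclusions = exclusions or []
    for exc in exclusions:
        tumor.require_aligned(exc, "tumor/exclusion masks")
    # EDT of the tumor complement = distance from each voxel centre to the
    # nearest tumor voxel centre, in mm.
    dist = ndimage.distance_transform_edt(~tumor.values, sampling=tumor.spacing)
    rim = (dist <= distance_mm) & ~tumor.values
    for exc in exclusions:
        rim &= ~exc.values
    if not rim.any():
        raise EmptyVoiError("peritumoral rim is empty after applying exclusions")
    return VoiMask(rim, tumor.spacing, "peritumoral", tumor.origin)


def voi_volume_ml(mask: VoiMask) -> float:
    """Mask volume in ml: voxel count x voxel volume / 1000."""
    return mask.voxel_count * mask.voxel_volume_mm3 / 1000.0


def below_volume_threshold(mask: VoiMask, threshold_ml: float = MIN_TUMOR_VOLUME_ML) -> bool:
    """True when the mask is strictly smaller than the exclusion threshold."""
    return voi_volume_ml(mask) < threshold_ml


def make_voi_pair(
    tumor: VoiMask,
    exclusions: list[VoiMask] | None = None,
    distance_mm: float = DEFAULT_RIM_MM,
) -> VoiPair:
    rim = make_peritumoral_rim(tumor, exclusions, distance_mm)
    return VoiPair(tumor, rim, voi_volume_ml(tumor), voi_volume_ml(rim))
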