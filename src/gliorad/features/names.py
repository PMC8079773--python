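"""Canonical feature names, family membership and literature aliases.

The extractor produces exactly 180 features per VOI: 24 shape, 19
intensity and 137 texture.  Texture features come from six matrix
constructions over five matrix families: grey-level co-occurrence
(merged over the 13 unique 3D directions, and averaged per direction),
grey-level run length (merged and averaged), grey-level size zone,
grey-level distance zone, neighborhood grey-tone difference and
neighboring grey-level dependence.

``ALIASES`` maps the spelled-out names used in the clinical radiomics
literature to the canonical snake-case names, so that published model
definitions can be applied verbatim.
"""

from __future__ import annotations

SHAPE_FEATURES: tuple[str, ...] = tuple(
    "shape_" + n
    for n in (
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
)

INTENSITY_FEATURES: tuple[str, ...] = tuple(
    "intensity_" + n
    for n in (
        "mean",
        "variance",
        "skewness",
        "kurtosis",
        "median",
        "minimum",
        "maximum",
        "range",
        "percentile_10",
        "percentile_90",
        "coefficient_of_variation",
        "robust_mean_absolute_deviation",
        "energy",
        "root_mean_square",
        "histogram_entropy",
        "histogram_energy",
        "enhancing_tumor_volume_30",
        "enhancing_tumor_volume_40",
        "enhancing_tumor_volume_70",
    )
)

_GLCM = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalised",
    "inverse_difference_moment",
    "inverse_difference_moment_normalised",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation_1",
    "information_correlation_2",
)

_GLRLM = (
    "short_runs_emphasis",
    "long_runs_emphasis",
    "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis",
    "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis",
    "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "run_length_non_uniformity",
    "run_length_non_uniformity_normalised",
    "run_percentage",
    "grey_level_variance",
    "run_length_variance",
    "run_entropy",
)

_GLSZM = (
    "small_zone_emphasis",
    "large_zone_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis",
    "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_size_variance",
    "zone_size_entropy",
)

_GLDZM = (
    "small_distance_emphasis",
    "large_distance_emphasis",
    "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis",
    "small_distance_low_grey_level_emphasis",
    "small_distance_high_grey_level_emphasis",
    "large_distance_low_grey_level_emphasis",
    "large_distance_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "zone_distance_non_uniformity",
    "zone_distance_non_uniformity_normalised",
    "zone_percentage",
    "grey_level_variance",
    "zone_distance_variance",
    "zone_distance_entropy",
)

_NGTDM = ("coarseness", "contrast", "busyness", "complexity", "strength")

_NGLDM = (
    "low_dependence_emphasis",
    "high_dependence_emphasis",
    "low_grey_level_count_emphasis",
    "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis",
    "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalised",
    "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalised",
    "dependence_count_percentage",
    "grey_level_variance",
    "dependence_count_variance",
    "dependence_count_entropy",
    "dependence_count_energy",
)

TEXTURE_FEATURES: tuple[str, ...] = (
    tuple("glcm_" + n for n in _GLCM)
    + ("glcm_maximal_correlation_coefficient",)
    + tuple("glcm_avg_" + n for n in _GLCM)
    + tuple("glrlm_" + n for n in _GLRLM)
    + tuple("glrlm_avg_" + n for n in _GLRLM)
    + tuple("glszm_" + n for n in _GLSZM)
    + tuple("gldzm_" + n for n in _GLDZM)
    + tuple("ngtdm_" + n for n in _NGTDM)
    + tuple("ngldm_" + n for n in _NGLDM)
)

ALL_FEATURES: tuple[str, ...] = SHAPE_FEATURES + INTENSITY_FEATURES + TEXTURE_FEATURES

assert len(SHAPE_FEATURES) == 24
assert len(INTENSITY_FEATURES) == 19
assert len(TEXTURE_FEATURES) == 137
assert len(set(ALL_FEATURES)) == 180

#: literature spelling -> canonical name
ALIASES: dict[str, str] = {
    "Neighborhood Gray Tone Difference Matrix busyness": "ngtdm_busyness",
    "Neighborhood Gray Level Dependence Matrix low dependence emphasis": "ngldm_low_dependence_emphasis",
    "Gray Level Size Zone Matrix zone size entropy": "glszm_zone_size_entropy",
    "Gray Level Size Zone Matrix large zone low gray level emphasis": "glszm_large_zone_low_grey_level_emphasis",
    "Grey Level Size Zone Matrix large zone low gray level emphasis": "glszm_large_zone_low_grey_level_emphasis",
    "Gray Level Run Length Matrix long runs emphasis": "glrlm_long_runs_emphasis",
    "Gray Level Run Length Matrix run length variance": "glrlm_run_length_variance",
    "coefficient of variation": "intensity_coefficient_of_variation",
    "kurtosis": "intensity_kurtosis",
    "histogram energy": "intensity_histogram_energy",
    "enhancing tumor volume 30%": "intensity_enhancing_tumor_volume_30",
    "enhancing tumor volume 40%": "intensity_enhancing_tumor_volume_40",
    "enhancing tumor volume 70%": "intensity_enhancing_tumor_volume_70",
    "minor axis": "shape_minor_axis_length",
}

assert all(v in ALL_FEATURES for v in ALIASES.values())


def feature_families() -> dict[str, str]:
    """Map every canonical feature name to its family tag."""
    fam = {}
    for n in SHAPE_FEATURES:
        fam[n] = "shape"
    for n in INTENSITY_FEATURES:
        fam[n] = "intensity"
    for n in TEXTURE_FEATURES:
        fam[n] = "texture"
    return fam


def resolve(name: str) -> str:
    """Resolve a canonical or literature feature name to the canonical one."""
    if name in ALL_FEATURES:
        return name
    if name in ALIASES:
        return ALIASES[name]
    raise KeyError(f"unknown feature name {name!r}")
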