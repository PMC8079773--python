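"""Texture matrices and features against brute-force references."""

import numpy as np
import pytest
from _oracles import oracle_all_texture_features, oracle_glcm

from gliorad.features import (
    ALIASES,
    TEXTURE_FEATURES,
    compute_texture_features,
    compute_texture_matrices,
    extract_voi,
)
from gliorad.features.names import resolve
from gliorad.grids import VoxelGrid
from gliorad.preprocess import DiscretizedVolume, NormalizationSpec


def _dv(levels, mask=None, G=None):
    levels = np.asarray(levels, dtype=np.int32)
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    G = G or int(levels[mask].max())
    return DiscretizedVolume(np.where(mask, levels, 0), mask, G)


class TestMatrices:
    def test_constant_volume_is_one_zone_of_27(self):
        tm = compute_texture_matrices(_dv(np.ones((3, 3, 3))))
        assert tm.glszm.shape == (1, 27)
        assert tm.glszm[0, 26] == 1
        assert tm.glszm.sum() == 1

    def test_checkerboard_has_no_equal_level_neighbors_on_odd_offsets(self):
        # 2-level 3D checkerboard: any offset with odd coordinate sum flips
        # the level, so those directional co-occurrence matrices have
        # empty diagonals
        idx = np.indices((4, 4, 4)).sum(axis=0)
        levels = (idx % 2) + 1
        tm = compute_texture_matrices(_dv(levels))
        from gliorad.features.matrices import DIRECTIONS

        for d, mat in zip(DIRECTIONS, tm.glcm_by_direction):
            if sum(d) % 2 != 0:
                assert np.all(np.diag(mat) == 0)
            np.testing.assert_array_equal(
                mat, oracle_glcm(levels, np.ones(levels.shape, bool), 2, direction=d)
            )

    def test_merged_glcm_is_symmetric_and_zone_sizes_cover_the_mask(self, rng):
        levels = rng.integers(1, 4, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask[0, 0, 0] = True
        tm = compute_texture_matrices(_dv(levels, mask, 3))
        np.testing.assert_array_equal(tm.glcm, tm.glcm.T)
        sizes = np.arange(1, tm.glszm.shape[1] + 1)
        assert (tm.glszm * sizes).sum() == mask.sum()

    def test_ngldm_dependence_counts_on_a_constant_cube(self):
        # constant 3x3x3, full mask: corners depend on 8 voxels, edges 12,
        # faces 18, centre 27 (the voxel itself counts)
        tm = compute_texture_matrices(_dv(np.ones((3, 3, 3))))
        counts = {j + 1: int(tm.ngldm[0, j]) for j in range(tm.ngldm.shape[1]) if tm.ngldm[0, j]}
        assert counts == {8: 8, 12: 12, 18: 6, 27: 1}
        vals, _ = compute_texture_features(tm)
        lde = sum(c / j**2 for j, c in counts.items()) / 27
        assert vals["ngldm_low_dependence_emphasis"] == pytest.approx(lde, rel=1e-12)


class TestFeatures:
    def test_constant_volume_degenerate_conventions(self):
        tm = compute_texture_matrices(_dv(np.ones((4, 4, 4))))
        vals, flags = compute_texture_features(tm)
        assert vals["ngtdm_busyness"] == 0.0  # no grey-tone differences
        assert vals["glcm_joint_entropy"] == 0.0
        assert vals["glszm_zone_size_entropy"] == 0.0
        assert vals["glcm_correlation"] == 0.0 and "glcm_correlation" in flags
        assert np.isfinite(list(vals.values())).all()

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_on_random_small_volumes(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(2, 6, size=3))
        G = int(rng.integers(1, 5))
        levels = rng.integers(1, G + 1, size=shape)
        mask = rng.random(shape) < 0.75
        mask.flat[0] = True
        tm = compute_texture_matrices(_dv(levels, mask, G))
        vals, _ = compute_texture_features(tm)
        ref = oracle_all_texture_features(levels, mask, G)
        assert set(vals) == set(ref)
        for k in ref:
            assert vals[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-12), k

    def test_rotation_consistency_of_merged_and_averaged_features(self, rng):
        levels = rng.integers(1, 4, size=(5, 5, 5))
        base = _dv(levels)
        vals0, _ = compute_texture_features(compute_texture_matrices(base))
        for axes in ((0, 1), (0, 2), (1, 2)):
            rot = np.rot90(levels, k=1, axes=axes)
            vals_r, _ = compute_texture_features(compute_texture_matrices(_dv(rot)))
            for k in vals0:
                assert vals0[k] == pytest.approx(vals_r[k], rel=1e-9), (k, axes)

    def test_translation_invariance(self, rng):
        levels = rng.integers(1, 4, size=(4, 4, 4))
        big = np.ones((9, 9, 9), dtype=np.int32)
        mask = np.zeros((9, 9, 9), dtype=bool)
        big[1:5, 1:5, 1:5] = levels
        mask[1:5, 1:5, 1:5] = True
        v1, _ = compute_texture_features(compute_texture_matrices(_dv(big, mask, 3)))
        big2 = np.roll(big, (3, 2, 4), axis=(0, 1, 2))
        mask2 = np.roll(mask, (3, 2, 4), axis=(0, 1, 2))
        v2, _ = compute_texture_features(compute_texture_matrices(_dv(big2, mask2, 3)))
        for k in v1:
            assert v1[k] == pytest.approx(v2[k], rel=1e-12)


class TestCensusAndAliases:
    def test_feature_census_and_family_counts(self, default_phantom):
        _, post, masks = default_phantom
        fv = extract_voi(
            post, masks["tumoral"], NormalizationSpec("fixed_bin_number"),
            masks["wm_reference"], masks["vitreous_reference"],
        )
        counts = fv.family_counts()
        assert len(fv.values) == 180
        assert counts == {"shape": 24, "intensity": 19, "texture": 137}

    def test_extraction_is_deterministic(self, default_phantom):
        _, post, masks = default_phantom
        spec = NormalizationSpec("linear_two_point")
        fv1 = extract_voi(post, masks["tumoral"], spec, masks["wm_reference"], masks["vitreous_reference"])
        fv2 = extract_voi(post, masks["tumoral"], spec, masks["wm_reference"], masks["vitreous_reference"])
        assert fv1.values == fv2.values

    def test_no_wavelet_features_present(self):
        assert not any("wavelet" in n.lower() for n in TEXTURE_FEATURES)

    def test_literature_names_resolve_to_present_features(self):
        for lit, canonical in ALIASES.items():
            assert resolve(lit) == canonical

    def test_fixed_bin_number_features_are_affine_invariant(self, default_phantom):
        _, post, masks = default_phantom
        spec = NormalizationSpec("fixed_bin_number")
        fv1 = extract_voi(post, masks["tumoral"], spec)
        post2 = VoxelGrid(3.0 * post.values + 11.0, post.spacing, post.origin)
        fv2 = extract_voi(post2, masks["tumoral"], spec)
        for name, v in fv1.values.items():
            if name.startswith("shape_"):
                continue
            assert v == pytest.approx(fv2.values[name], rel=1e-6), name
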