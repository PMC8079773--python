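"""Resampling, two-point normalization and both discretization schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliorad.grids import VoiMask, VoxelGrid
from gliorad.preprocess import (
    DegenerateIntensityWarning,
    NormalizationSpec,
    discretize_fixed_bin_number,
    discretize_fixed_bin_size,
    normalize_linear_two_point,
    resample_mask_trilinear,
    resample_trilinear,
)


def _grid(values, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(values, dtype=np.float64), spacing)


def _full_mask(grid, role="tumoral"):
    return VoiMask(np.ones(grid.shape), grid.spacing, role, grid.origin)


class TestResample:
    def test_constant_volume_stays_constant(self):
        g = _grid(np.full((10, 10, 10), 42.0), (0.8, 0.8, 2.0))
        out = resample_trilinear(g, 3.0)
        assert out.spacing == (3.0, 3.0, 3.0)
        np.testing.assert_allclose(out.values, 42.0, rtol=1e-12)

    def test_already_cubic_at_target_is_identity(self):
        rng = np.random.default_rng(0)
        g = _grid(rng.normal(size=(7, 7, 7)), (2.0, 2.0, 2.0))
        out = resample_trilinear(g, 2.0)
        np.testing.assert_allclose(out.values, g.values, rtol=1e-6)

    def test_linear_ramp_is_reproduced_exactly(self):
        # trilinear interpolation is exact for affine intensity fields
        x = np.arange(13, dtype=np.float64)
        ramp = np.broadcast_to(x[:, None, None], (13, 13, 13)).copy()
        g = _grid(ramp, (1.0, 1.0, 1.0))
        out = resample_trilinear(g, 3.0)
        expected = np.arange(out.shape[0]) * 3.0  # ramp value at new centres
        np.testing.assert_allclose(out.values[:, 0, 0], expected, atol=1e-6)

    def test_target_exceeding_extent_errors(self):
        g = _grid(np.zeros((3, 3, 3)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="extent"):
            resample_trilinear(g, 10.0)

    def test_mask_resampling_thresholds_at_half(self):
        m = np.zeros((12, 12, 12))
        m[3:9, 3:9, 3:9] = 1
        mask = VoiMask(m, (1.0, 1.0, 1.0), "tumoral")
        out = resample_mask_trilinear(mask, 2.0)
        assert out.values.dtype == bool
        # 6 mm cube keeps roughly its volume at 2 mm spacing
        assert 10 <= out.voxel_count <= 40


class TestFixedBinNumber:
    def test_range_endpoints_map_to_first_and_last_level(self, rng):
        vals = rng.uniform(10, 50, size=(6, 6, 6))
        vals[0, 0, 0], vals[5, 5, 5] = 10.0, 50.0
        g = _grid(vals)
        dv = discretize_fixed_bin_number(g, _full_mask(g), 32)
        assert dv.levels[0, 0, 0] == 1
        assert dv.levels[5, 5, 5] == 32
        assert dv.n_levels == 32

    def test_constant_region_warns_and_gets_level_one(self):
        g = _grid(np.full((4, 4, 4), 5.0))
        with pytest.warns(DegenerateIntensityWarning):
            dv = discretize_fixed_bin_number(g, _full_mask(g), 32)
        assert np.all(dv.levels[dv.mask] == 1)

    def test_equal_spaced_input_fills_bins_evenly(self):
        # 3200 values in an exact arithmetic sequence on [0, 1)
        seq = (np.arange(3200) / 3200.0).reshape((20, 16, 10))
        g = _grid(seq)
        dv = discretize_fixed_bin_number(g, _full_mask(g), 32)
        counts = np.bincount(dv.levels[dv.mask])[1:]
        assert len(counts) == 32
        # maximum maps into the top level: 100 everywhere except +-1 at the edge
        assert counts.sum() == 3200
        assert np.all(np.abs(counts - 100) <= 1)

    def test_affine_invariance(self, rng):
        vals = rng.uniform(size=(5, 5, 5))
        g1 = _grid(vals)
        g2 = _grid(2.5 * vals - 7.0)
        dv1 = discretize_fixed_bin_number(g1, _full_mask(g1), 16)
        dv2 = discretize_fixed_bin_number(g2, _full_mask(g2), 16)
        np.testing.assert_array_equal(dv1.levels, dv2.levels)


class TestLinearTwoPoint:
    def _setup(self, wm_value, vit_value):
        vals = np.full((8, 8, 8), 125.0)
        wm = np.zeros((8, 8, 8))
        wm[:2] = 1
        vit = np.zeros((8, 8, 8))
        vit[6:] = 1
        vals[wm.astype(bool)] = wm_value
        vals[vit.astype(bool)] = vit_value
        g = _grid(vals)
        return (
            g,
            VoiMask(wm, g.spacing, "wm_reference"),
            VoiMask(vit, g.spacing, "vitreous_reference"),
        )

    def test_solves_the_two_point_system(self):
        # wm 200 -> 300 and vitreous 50 -> 0 forces a=2, b=-100; 125 -> 150
        g, wm, vit = self._setup(200.0, 50.0)
        spec = NormalizationSpec("linear_two_point", anchor_wm=300.0, anchor_vitreous=0.0)
        out = normalize_linear_two_point(g, wm, vit, spec)
        assert out.values[4, 4, 4] == pytest.approx(150.0)
        assert out.values[wm.values].mean() == pytest.approx(300.0)
        assert out.values[vit.values].mean() == pytest.approx(0.0)

    def test_identity_when_references_already_anchored(self):
        g, wm, vit = self._setup(300.0, 0.0)
        spec = NormalizationSpec("linear_two_point", anchor_wm=300.0, anchor_vitreous=0.0)
        out = normalize_linear_two_point(g, wm, vit, spec)
        np.testing.assert_allclose(out.values, g.values, atol=1e-9)

    def test_affine_invariance_of_the_normalized_output(self):
        g, wm, vit = self._setup(200.0, 50.0)
        spec = NormalizationSpec("linear_two_point")
        out1 = normalize_linear_two_point(g, wm, vit, spec)
        g2 = VoxelGrid(2.0 * g.values + 7.0, g.spacing)
        out2 = normalize_linear_two_point(g2, wm, vit, spec)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-6)

    def test_idempotence(self):
        g, wm, vit = self._setup(200.0, 50.0)
        spec = NormalizationSpec("linear_two_point")
        once = normalize_linear_two_point(g, wm, vit, spec)
        twice = normalize_linear_two_point(once, wm, vit, spec)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)

    def test_equal_reference_means_degenerate(self):
        g, wm, vit = self._setup(100.0, 100.0)
        with pytest.raises(ValueError, match="degenerate"):
            normalize_linear_two_point(g, wm, vit, NormalizationSpec("linear_two_point"))


class TestFixedBinSize:
    def test_direct_formula_evaluation(self):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [0.0, 49.9, 50.0, 149.0]
        g = _grid(vals)
        dv = discretize_fixed_bin_size(g, _full_mask(g), 50.0)
        assert list(dv.levels[:, 0, 0]) == [1, 1, 2, 3]
        assert dv.n_levels == 3

    def test_constant_region_single_level(self):
        g = _grid(np.full((3, 3, 3), 77.0))
        dv = discretize_fixed_bin_size(g, _full_mask(g), 50.0)
        assert dv.n_levels == 1

    def test_range_1600_gives_33_levels(self):
        # bin size 50 over a 1600-unit range stays comparable to 32 bins
        vals = np.linspace(0.0, 1600.0, 64).reshape((4, 4, 4))
        g = _grid(vals)
        dv = discretize_fixed_bin_size(g, _full_mask(g), 50.0)
        assert dv.n_levels == 33


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.lists(st.floats(-1e3, 1e3), min_size=8, max_size=8),
    scheme=st.sampled_from(["number", "size"]),
)
def test_discretization_is_monotone(data, scheme):
    """I1 <= I2 implies level(I1) <= level(I2) for both schemes."""
    import warnings

    vals = np.array(data).reshape((2, 2, 2))
    g = _grid(vals)
    mask = _full_mask(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if scheme == "number":
            dv = discretize_fixed_bin_number(g, mask, 8)
        else:
            dv = discretize_fixed_bin_size(g, mask, 100.0)
    flat_vals = vals.ravel()
    flat_levels = dv.levels.ravel()
    order = np.argsort(flat_vals, kind="stable")
    assert np.all(np.diff(flat_levels[order]) >= 0)
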