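import math

import numpy as np
import pytest

from terraflux import ElevationRaster
from terraflux.terrain import (
    ATTRIBUTE_NAMES,
    aggregate_dem,
    build_pyramid,
    compute_attributes,
    disaggregate,
    extract_at_positions,
    smooth_dem,
)


def flat(value=2.0, shape=(12, 12), cs=1.0):
    return ElevationRaster(np.full(shape, value), cs)


# ------------------------------------------------------------- aggregation
class TestAggregate:
    def test_constant_survives(self):
        out = aggregate_dem(flat(3.0), 2)
        np.testing.assert_array_equal(out.values, 3.0)
        assert out.cell_size == 2.0

    def test_block_mean(self):
        out = aggregate_dem(ElevationRaster([[1.0, 2.0], [3.0, 4.0]], 1.0), 2)
        assert out.values.shape == (1, 1)
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_mean_preserved_even_dims(self):
        rng = np.random.default_rng(0)
        dem = ElevationRaster(rng.normal(size=(16, 24)), 0.5)
        out = aggregate_dem(dem, 4)
        assert out.values.mean() == pytest.approx(dem.values.mean(), abs=1e-12)

    def test_all_missing_block_stays_missing(self):
        vals = np.ones((4, 4))
        vals[:2, :2] = np.nan
        out = aggregate_dem(ElevationRaster(vals, 1.0), 2)
        assert np.isnan(out.values[0, 0]) and out.values[1, 1] == 1.0

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            aggregate_dem(flat(), 1)


# --------------------------------------------------------------- smoothing
class TestSmooth:
    def test_constant_unchanged(self):
        out = smooth_dem(flat(5.0), "box", 3)
        np.testing.assert_allclose(out.values, 5.0)

    def test_box_impulse_response(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 1.0
        out = smooth_dem(ElevationRaster(vals, 1.0), "box", 3)
        np.testing.assert_allclose(out.values[3:6, 3:6], 1 / 9, atol=1e-12)
        assert out.values[0, 0] == 0.0

    def test_width_one_is_identity(self):
        dem = ElevationRaster(np.random.default_rng(1).normal(size=(6, 6)), 1.0)
        for kernel in ("box", "gaussian"):
            np.testing.assert_array_equal(smooth_dem(dem, kernel, 1).values, dem.values)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            smooth_dem(flat(), "box", 4)


# -------------------------------------------------------------- attributes
class TestAttributes:
    def test_flat_raster_all_zero(self):
        attrs = compute_attributes(flat(7.0), 3)
        np.testing.assert_allclose(attrs["Sl"].values, 0.0)
        np.testing.assert_allclose(attrs["TPI"].values, 0.0, atol=1e-12)
        np.testing.assert_allclose(attrs["SD"].values, 0.0, atol=1e-12)
        np.testing.assert_allclose(attrs["mALT"].values, 7.0)
        np.testing.assert_allclose(attrs["North"].values, 0.0)

    def test_east_facing_plane(self):
        """z = 0.01 x: interior slope atan(0.01), downslope faces west."""
        nx, ny, cs = 20, 15, 1.0
        x = (np.arange(nx) + 0.5) * cs
        dem = ElevationRaster(np.tile(0.01 * x, (ny, 1)), cs)
        attrs = compute_attributes(dem, 3)
        interior = (slice(1, -1), slice(1, -1))
        expected = math.degrees(math.atan(0.01))
        np.testing.assert_allclose(attrs["Sl"].values[interior], expected, rtol=1e-9)
        np.testing.assert_allclose(attrs["East"].values[interior], -1.0, atol=1e-12)
        np.testing.assert_allclose(attrs["North"].values[interior], 0.0, atol=1e-12)

    def test_peak_tpi_sign(self):
        vals = np.zeros((7, 7))
        vals[3, 3] = 1.0
        attrs = compute_attributes(ElevationRaster(vals, 1.0), 3)
        assert attrs["TPI"].values[3, 3] == pytest.approx(1.0)
        assert (attrs["TPI"].values[2:5, 2:5].ravel()[[0, 1, 2, 3, 5, 6, 7, 8]] < 0).all()

    def test_aspect_unit_vector_where_sloped(self):
        rng = np.random.default_rng(2)
        dem = ElevationRaster(rng.normal(size=(15, 15)), 1.0)
        attrs = compute_attributes(dem, 3)
        sl = attrs["Sl"].values
        norm = attrs["North"].values ** 2 + attrs["East"].values ** 2
        np.testing.assert_allclose(norm[sl > 0], 1.0, atol=1e-9)

    def test_tpi_zero_mean_under_periodic_boundaries(self):
        rng = np.random.default_rng(3)
        dem = ElevationRaster(rng.normal(size=(32, 32)), 1.0)
        attrs = compute_attributes(dem, 3, boundary="wrap")
        assert abs(attrs["TPI"].values.mean()) < 1e-6 * dem.values.std()

    def test_window_larger_than_raster_rejected(self):
        with pytest.raises(ValueError):
            compute_attributes(flat(shape=(2, 2)), 3)


# ------------------------------------------------------------ disaggregate
class TestDisaggregate:
    def test_single_cell_replication(self):
        out = disaggregate(ElevationRaster([[7.0]], 2.0), 1.0)
        np.testing.assert_array_equal(out.values, np.full((2, 2), 7.0))

    def test_roundtrip_constant(self):
        dem = flat(4.0, shape=(6, 6))
        back = disaggregate(aggregate_dem(dem, 2), dem.cell_size)
        np.testing.assert_array_equal(back.values, dem.values)

    def test_block_means_match_coarse(self):
        rng = np.random.default_rng(4)
        coarse = ElevationRaster(rng.normal(size=(5, 4)), 2.0)
        fine = disaggregate(coarse, 1.0)
        again = aggregate_dem(fine, 2)
        np.testing.assert_allclose(again.values, coarse.values, atol=1e-12)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            disaggregate(ElevationRaster([[1.0]], 1.0), 0.3)


# ----------------------------------------------------------------- pyramid
@pytest.fixture(scope="module")
def dem0():
    rng = np.random.default_rng(5)
    base = rng.normal(size=(150, 200)).cumsum(axis=0).cumsum(axis=1)
    return ElevationRaster(base / np.abs(base).max(), 0.2)


class TestPyramid:
    def test_native_resolutions(self, dem0):
        stack = build_pyramid(dem0, max_level=7)
        got = [stack.native_resolution[lv] for lv in range(1, 8)]
        assert got == pytest.approx([0.2, 0.4, 0.8, 1.6, 3.2, 6.4, 10.0])

    def test_constant_dem_trivial_attributes(self):
        stack = build_pyramid(flat(1.0, shape=(60, 80), cs=0.2), max_level=3)
        for level in stack.level_ids:
            np.testing.assert_allclose(stack.levels[level]["Sl"].values, 0.0)
            np.testing.assert_allclose(stack.levels[level]["TPI"].values, 0.0, atol=1e-12)
            np.testing.assert_allclose(stack.levels[level]["SD"].values, 0.0, atol=1e-12)

    def test_level_attributes_match_stepwise_oracle(self, dem0):
        """Pipeline output at level 3 equals aggregate-aggregate-compute-disaggregate
        assembled by hand from the primitive operations."""
        stack = build_pyramid(dem0, max_level=3)
        dem3 = aggregate_dem(aggregate_dem(dem0, 2), 2)
        attrs = compute_attributes(dem3, 3)
        for name in ATTRIBUTE_NAMES:
            manual = disaggregate(attrs[name], dem0.cell_size)
            np.testing.assert_allclose(
                stack.levels[3][name].values,
                manual.values[: dem0.ny, : dem0.nx],
                atol=1e-12,
                err_msg=name,
            )

    def test_elevation_variance_nonincreasing_with_level(self, dem0):
        stack = build_pyramid(dem0, max_level=5)
        variances = [np.nanvar(stack.levels[lv]["mALT"].values) for lv in range(1, 6)]
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))

    def test_too_small_for_campaign_level(self):
        # 20 x 20 m supports the 6.4 m level but not 3 cells at 10 m
        with pytest.raises(ValueError, match="level 7"):
            build_pyramid(flat(shape=(100, 100), cs=0.2), max_level=7)


# -------------------------------------------------------------- extraction
class TestExtraction:
    def test_shape_contract(self, dataset):
        dem, _, panel = dataset
        stack = build_pyramid(dem, max_level=5)
        table = extract_at_positions(stack, panel.positions)
        assert len(table) == 78
        attr_cols = [c for c in table.columns if "_L" in c]
        assert len(attr_cols) == 5 * 6

    def test_matches_manual_indexing(self, dataset):
        dem, _, panel = dataset
        stack = build_pyramid(dem, max_level=2)
        table = extract_at_positions(stack, panel.positions)
        rng = np.random.default_rng(6)
        for i in rng.choice(len(table), 5, replace=False):
            row = table.iloc[i]
            r, c = stack.base.index_of(row["x"], row["y"])
            for name in ATTRIBUTE_NAMES:
                assert row[f"{name}_L2"] == stack.levels[2][name].values[r, c]

    def test_position_outside_extent_rejected(self, dataset):
        dem, _, panel = dataset
        stack = build_pyramid(dem, max_level=1)
        bad = panel.positions.copy()
        bad.loc[0, "x"] = -5.0
        with pytest.raises(IndexError):
            extract_at_positions(stack, bad)
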