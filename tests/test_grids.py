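"""Raster stack handling: slice selection, resampling, sea-level masking."""

import numpy as np
import pytest
import xarray as xr

from paleohab.errors import InvalidConfigError, ModeMismatchError, OutOfRangeError
from paleohab.grids import (
    SeaLevelCurve,
    apply_sealevel_mask,
    resample,
    round_age_to_slice,
)

from conftest import toy_stack


def grid2d(values, lats, lons, name="bio01"):
    return xr.DataArray(
        np.asarray(values, float),
        coords={"lat": np.asarray(lats, float), "lon": np.asarray(lons, float)},
        dims=("lat", "lon"),
        name=name,
    )


class TestSliceSelection:
    @pytest.mark.parametrize(
        "mid_age,expected", [(63.4, 63), (62.5, 63), (63.0, 63), (61.9, 62)]
    )
    def test_nearest_rounding_ties_away_from_zero(self, mid_age, expected):
        assert round_age_to_slice(mid_age) == expected

    def test_slice_at_returns_matching_age(self):
        stack = toy_stack({a: np.full((4, 4), a) for a in (60, 61, 62, 63)})
        sl = stack.slice_at(62.5)
        assert float(sl["age"]) == 63.0
        assert np.all(sl["bio01"].values == 63.0)

    def test_age_beyond_oldest_slice_errors(self):
        stack = toy_stack({a: np.zeros((4, 4)) for a in (60, 61, 62)})
        with pytest.raises(OutOfRangeError):
            stack.slice_at(70.0)
        with pytest.raises(OutOfRangeError):
            stack.slice_at(59.4)


class TestResample:
    lats = np.array([0.25, 0.75, 1.25, 1.75])
    lons = np.array([30.25, 30.75, 31.25, 31.75])

    @pytest.mark.parametrize("mode,factor", [("bilinear", 2), ("nearest", 3)])
    def test_constant_grid_stays_constant(self, mode, factor):
        g = grid2d(np.full((4, 4), 7.5), self.lats, self.lons)
        out = resample(g, factor, mode)
        assert out.shape == (4 * factor, 4 * factor)
        assert np.allclose(out.values, 7.5)

    def test_bilinear_reproduces_planar_field_exactly(self):
        la, lo = np.meshgrid(self.lats, self.lons, indexing="ij")
        g = grid2d(2.0 * lo - 3.0 * la + 1.0, self.lats, self.lons)
        out = resample(g, 4, "bilinear")
        la2, lo2 = np.meshgrid(out["lat"].values, out["lon"].values, indexing="ij")
        assert np.max(np.abs(out.values - (2.0 * lo2 - 3.0 * la2 + 1.0))) < 1e-10

    def test_extent_preserved_and_cell_count_scales(self):
        g = grid2d(np.random.default_rng(0).normal(size=(4, 4)), self.lats, self.lons)
        out = resample(g, 5, "bilinear")
        # outer cell edges identical
        for ax, orig in (("lat", self.lats), ("lon", self.lons)):
            step_in = orig[1] - orig[0]
            new = out[ax].values
            step_out = new[1] - new[0]
            assert np.isclose(step_out, step_in / 5)
            assert np.isclose(new[0] - step_out / 2, orig[0] - step_in / 2)
            assert np.isclose(new[-1] + step_out / 2, orig[-1] + step_in / 2)
        assert out.size == g.size * 25

    def test_interior_matches_bruteforce_bilinear(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 6))
        lats = 0.5 + np.arange(5) * 0.5
        lons = 30.0 + np.arange(6) * 0.5
        g = grid2d(vals, lats, lons)
        out = resample(g, 3, "bilinear")

        def brute(lat, lon):
            i = np.clip(np.searchsorted(lats, lat) - 1, 0, len(lats) - 2)
            j = np.clip(np.searchsorted(lons, lon) - 1, 0, len(lons) - 2)
            ty = (lat - lats[i]) / (lats[i + 1] - lats[i])
            tx = (lon - lons[j]) / (lons[j + 1] - lons[j])
            return (
                vals[i, j] * (1 - ty) * (1 - tx)
                + vals[i + 1, j] * ty * (1 - tx)
                + vals[i, j + 1] * (1 - ty) * tx
                + vals[i + 1, j + 1] * ty * tx
            )

        for ii, lat in enumerate(out["lat"].values):
            for jj, lon in enumerate(out["lon"].values):
                if lats[0] <= lat <= lats[-1] and lons[0] <= lon <= lons[-1]:
                    assert abs(out.values[ii, jj] - brute(lat, lon)) < 1e-10

    def test_nearest_keeps_category_set(self):
        rng = np.random.default_rng(2)
        cats = rng.integers(0, 5, size=(4, 4)).astype(float)
        g = grid2d(cats, self.lats, self.lons, name="biome")
        out = resample(g, 3, "nearest")
        assert set(np.unique(out.values)) <= set(np.unique(cats))

    def test_bilinear_on_categorical_rejected(self):
        g = grid2d(np.zeros((4, 4)), self.lats, self.lons, name="biome")
        with pytest.raises(ModeMismatchError):
            resample(g, 2, "bilinear")

    def test_invalid_factor(self):
        g = grid2d(np.zeros((4, 4)), self.lats, self.lons)
        with pytest.raises(InvalidConfigError):
            resample(g, 0, "bilinear")


class TestSeaLevelCurve:
    curve = SeaLevelCurve(np.array([0.0, 10.0, 20.0, 30.0]), np.array([0.0, -40.0, -120.0, -60.0]))

    def test_tabulated_age_exact(self):
        assert self.curve.level_at(20.0) == -120.0

    def test_linear_interpolation_between_neighbours(self):
        # hand interpolation between (10, -40) and (20, -120): at 12.5 ka
        assert np.isclose(self.curve.level_at(12.5), -40.0 + 0.25 * (-80.0))

    def test_outside_span_errors(self):
        with pytest.raises(OutOfRangeError):
            self.curve.level_at(31.0)

    def test_stage_mean_is_trapezoidal_average(self):
        # over [0, 20]: piecewise linear, mean = (mean(0,-40)*10 + mean(-40,-120)*10)/20
        assert np.isclose(self.curve.stage_mean(0.0, 20.0), (-20.0 * 10 - 80.0 * 10) / 20)

    def test_nonincreasing_ages_rejected(self):
        with pytest.raises(InvalidConfigError):
            SeaLevelCurve(np.array([5.0, 5.0, 10.0]), np.zeros(3))


class TestSeaLevelMask:
    lats = np.array([0.25, 0.75])
    lons = np.array([30.25, 30.75])

    def make(self, elev):
        g = grid2d(np.arange(4.0).reshape(2, 2), self.lats, self.lons)
        e = grid2d(elev, self.lats, self.lons, name="elevation")
        return g, e

    def test_shelf_exposed_at_lowstand(self):
        g, e = self.make([[-50.0, 10.0], [5.0, -130.0]])
        out = apply_sealevel_mask(g, e, sea_level_m=-120.0)
        # -50 m cell is land at -120 m sea level; -130 m cell is sea
        assert np.isfinite(out.values[0, 0])
        assert np.isnan(out.values[1, 1])

    def test_submerged_at_present_sea_level(self):
        g, e = self.make([[-50.0, 10.0], [5.0, -130.0]])
        out = apply_sealevel_mask(g, e, sea_level_m=0.0)
        assert np.isnan(out.values[0, 0])

    def test_coastline_tie_counts_as_sea(self):
        g, e = self.make([[0.0, 1.0], [1.0, 1.0]])
        out = apply_sealevel_mask(g, e, sea_level_m=0.0)
        assert np.isnan(out.values[0, 0])

    def test_masking_idempotent_and_monotone_in_sea_level(self):
        rng = np.random.default_rng(3)
        elev = rng.normal(0, 100, size=(2, 2))
        g, e = self.make(elev)
        prev_land = 5
        for sl in (-150.0, -50.0, 0.0, 50.0, 200.0):
            out = apply_sealevel_mask(g, e, sea_level_m=sl)
            twice = apply_sealevel_mask(out, e, sea_level_m=sl)
            assert np.array_equal(np.isnan(out.values), np.isnan(twice.values))
            land = int(np.isfinite(out.values).sum())
            assert land <= prev_land
            prev_land = land


def test_stack_netcdf_roundtrip(tmp_path, small_world):
    stack = small_world["stack"]
    path = tmp_path / "stack.nc"
    stack.to_netcdf(path)
    from paleohab.grids import ClimateStack

    back = ClimateStack.from_netcdf(path)
    for var in ("bio01", "bio12", "biome"):
        np.testing.assert_allclose(back.data[var].values, stack.data[var].values)
    np.testing.assert_allclose(back.ages, stack.ages)
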