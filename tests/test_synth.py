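"""Synthetic world generator: determinism, coherence, planted structure."""

import numpy as np
import pytest

from paleohab import (
    SyntheticConfig,
    generate_bathymetry_sealevel,
    generate_climate_stack,
    generate_occupations,
)
from paleohab.errors import InfeasiblePlacementError, InvalidConfigError
from paleohab.extraction import haversine_km
from paleohab.grids import apply_sealevel_mask
from paleohab.synth import classify_biome


def cfg(**kw):
    base = dict(
        grid_nlat=16,
        grid_nlon=16,
        lon_min=30.0,
        lon_max=46.0,
        lat_min=-8.0,
        lat_max=8.0,
        n_slices=30,
        age_start=60.0,
        n_occupations=10,
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_slices": 0},
            {"grid_nlat": 3},
            {"grid_nlon": 2},
            {"lon_min": 50.0, "lon_max": 40.0},
            {"n_biomes": 0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            cfg(**kw)


class TestClimateStack:
    def test_fixed_seed_determinism(self):
        a = generate_climate_stack(cfg(seed=7))
        b = generate_climate_stack(cfg(seed=7))
        for var in ("bio01", "bio12", "biome"):
            np.testing.assert_array_equal(a.data[var].values, b.data[var].values)

    def test_distinct_seeds_diverge(self):
        a = generate_climate_stack(cfg(seed=7))
        b = generate_climate_stack(cfg(seed=8))
        assert not np.array_equal(a.data["bio01"].values, b.data["bio01"].values)

    def test_zero_variance_gives_constant_temperature(self):
        stack = generate_climate_stack(cfg(temp_sd=0.0, temp_mean=17.5))
        assert np.all(stack.data["bio01"].values == 17.5)

    def test_precipitation_nonnegative_biomes_in_category_set(self):
        c = cfg(precip_mean=200.0, precip_sd=600.0)  # would go negative unclipped
        stack = generate_climate_stack(c)
        assert stack.data["bio12"].values.min() >= 0.0
        assert set(np.unique(stack.data["biome"].values.astype(int))) <= set(
            range(c.n_biomes)
        )

    def test_biome_is_deterministic_function_of_climate(self):
        c = cfg()
        stack = generate_climate_stack(c)
        expected = classify_biome(
            stack.data["bio01"].values, stack.data["bio12"].values, c
        )
        np.testing.assert_array_equal(stack.data["biome"].values.astype(int), expected)

    def test_correlogram_crosses_half_near_length_scale(self):
        # brute-force correlation over >=1e3 cell pairs, binned by separation
        c = SyntheticConfig(
            grid_nlat=40,
            grid_nlon=40,
            lon_min=30.0,
            lon_max=50.0,
            lat_min=-10.0,
            lat_max=10.0,
            n_slices=60,
            age_start=60.0,
            autocorr_length_km=250.0,
            seed=4,
        )
        stack = generate_climate_stack(c)
        vals = stack.data["bio01"].values.reshape(c.n_slices, -1)
        lats = np.repeat(c.lat_centres, c.grid_nlon)
        lons = np.tile(c.lon_centres, c.grid_nlat)
        rng = np.random.default_rng(0)
        ncell = vals.shape[1]
        ii = rng.integers(0, ncell, 40000)
        jj = rng.integers(0, ncell, 40000)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
        d = haversine_km(lons[ii], lats[ii], lons[jj], lats[jj])
        vc = vals - vals.mean(axis=0)
        num = (vc[:, ii] * vc[:, jj]).mean(axis=0)
        den = vc[:, ii].std(axis=0) * vc[:, jj].std(axis=0)
        corr = num / den
        bins = np.arange(0.0, 800.0, 50.0)
        mids, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (d >= lo) & (d < hi)
            if sel.sum() > 100:
                mids.append((lo + hi) / 2)
                means.append(corr[sel].mean())
        mids, means = np.array(mids), np.array(means)
        assert means[0] > 0.5 > means[-1]  # decreases with separation
        crossing = mids[np.argmax(means < 0.5)]
        assert 0.6 * c.autocorr_length_km <= crossing <= 1.5 * c.autocorr_length_km


class TestBathymetrySeaLevel:
    def test_curve_covers_stack_and_lookup_exact(self):
        c = cfg()
        elev, curve = generate_bathymetry_sealevel(c)
        assert curve.ages[0] <= c.ages.min() and curve.ages[-1] >= c.ages.max()
        k = 3
        assert curve.level_at(curve.ages[k]) == curve.levels[k]

    def test_interpolation_between_tabulated_ages(self):
        _, curve = generate_bathymetry_sealevel(cfg())
        a0, a1 = curve.ages[2], curve.ages[3]
        mid = (a0 + a1) / 2
        assert np.isclose(curve.level_at(mid), (curve.levels[2] + curve.levels[3]) / 2)

    def test_elevation_on_climate_grid(self):
        c = cfg()
        elev, _ = generate_bathymetry_sealevel(c)
        assert elev.shape == (c.grid_nlat, c.grid_nlon)
        np.testing.assert_allclose(elev["lat"].values, c.lat_centres)

    def test_all_positive_elevation_is_all_land(self):
        import xarray as xr

        c = cfg()
        elev, curve = generate_bathymetry_sealevel(c)
        pos = xr.DataArray(
            np.abs(elev.values) + 1.0, coords=elev.coords, dims=elev.dims
        )
        stack = generate_climate_stack(c)
        sl = stack.data.isel(age=0)["bio01"]
        for level in (-120.0, -50.0, 0.0):
            out = apply_sealevel_mask(sl, pos, sea_level_m=level)
            assert np.isfinite(out.values).all()


class TestOccupations:
    def test_determinism_and_on_land_at_mid_age(self):
        c = cfg(seed=5)
        stack = generate_climate_stack(c)
        elev, curve = generate_bathymetry_sealevel(c)
        recs1, truth1 = generate_occupations(stack, c, elev, curve)
        recs2, _ = generate_occupations(stack, c, elev, curve)
        assert [(r.lon, r.lat, r.age_min, r.age_max) for r in recs1] == [
            (r.lon, r.lat, r.age_min, r.age_max) for r in recs2
        ]
        for r in recs1:
            assert r.age_min < r.age_max
            sea = curve.level_at(r.mid_age)
            i = int(np.argmin(np.abs(c.lat_centres - r.lat)))
            j = int(np.argmin(np.abs(c.lon_centres - r.lon)))
            assert float(elev.values[i, j]) > sea

    def test_every_stage_in_span_receives_an_occupation(self):
        c = SyntheticConfig(
            grid_nlat=16, grid_nlon=16, lon_min=30, lon_max=46, lat_min=-8,
            lat_max=8, n_slices=270, age_start=300.0, n_occupations=12, seed=2,
        )
        stack = generate_climate_stack(c)
        elev, curve = generate_bathymetry_sealevel(c)
        recs, _ = generate_occupations(stack, c, elev, curve)
        stages = {r.mis() for r in recs}
        assert {"MIS3", "MIS4", "MIS5", "MIS6", "MIS7", "MIS8"} <= stages

    def test_infeasible_placement_errors(self):
        c = cfg(n_occupations=300)  # more than 16x16 cells can host
        stack = generate_climate_stack(c)
        elev, curve = generate_bathymetry_sealevel(c)
        with pytest.raises(InfeasiblePlacementError):
            generate_occupations(stack, c, elev, curve)

    def test_null_preference_matches_availability(self):
        # with biome_preference_logit = 0 the occupied-biome frequency of the
        # focal biome must track its land availability within binomial error
        c = cfg(biome_preference_logit=0.0, n_occupations=8, seed=1)
        stack = generate_climate_stack(c)
        elev, curve = generate_bathymetry_sealevel(c)
        n_rep = 200
        occupied_focal = 0
        total = 0
        fracs = []
        for rep in range(n_rep):
            c_rep = cfg(biome_preference_logit=0.0, n_occupations=8, seed=1000 + rep)
            recs, truth = generate_occupations(stack, c_rep, elev, curve)
            focal = truth["focal_biome"]
            occupied_focal += sum(1 for b in truth["biome_at_site"] if b == focal)
            total += len(recs)
            # availability of the focal biome at each occupation's mid-age
            for r in recs:
                biome = apply_sealevel_mask(
                    stack.slice_at(r.mid_age)["biome"], elev, curve, r.mid_age
                ).values
                land = biome[np.isfinite(biome)]
                fracs.append(np.mean(land == focal))
        p_avail = float(np.mean(fracs))
        p_hat = occupied_focal / total
        se = np.sqrt(p_avail * (1 - p_avail) / total)
        assert abs(p_hat - p_avail) < 4 * se

    def test_preference_enriches_focal_biome(self):
        c0 = cfg(biome_preference_logit=0.0, n_occupations=40, seed=3)
        c1 = cfg(biome_preference_logit=3.0, n_occupations=40, seed=3)
        stack = generate_climate_stack(c0)
        elev, curve = generate_bathymetry_sealevel(c0)
        _, t0 = generate_occupations(stack, c0, elev, curve)
        _, t1 = generate_occupations(stack, c1, elev, curve)
        f = t1["focal_biome"]
        n0 = sum(1 for b in t0["biome_at_site"] if b == f)
        n1 = sum(1 for b in t1["biome_at_site"] if b == f)
        assert n1 > n0
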