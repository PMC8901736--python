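import numpy as np
import pandas as pd
import pytest
import xarray as xr

from paleohab import (
    OccupationRecord,
    SyntheticConfig,
    generate_bathymetry_sealevel,
    generate_climate_stack,
    generate_occupations,
)
from paleohab.grids import ClimateStack


def make_record(occ_id="occ_001", lon=36.0, lat=0.0, age_min=60.0, age_max=70.0, **kw):
    rng = np.random.default_rng(0)
    return OccupationRecord(
        site=kw.pop("site", "site_01"),
        occ_id=occ_id,
        lon=lon,
        lat=lat,
        age_min=age_min,
        age_max=age_max,
        site_type=kw.pop("site_type", 0),
        method=kw.pop("method", 1),
        toolkit=kw.pop("toolkit", rng.integers(0, 2, 16)),
        raw_material=kw.pop("raw_material", rng.integers(0, 2, 8)),
    )


def toy_stack(values_by_age, lats=None, lons=None, variables=("bio01",)):
    """Build a small stack from {age: 2-D array} (same array for each variable)."""
    ages = sorted(values_by_age, reverse=True)
    arr = np.stack([np.asarray(values_by_age[a], float) for a in ages])
    nlat, nlon = arr.shape[1:]
    lats = np.linspace(-1.0, 1.0, nlat) if lats is None else np.asarray(lats)
    lons = np.linspace(35.0, 37.0, nlon) if lons is None else np.asarray(lons)
    data = {v: (("age", "lat", "lon"), arr.copy()) for v in variables}
    ds = xr.Dataset(data, coords={"age": np.asarray(ages, float), "lat": lats, "lon": lons})
    return ClimateStack(ds)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        grid_nlat=20,
        grid_nlon=24,
        lon_min=30.0,
        lon_max=54.0,
        lat_min=-8.0,
        lat_max=12.0,
        n_slices=40,
        age_start=80.0,
        n_occupations=16,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    stack = generate_climate_stack(small_config)
    elevation, curve = generate_bathymetry_sealevel(small_config)
    records, truth = generate_occupations(stack, small_config, elevation, curve)
    return {
        "config": small_config,
        "stack": stack,
        "elevation": elevation,
        "curve": curve,
        "records": records,
        "truth": truth,
    }
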