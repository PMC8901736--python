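"""Raster time-stack handling.

Grids are regular lon/lat fields stored in :class:`xarray.DataArray` /
:class:`xarray.Dataset` containers with cell-centre registration: the
coordinate arrays hold cell-centre positions, and the extent of a grid is
defined by the outer cell edges (centre +/- half a step on each axis).
Missing values (sea, or outside the study region) are encoded as NaN; the
``biome`` variable carries integer category codes stored as floats so that
NaN masking composes uniformly across variables.

A climate stack is a Dataset with dimensions ``(age, lat, lon)`` and data
variables ``bio01`` (mean annual temperature, degC), ``bio12`` (total annual
precipitation, mm) and ``biome`` (categorical). Ages are in ka BP at 1-kyr
spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

from .errors import InvalidConfigError, ModeMismatchError, OutOfRangeError

CATEGORICAL_VARS = frozenset({"biome"})
CLIMATE_VARS = ("bio01", "bio12", "biome")


def round_age_to_slice(age_ka: float) -> int:
    """Round an age to the nearest integer kyr, ties away from zero."""
    return int(math.floor(abs(age_ka) + 0.5) * (1 if age_ka >= 0 else -1))


def _check_regular(axis: np.ndarray, name: str) -> float:
    if axis.ndim != 1 or axis.size < 2:
        raise InvalidConfigError(f"{name} axis must be 1-D with >=2 points")
    steps = np.diff(axis)
    if not (np.all(steps > 0) or np.all(steps < 0)):
        raise InvalidConfigError(f"{name} axis must be strictly monotone")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise InvalidConfigError(f"{name} axis must be regularly spaced")
    return float(steps[0])


@dataclass
class ClimateStack:
    """Time-indexed set of co-registered climate grids at 1-kyr spacing."""

    data: xr.Dataset

    def __post_init__(self) -> None:
        ds = self.data
        for dim in ("age", "lat", "lon"):
            if dim not in ds.dims:
                raise InvalidConfigError(f"stack missing dimension {dim!r}")
        ages = np.asarray(ds["age"].values, dtype=float)
        if len(np.unique(ages)) != len(ages):
            raise InvalidConfigError("stack ages must be unique")
        if ages.size > 1 and not np.allclose(np.abs(np.diff(ages)), 1.0):
            raise InvalidConfigError("stack ages must be at 1-kyr spacing")
        _check_regular(np.asarray(ds["lat"].values, float), "lat")
        _check_regular(np.asarray(ds["lon"].values, float), "lon")

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.data["age"].values, dtype=float)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for v in CLIMATE_VARS if v in self.data)

    def slice_at(self, mid_age: float) -> xr.Dataset:
        """Return the slice whose age equals ``mid_age`` rounded to 1 kyr.

        Ties (x.5 ka) round away from zero.
        """
        target = round_age_to_slice(mid_age)
        ages = self.ages
        if target < ages.min() or target > ages.max():
            raise OutOfRangeError(
                f"rounded age {target} ka outside stack span "
                f"[{ages.min():g}, {ages.max():g}] ka"
            )
        idx = np.nonzero(ages == target)[0]
        if idx.size == 0:
            raise OutOfRangeError(f"no slice at {target} ka")
        return self.data.isel(age=int(idx[0]))

    def to_netcdf(self, path) -> None:
        self.data.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "ClimateStack":
        return cls(xr.load_dataset(path, engine="scipy"))


def slice_at(stack: ClimateStack, mid_age: float) -> xr.Dataset:
    """Module-level alias for :meth:`ClimateStack.slice_at`."""
    return stack.slice_at(mid_age)


def _axis_edges(axis: np.ndarray) -> tuple[float, float, float]:
    step = _check_regular(axis, "axis")
    return axis[0] - step / 2.0, axis[-1] + step / 2.0, step


def refined_axis(axis: np.ndarray, factor: int) -> np.ndarray:
    """Cell-centre axis after refining by ``factor``, same outer extent."""
    lo, _hi, step = _axis_edges(axis)
    new_step = step / factor
    n = axis.size * factor
    return lo + (np.arange(n) + 0.5) * new_step


def resample(grid: xr.DataArray, factor: int, mode: str) -> xr.DataArray:
    """Refine a lon/lat grid by an integer factor.

    ``bilinear`` interpolates from the four surrounding input cell centres
    (linear extrapolation in the outer half-cell rim so that planar fields
    are reproduced exactly); ``nearest`` copies the closest input cell and is
    mandatory for categorical variables.
    """
    if factor < 1 or int(factor) != factor:
        raise InvalidConfigError("resample factor must be a positive integer")
    if mode not in ("bilinear", "nearest"):
        raise InvalidConfigError(f"unknown resample mode {mode!r}")
    if grid.name in CATEGORICAL_VARS and mode != "nearest":
        raise ModeMismatchError(
            f"categorical variable {grid.name!r} requires nearest-neighbour resampling"
        )
    factor = int(factor)
    lat = np.asarray(grid["lat"].values, float)
    lon = np.asarray(grid["lon"].values, float)
    new_lat = refined_axis(lat, factor)
    new_lon = refined_axis(lon, factor)
    if factor == 1:
        return grid.copy()

    values = np.asarray(grid.values, float)
    # RegularGridInterpolator needs ascending axes.
    lat_order = slice(None) if lat[1] > lat[0] else slice(None, None, -1)
    lon_order = slice(None) if lon[1] > lon[0] else slice(None, None, -1)
    interp = RegularGridInterpolator(
        (lat[lat_order], lon[lon_order]),
        values[lat_order, lon_order],
        method="linear" if mode == "bilinear" else "nearest",
        bounds_error=False,
        fill_value=None,
    )
    mlat, mlon = np.meshgrid(new_lat, new_lon, indexing="ij")
    if mode == "nearest":
        # clamp into the centre hull so the rim copies the edge cells
        mlat = np.clip(mlat, min(lat[0], lat[-1]), max(lat[0], lat[-1]))
        mlon = np.clip(mlon, min(lon[0], lon[-1]), max(lon[0], lon[-1]))
    out = interp(np.stack([mlat.ravel(), mlon.ravel()], axis=-1)).reshape(mlat.shape)
    return xr.DataArray(
        out,
        coords={"lat": new_lat, "lon": new_lon},
        dims=("lat", "lon"),
        name=grid.name,
        attrs=dict(grid.attrs),
    )


@dataclass
class SeaLevelCurve:
    """Global sea level (m relative to present) against age (ka BP)."""

    ages: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.ages.ndim != 1 or self.ages.size < 2:
            raise InvalidConfigError("sea-level curve needs >=2 points")
        if not np.all(np.diff(self.ages) > 0):
            raise InvalidConfigError("sea-level curve ages must be strictly increasing")
        if not np.all(np.isfinite(self.levels)):
            raise InvalidConfigError("sea-level curve levels must be finite")

    def level_at(self, age_ka: float) -> float:
        """Linearly interpolated sea level; error outside the tabulated span."""
        if age_ka < self.ages[0] or age_ka > self.ages[-1]:
            raise OutOfRangeError(
                f"age {age_ka} ka outside sea-level curve span "
                f"[{self.ages[0]:g}, {self.ages[-1]:g}] ka"
            )
        return float(np.interp(age_ka, self.ages, self.levels))

    def stage_mean(self, young_ka: float, old_ka: float) -> float:
        """Arithmetic mean of the piecewise-linear curve over [young, old]."""
        if young_ka >= old_ka:
            raise InvalidConfigError("stage interval needs young < old")
        lo = self.level_at(young_ka)  # also validates coverage
        hi = self.level_at(old_ka)
        inner = self.ages[(self.ages > young_ka) & (self.ages < old_ka)]
        xs = np.concatenate([[young_ka], inner, [old_ka]])
        ys = np.concatenate([[lo], np.interp(inner, self.ages, self.levels), [hi]])
        return float(np.trapezoid(ys, xs) / (old_ka - young_ka))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_ka": self.ages, "level_m": self.levels}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "SeaLevelCurve":
        df = pd.read_csv(path)
        return cls(df["age_ka"].to_numpy(), df["level_m"].to_numpy())


def apply_sealevel_mask(
    grid: xr.DataArray,
    elevation: xr.DataArray,
    curve: SeaLevelCurve | None = None,
    age_ka: float | None = None,
    sea_level_m: float | None = None,
) -> xr.DataArray:
    """Mask cells that are sea at the given age (elevation <= sea level).

    The coastline tie (elevation exactly equal to sea level) counts as sea.
    Either an explicit ``sea_level_m`` or a curve plus age must be given.
    Elevation must be co-registered with the grid (resample first if needed).
    """
    if sea_level_m is None:
        if curve is None or age_ka is None:
            raise InvalidConfigError("need sea_level_m, or curve and age_ka")
        sea_level_m = curve.level_at(age_ka)
    if grid.shape != elevation.shape:
        raise InvalidConfigError("elevation grid not co-registered with climate grid")
    if not (
        np.allclose(grid["lat"].values, elevation["lat"].values)
        and np.allclose(grid["lon"].values, elevation["lon"].values)
    ):
        raise InvalidConfigError("elevation axes differ from climate grid axes")
    sea = np.asarray(elevation.values, float) <= sea_level_m
    return grid.where(~xr.DataArray(sea, coords=grid.coords, dims=grid.dims))


def land_mask(elevation: xr.DataArray, sea_level_m: float) -> xr.DataArray:
    """Boolean land mask at a given sea level (tie counts as sea)."""
    return xr.DataArray(
        np.asarray(elevation.values, float) > sea_level_m,
        coords=elevation.coords,
        dims=elevation.dims,
        name="land",
    )
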