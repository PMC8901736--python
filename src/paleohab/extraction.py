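"""Logistical-landscape extraction.

Each dated occupation is summarised over its "logistical landscape": the set
of grid cells whose centres lie within a great-circle radius (default 50 km)
of the site, taken at the climate slice nearest the occupation's mid-age
(the midpoint of its dated range). Means and standard deviations over that
buffer are the per-occupation climate parameters used everywhere downstream.

Distances are haversine on a sphere of radius 6371.0088 km; buffer
membership is decided by cell centre. Standard deviations use the sample
(n-1) convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import EmptyBufferError, InvalidConfigError, OutOfRangeError
from .grids import ClimateStack, SeaLevelCurve, apply_sealevel_mask, resample

EARTH_RADIUS_KM = 6371.0088

N_TOOL_TYPES = 16
N_RAW_MATERIALS = 8
TOOL_COLUMNS = tuple(f"tool_{i:02d}" for i in range(1, N_TOOL_TYPES + 1))
RAW_COLUMNS = tuple(f"raw_{i}" for i in range(1, N_RAW_MATERIALS + 1))

#: Default Marine Isotope Stage boundaries, ka BP (young, old); standard
#: benthic oxygen-isotope chronology. A stage owns the half-open interval
#: (young, old]; the youngest tabulated stage also owns its young edge.
DEFAULT_MIS_TABLE: dict[str, tuple[float, float]] = {
    "MIS3": (29.0, 57.0),
    "MIS4": (57.0, 71.0),
    "MIS5": (71.0, 130.0),
    "MIS6": (130.0, 191.0),
    "MIS7": (191.0, 243.0),
    "MIS8": (243.0, 300.0),
    "MIS9": (300.0, 337.0),
}


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def buffer_cells(
    grid: xr.DataArray, lon: float, lat: float, radius_km: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ilat, ilon) of unmasked cells within ``radius_km`` of a point.

    Membership is by cell centre; the containing cell is always included when
    unmasked, even if the radius is smaller than half a cell diagonal.
    """
    if radius_km <= 0:
        raise InvalidConfigError("radius must be positive")
    lats = np.asarray(grid["lat"].values, float)
    lons = np.asarray(grid["lon"].values, float)
    step_lat = abs(lats[1] - lats[0])
    step_lon = abs(lons[1] - lons[0])
    lat_lo, lat_hi = min(lats[0], lats[-1]) - step_lat / 2, max(lats[0], lats[-1]) + step_lat / 2
    lon_lo, lon_hi = min(lons[0], lons[-1]) - step_lon / 2, max(lons[0], lons[-1]) + step_lon / 2
    if not (lat_lo <= lat <= lat_hi and lon_lo <= lon <= lon_hi):
        raise OutOfRangeError(f"point ({lon}, {lat}) outside grid extent")

    # search window: radius in degrees, padded by one cell
    dlat = radius_km / 111.195 + step_lat
    coslat = max(np.cos(np.radians(lat)), 1e-6)
    dlon = radius_km / (111.195 * coslat) + step_lon
    ilat = np.nonzero(np.abs(lats - lat) <= dlat)[0]
    ilon = np.nonzero(np.abs(lons - lon) <= dlon)[0]
    if ilat.size == 0 or ilon.size == 0:
        raise EmptyBufferError("no cells in search window")
    glat, glon = np.meshgrid(lats[ilat], lons[ilon], indexing="ij")
    dist = haversine_km(lon, lat, glon, glat)
    inside = dist <= radius_km
    # always include the containing cell
    ci = int(np.argmin(np.abs(lats - lat)))
    cj = int(np.argmin(np.abs(lons - lon)))
    values = np.asarray(grid.values, float)
    sel_i, sel_j = np.nonzero(inside)
    rows = ilat[sel_i]
    cols = ilon[sel_j]
    if not np.any((rows == ci) & (cols == cj)):
        rows = np.append(rows, ci)
        cols = np.append(cols, cj)
    ok = np.isfinite(values[rows, cols])
    rows, cols = rows[ok], cols[ok]
    if rows.size == 0:
        raise EmptyBufferError(
            f"no unmasked cells within {radius_km} km of ({lon}, {lat})"
        )
    order = np.lexsort((cols, rows))
    return rows[order], cols[order]


@dataclass(frozen=True)
class BufferSummary:
    """Mean/SD of one variable over one occupation's logistical landscape."""

    occ_id: str
    variable: str
    mean: float
    sd: float
    n_cells: int


def summarize_values(occ_id: str, variable: str, vals: np.ndarray) -> BufferSummary:
    vals = np.asarray(vals, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyBufferError(f"no values for {occ_id}/{variable}")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return BufferSummary(occ_id, variable, float(np.mean(vals)), sd, int(vals.size))


def summarize_buffer(
    stack: ClimateStack,
    occ: "OccupationRecord",
    variable: str,
    radius_km: float = 50.0,
    resample_factor: int = 1,
    elevation: xr.DataArray | None = None,
    curve: SeaLevelCurve | None = None,
) -> BufferSummary:
    """Buffer mean/SD of a (resampled, optionally sea-level-masked) slice."""
    sl = stack.slice_at(occ.mid_age)
    grid = sl[variable]
    mode = "nearest" if variable == "biome" else "bilinear"
    if resample_factor > 1:
        grid = resample(grid, resample_factor, mode)
    if elevation is not None and curve is not None:
        elev = elevation
        if resample_factor > 1:
            elev = resample(elevation, resample_factor, "bilinear")
        grid = apply_sealevel_mask(grid, elev, curve, occ.mid_age)
    rows, cols = buffer_cells(grid, occ.lon, occ.lat, radius_km)
    vals = np.asarray(grid.values, float)[rows, cols]
    return summarize_values(occ.occ_id, variable, vals)


def assign_mis(
    mid_age: float, table: dict[str, tuple[float, float]] | None = None
) -> str:
    """Stage label for a mid-age; boundaries belong to the younger stage."""
    table = table or DEFAULT_MIS_TABLE
    youngest = min(table.items(), key=lambda kv: kv[1][0])
    for name, (young, old) in table.items():
        if young < mid_age <= old:
            return name
        if name == youngest[0] and mid_age == young:
            return name
    bounds = [b for pair in table.values() for b in pair]
    raise OutOfRangeError(
        f"mid-age {mid_age} ka outside stage table span "
        f"[{min(bounds):g}, {max(bounds):g}] ka"
    )


@dataclass
class OccupationRecord:
    """One dated assemblage with its binary descriptors."""

    site: str
    occ_id: str
    lon: float
    lat: float
    age_min: float
    age_max: float
    site_type: int
    method: int
    toolkit: np.ndarray
    raw_material: np.ndarray

    def __post_init__(self) -> None:
        if not self.age_min < self.age_max:
            raise InvalidConfigError(
                f"{self.occ_id}: age_min must be < age_max "
                f"(got {self.age_min}, {self.age_max})"
            )
        self.toolkit = np.asarray(self.toolkit, int)
        self.raw_material = np.asarray(self.raw_material, int)
        for flags, n in ((self.toolkit, N_TOOL_TYPES), (self.raw_material, N_RAW_MATERIALS)):
            if flags.shape != (n,) or not np.isin(flags, (0, 1)).all():
                raise InvalidConfigError(f"{self.occ_id}: flags must be {n} binary values")

    @property
    def mid_age(self) -> float:
        return (self.age_min + self.age_max) / 2.0

    def mis(self, table: dict[str, tuple[float, float]] | None = None) -> str:
        return assign_mis(self.mid_age, table)


def records_to_frame(records: list[OccupationRecord]) -> pd.DataFrame:
    """Tidy occupation table (one row per occupation, documented schema)."""
    rows = []
    for r in records:
        row: dict = {
            "site": r.site,
            "occ_id": r.occ_id,
            "lon": r.lon,
            "lat": r.lat,
            "age_min_ka": r.age_min,
            "age_max_ka": r.age_max,
            "mid_age_ka": r.mid_age,
            "mis": r.mis(),
            "site_type": r.site_type,
            "method": r.method,
        }
        row.update({c: int(v) for c, v in zip(TOOL_COLUMNS, r.toolkit)})
        row.update({c: int(v) for c, v in zip(RAW_COLUMNS, r.raw_material)})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[OccupationRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            OccupationRecord(
                site=str(row["site"]),
                occ_id=str(row["occ_id"]),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                age_min=float(row["age_min_ka"]),
                age_max=float(row["age_max_ka"]),
                site_type=int(row["site_type"]),
                method=int(row["method"]),
                toolkit=np.array([row[c] for c in TOOL_COLUMNS], int),
                raw_material=np.array([row[c] for c in RAW_COLUMNS], int),
            )
        )
    return records


def read_occupations(path) -> list[OccupationRecord]:
    return frame_to_records(pd.read_csv(path))


def summaries_to_frame(summaries: list[BufferSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "occ_id": s.occ_id,
                "variable": s.variable,
                "mean": s.mean,
                "sd": s.sd,
                "n_cells": s.n_cells,
            }
            for s in summaries
        ]
    )
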