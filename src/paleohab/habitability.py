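"""Phased climate-envelope habitability persistence mapping.

For each occupational phase (Marine Isotope Stage) the inhabited climate
envelope is the [min, max] interval of the member occupations' buffer-mean
temperature or precipitation. Projecting that envelope through every 1-kyr
slice of the stage and counting, per cell, the percentage of slices whose
value lies inside the envelope yields a habitability persistence map:
100% marks landscape that stayed within occupied conditions for the whole
stage, 0% landscape that never did. The combined mode requires both
variables to be in range *in the same slice* before a slice counts (joint
suitability per interval), so the combined map can never exceed either
marginal map. Sea cells are masked at the stage-mean sea level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InvalidConfigError
from .extraction import BufferSummary
from .grids import ClimateStack, SeaLevelCurve

MODES = ("temperature", "precipitation", "combined")
MODE_VARS = {"temperature": "bio01", "precipitation": "bio12"}


@dataclass(frozen=True)
class Envelope:
    """Inhabited [lo, hi] range of one climate variable in one stage."""

    mis: str
    variable: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise InvalidConfigError("envelope needs lo <= hi")

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Inclusive in-range test (the envelope is built from realized values)."""
        v = np.asarray(values, float)
        return (v >= self.lo) & (v <= self.hi)


def phase_envelope(
    summaries: list[BufferSummary], mis: str, variable: str
) -> Envelope:
    """Min/max envelope over the buffer means of one stage's occupations."""
    means = [s.mean for s in summaries if s.variable == variable]
    if not means:
        raise InvalidConfigError(f"no occupations with {variable!r} summaries in {mis}")
    return Envelope(mis=mis, variable=variable, lo=min(means), hi=max(means))


@dataclass
class HabitabilityMap:
    """Grid of per-cell 'percentage of stage slices in envelope' values."""

    mis: str
    mode: str
    grid: xr.DataArray  # percentages 0-100, NaN over sea
    n_slices: int


def habitability_map(
    stack: ClimateStack,
    envelopes: dict[str, Envelope],
    mis_slices: list[float],
    mode: str = "combined",
    elevation: xr.DataArray | None = None,
    curve: SeaLevelCurve | None = None,
) -> HabitabilityMap:
    """Percentage of the stage's slices each land cell spends in envelope.

    ``envelopes`` maps variable name (bio01/bio12) to its stage envelope;
    ``mis_slices`` lists the stage's slice ages (ka). Sea cells are masked
    using the arithmetic stage-mean sea level when bathymetry and a curve
    are supplied.
    """
    if mode not in MODES:
        raise InvalidConfigError(f"unknown mode {mode!r}")
    ages = sorted(set(float(a) for a in mis_slices))
    if not ages:
        raise InvalidConfigError("empty slice set")
    needed = (
        [MODE_VARS[mode]] if mode in MODE_VARS else ["bio01", "bio12"]
    )
    for var in needed:
        if var not in envelopes:
            raise InvalidConfigError(f"missing envelope for {var!r}")

    counts = None
    for age in ages:
        sl = stack.slice_at(age)
        ok = None
        for var in needed:
            inside = envelopes[var].contains(np.asarray(sl[var].values, float))
            ok = inside if ok is None else (ok & inside)
        counts = ok.astype(int) if counts is None else counts + ok
    pct = 100.0 * counts / len(ages)

    template = stack.data.isel(age=0)["bio01"]
    grid = xr.DataArray(
        pct,
        coords={"lat": template["lat"].values, "lon": template["lon"].values},
        dims=("lat", "lon"),
        name=f"habitability_{mode}",
    )
    if elevation is not None and curve is not None:
        sea_level = curve.stage_mean(min(ages), max(ages)) if len(ages) > 1 else curve.level_at(ages[0])
        sea = np.asarray(elevation.values, float) <= sea_level
        grid = grid.where(~xr.DataArray(sea, coords=grid.coords, dims=grid.dims))
    mis = next(iter(envelopes.values())).mis
    return HabitabilityMap(mis=mis, mode=mode, grid=grid, n_slices=len(ages))


def persistence_summary(
    maps: list[HabitabilityMap], thresholds: tuple[float, ...] = (50.0, 80.0, 100.0)
) -> pd.DataFrame:
    """% of land area at or above each persistence threshold, per map."""
    rows = []
    for hm in maps:
        vals = np.asarray(hm.grid.values, float)
        land = vals[np.isfinite(vals)]
        for thr in thresholds:
            frac = float(np.mean(land >= thr)) * 100.0 if land.size else np.nan
            rows.append(
                {
                    "mis": hm.mis,
                    "mode": hm.mode,
                    "threshold_pct": thr,
                    "land_area_pct": frac,
                    "n_slices": hm.n_slices,
                }
            )
    return pd.DataFrame(rows)
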