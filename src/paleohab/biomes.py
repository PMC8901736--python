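"""Biome access, ecotones and occupied-vs-available comparisons.

For each occupation the biome grid (nearest-neighbour resampled to the
analysis resolution) is tallied within the 50 km logistical landscape: the
set of biome categories with at least one cell is what the group could
access, and a landscape touching two or more categories is *ecotonal*.
Regional availability pools, per occupational phase (MIS), the land-cell
biome fractions over the phase's occupied slices, so that the proportion of
occupations with access to a focal biome can be compared against how much
of the landscape that biome actually covered (two-sample proportion test),
and shifts of the available proportions through time can be tested for
independence (chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import chi2_contingency, norm

from .errors import (
    EmptyBufferError,
    InvalidConfigError,
    InvalidRegionError,
    UndefinedStatisticError,
)
from .extraction import OccupationRecord, buffer_cells
from .grids import ClimateStack, SeaLevelCurve, apply_sealevel_mask, resample


@dataclass
class BiomeProfile:
    """Per-biome cell counts within one occupation's logistical landscape."""

    occ_id: str
    counts: dict[int, int]
    n_cells: int

    @property
    def accessible(self) -> set[int]:
        return {b for b, c in self.counts.items() if c >= 1}

    @property
    def ecotonal(self) -> bool:
        return len(self.accessible) >= 2


def biome_profile(
    stack: ClimateStack,
    occ: OccupationRecord,
    radius_km: float = 50.0,
    resample_factor: int = 1,
    elevation: xr.DataArray | None = None,
    curve: SeaLevelCurve | None = None,
) -> BiomeProfile:
    """Tally biome categories in the buffer at the occupation's mid-age."""
    sl = stack.slice_at(occ.mid_age)
    grid = sl["biome"]
    if resample_factor > 1:
        grid = resample(grid, resample_factor, "nearest")
    if elevation is not None and curve is not None:
        elev = elevation
        if resample_factor > 1:
            elev = resample(elevation, resample_factor, "bilinear")
        grid = apply_sealevel_mask(grid, elev, curve, occ.mid_age)
    rows, cols = buffer_cells(grid, occ.lon, occ.lat, radius_km)
    vals = np.asarray(grid.values, float)[rows, cols]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyBufferError(f"empty biome buffer for {occ.occ_id}")
    cats, counts = np.unique(vals.astype(int), return_counts=True)
    return BiomeProfile(
        occ_id=occ.occ_id,
        counts={int(c): int(k) for c, k in zip(cats, counts)},
        n_cells=int(vals.size),
    )


def profiles_to_frame(profiles: list[BiomeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for b, c in sorted(p.counts.items()):
            rows.append(
                {
                    "occ_id": p.occ_id,
                    "biome": b,
                    "count": c,
                    "n_cells": p.n_cells,
                    "ecotonal": p.ecotonal,
                }
            )
    return pd.DataFrame(rows)


def regional_availability(
    stack: ClimateStack,
    phase_slices: dict[str, list[float]],
    region_mask: xr.DataArray | None = None,
    elevation: xr.DataArray | None = None,
    curve: SeaLevelCurve | None = None,
) -> pd.DataFrame:
    """Per-phase biome fractions of regional land cells.

    Each phase pools its (deduplicated) occupied slices with equal weight:
    the phase fraction of a biome is the mean over slices of that slice's
    land-cell fraction, so two slices contribute equally regardless of how
    much land each exposes. Returns a tidy frame (phase, biome, fraction,
    n_cells) where ``n_cells`` is the summed land-cell count behind the
    phase's pooled estimate.
    """
    rows = []
    for phase, ages in phase_slices.items():
        ages = sorted(set(float(a) for a in ages))
        if not ages:
            raise InvalidConfigError(f"phase {phase!r} has no slices")
        per_slice = []
        n_land_total = 0
        for age in ages:
            grid = stack.slice_at(age)["biome"]
            if elevation is not None and curve is not None:
                grid = apply_sealevel_mask(grid, elevation, curve, age)
            vals = np.asarray(grid.values, float)
            if region_mask is not None:
                vals = np.where(np.asarray(region_mask.values, bool), vals, np.nan)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise InvalidRegionError(f"no land cells for {phase} at {age} ka")
            cats, counts = np.unique(vals.astype(int), return_counts=True)
            per_slice.append(dict(zip(cats.tolist(), (counts / vals.size).tolist())))
            n_land_total += int(vals.size)
        biomes = sorted({b for d in per_slice for b in d})
        for b in biomes:
            frac = float(np.mean([d.get(b, 0.0) for d in per_slice]))
            rows.append(
                {"phase": phase, "biome": b, "fraction": frac, "n_cells": n_land_total}
            )
    return pd.DataFrame(rows)


def occupied_proportion(
    profiles: list[BiomeProfile], focal_biome: int
) -> tuple[int, int]:
    """(x, n): occupations with the focal biome accessible, total occupations."""
    x = sum(1 for p in profiles if focal_biome in p.accessible)
    return x, len(profiles)


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, correction: bool = False
) -> tuple[float, float]:
    """Pooled two-sample proportion Z test, two-sided normal p.

    With ``correction`` a Yates-style continuity correction of
    0.5*(1/n1 + 1/n2) is subtracted from |p1 - p2| (floored at zero).
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n < 1 or not 0 <= x <= n:
            raise InvalidConfigError("need 0 <= x <= n and n >= 1")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise UndefinedStatisticError("pooled proportion is 0 or 1; variance undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    diff = p1 - p2
    if correction:
        cc = 0.5 * (1 / n1 + 1 / n2)
        diff = np.sign(diff) * max(abs(diff) - cc, 0.0)
    z = diff / se
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts matrix."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise InvalidConfigError("table must be at least 2x2")
    if np.any(obs < 0):
        raise InvalidConfigError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise UndefinedStatisticError("zero row or column margin")
    res = chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def availability_counts(
    availability: pd.DataFrame, per_phase_cells: dict[str, int] | None = None
) -> pd.DataFrame:
    """Phase x biome integer cell counts from pooled fractions.

    Fractions are scaled by the phase's pooled land-cell count and rounded
    to the nearest integer (pooling over slices makes exact counts
    non-integer); suitable as a chi-square input for the change-through-time
    test.
    """
    out = availability.pivot_table(
        index="phase", columns="biome", values="fraction", fill_value=0.0
    )
    cells = (
        availability.groupby("phase")["n_cells"].first()
        if per_phase_cells is None
        else pd.Series(per_phase_cells)
    )
    counts = (out.mul(cells, axis=0)).round().astype(int)
    return counts
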