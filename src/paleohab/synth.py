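"""Synthetic climate stacks, bathymetry, sea-level curves and occupations.

The generator emulates the structure of the inputs the analysis consumes —
a 1-kyr-resolution stack of mean annual temperature (bio01, degC), total
annual precipitation (bio12, mm) and categorical biome grids on a regular
30-arc-min lon/lat grid, a bathymetry/elevation grid, a glacial-cycle
sea-level curve, and a table of dated occupations carrying 16 binary
tool-type and 8 binary raw-material flags — with *known planted structure*:

* climate fields are spatially and temporally autocorrelated Gaussian noise
  (white noise convolved with a Gaussian kernel whose width is set so the
  field correlogram crosses 0.5 near ``autocorr_length_km``);
* the biome grid is a deterministic function of (bio01, bio12) via fixed
  thresholds, so climate and vegetation are coherent by construction;
* occupations are placed on land cells with placement probability tilted
  toward a focal biome by ``biome_preference_logit``;
* designated tool types are drawn from a logistic model with coefficient
  ``tool_effect_beta`` on the standardized buffer-mean precipitation of the
  site, so downstream matrix statistics have a recoverable planted effect.

Everything is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import norm

from .errors import InfeasiblePlacementError, InvalidConfigError
from .extraction import (
    DEFAULT_MIS_TABLE,
    N_RAW_MATERIALS,
    N_TOOL_TYPES,
    OccupationRecord,
    buffer_cells,
    records_to_frame,
)
from .grids import ClimateStack, SeaLevelCurve, apply_sealevel_mask

KM_PER_DEGREE = 111.195


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world; defaults emulate the study conditions.

    The grid is eastern-Africa-sized at 30 arc-min (0.5 deg) resolution; the
    stack spans the Middle Stone Age at 1-kyr spacing; the occupation count
    matches the assemblage database scale (n = 84).
    """

    grid_nlat: int = 60
    grid_nlon: int = 80
    lon_min: float = 22.0
    lon_max: float = 62.0
    lat_min: float = -12.0
    lat_max: float = 18.0
    n_slices: int = 300
    age_start: float = 300.0  # ka BP of the oldest slice
    autocorr_length_km: float = 250.0
    temp_mean: float = 20.0
    temp_sd: float = 4.0
    precip_mean: float = 900.0
    precip_sd: float = 450.0
    n_biomes: int = 10
    n_occupations: int = 84
    biome_preference_logit: float = 1.5
    tool_effect_beta: float = 2.0
    n_effect_tools: int = 4
    focal_biome: int | None = None  # None -> modal biome of the mid-stack slice
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise InvalidConfigError("n_slices must be >= 1")
        if self.grid_nlat < 4 or self.grid_nlon < 4:
            raise InvalidConfigError("grid must be at least 4x4")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise InvalidConfigError("extent must be nonempty")
        if self.n_biomes < 1:
            raise InvalidConfigError("n_biomes must be >= 1")
        if self.n_occupations < 0:
            raise InvalidConfigError("n_occupations must be >= 0")
        if not 0 <= self.n_effect_tools <= N_TOOL_TYPES:
            raise InvalidConfigError("n_effect_tools out of range")

    @property
    def lat_centres(self) -> np.ndarray:
        step = (self.lat_max - self.lat_min) / self.grid_nlat
        return self.lat_min + (np.arange(self.grid_nlat) + 0.5) * step

    @property
    def lon_centres(self) -> np.ndarray:
        step = (self.lon_max - self.lon_min) / self.grid_nlon
        return self.lon_min + (np.arange(self.grid_nlon) + 0.5) * step

    @property
    def ages(self) -> np.ndarray:
        return self.age_start - np.arange(self.n_slices, dtype=float)


def _smoothing_sigma_cells(config: SyntheticConfig) -> tuple[float, float]:
    """Kernel sigma (lat cells, lon cells) so field correlation hits 0.5 at L.

    Smoothing white noise with a Gaussian of s.d. sigma gives a field with
    Gaussian autocorrelation exp(-d^2 / (4 sigma^2)); solving for correlation
    0.5 at distance L gives sigma = L / (2 sqrt(ln 2)).
    """
    sigma_km = config.autocorr_length_km / (2.0 * math.sqrt(math.log(2.0)))
    step_lat = (config.lat_max - config.lat_min) / config.grid_nlat
    step_lon = (config.lon_max - config.lon_min) / config.grid_nlon
    mean_lat = 0.5 * (config.lat_min + config.lat_max)
    km_lat = KM_PER_DEGREE * step_lat
    km_lon = KM_PER_DEGREE * step_lon * max(math.cos(math.radians(mean_lat)), 1e-6)
    return sigma_km / km_lat, sigma_km / km_lon


def _correlated_field(
    rng: np.random.Generator, config: SyntheticConfig, sigma_t: float = 2.0
) -> np.ndarray:
    """Standardized (n_slices, nlat, nlon) field, smooth in space and time."""
    noise = rng.standard_normal((config.n_slices, config.grid_nlat, config.grid_nlon))
    s_lat, s_lon = _smoothing_sigma_cells(config)
    sig_t = sigma_t if config.n_slices > 1 else 0.0
    # periodic boundaries in space keep the smoothed field stationary (edge
    # cells would otherwise have inflated variance and unphysical extremes)
    smooth = gaussian_filter(
        noise, sigma=(sig_t, s_lat, s_lon), mode=("nearest", "wrap", "wrap")
    )
    sd = smooth.std()
    if sd == 0:
        return np.zeros_like(smooth)
    return (smooth - smooth.mean()) / sd


def classify_biome(
    bio01: np.ndarray, bio12: np.ndarray, config: SyntheticConfig
) -> np.ndarray:
    """Deterministic biome categories from climate via fixed thresholds.

    Temperature and precipitation are each cut into bins at fixed normal
    quantiles of the configured (mean, sd); the bin pair indexes a category,
    capped at ``n_biomes - 1``. The mapping is documented so that tests can
    predict the biome of any climate pair exactly.
    """
    n = config.n_biomes
    nt = max(1, int(math.floor(math.sqrt(n))))
    npb = int(math.ceil(n / nt))

    def bin_index(values: np.ndarray, mean: float, sd: float, nbins: int) -> np.ndarray:
        if nbins <= 1 or sd == 0:
            return np.zeros(np.shape(values), dtype=int)
        edges = mean + sd * norm.ppf(np.arange(1, nbins) / nbins)
        return np.digitize(values, edges)

    tb = bin_index(np.asarray(bio01, float), config.temp_mean, config.temp_sd, nt)
    pb = bin_index(np.asarray(bio12, float), config.precip_mean, config.precip_sd, npb)
    return np.minimum(tb * npb + pb, n - 1)


def generate_climate_stack(config: SyntheticConfig) -> ClimateStack:
    """Spatially/temporally autocorrelated bio01 and bio12, coherent biome."""
    rng = np.random.default_rng([int(config.seed), 11])
    z_t = _correlated_field(rng, config)
    z_p = _correlated_field(rng, config)
    bio01 = config.temp_mean + config.temp_sd * z_t
    bio12 = np.clip(config.precip_mean + config.precip_sd * z_p, 0.0, None)
    biome = classify_biome(bio01, bio12, config).astype(float)
    coords = {"age": config.ages, "lat": config.lat_centres, "lon": config.lon_centres}
    dims = ("age", "lat", "lon")
    ds = xr.Dataset(
        {
            "bio01": (dims, bio01, {"units": "degC", "long_name": "mean annual temperature"}),
            "bio12": (dims, bio12, {"units": "mm", "long_name": "total annual precipitation"}),
            "biome": (dims, biome, {"long_name": "biome category"}),
        },
        coords=coords,
        attrs={"age_units": "ka BP"},
    )
    return ClimateStack(ds)


def generate_bathymetry_sealevel(
    config: SyntheticConfig,
) -> tuple[xr.DataArray, SeaLevelCurve]:
    """Elevation grid (m, negative below present sea level) and a 100-kyr
    glacial-cycle sea-level curve covering the whole stack span."""
    rng = np.random.default_rng([int(config.seed), 13])
    noise = rng.standard_normal((config.grid_nlat, config.grid_nlon))
    s_lat, s_lon = _smoothing_sigma_cells(config)
    smooth = gaussian_filter(noise, sigma=(s_lat, s_lon), mode="wrap")
    sd = smooth.std()
    z = smooth / sd if sd > 0 else smooth
    # continental interior with an eastern ocean margin and a shelf whose
    # exposure tracks the sea-level curve
    lons = config.lon_centres
    ramp_centre = config.lon_max - 0.2 * (config.lon_max - config.lon_min)
    ramp_width = 0.05 * (config.lon_max - config.lon_min)
    ramp = expit((lons - ramp_centre) / ramp_width)
    elev = 500.0 + 450.0 * z - 1600.0 * ramp[None, :]
    elevation = xr.DataArray(
        elev,
        coords={"lat": config.lat_centres, "lon": config.lon_centres},
        dims=("lat", "lon"),
        name="elevation",
        attrs={"units": "m", "long_name": "elevation relative to present sea level"},
    )
    ages = np.arange(0.0, config.age_start + 10.0 + 1e-9, 5.0)
    levels = -60.0 + 60.0 * np.cos(2.0 * np.pi * ages / 100.0)
    return elevation, SeaLevelCurve(ages, levels)


def _stage_table_for_span(age_lo: float, age_hi: float) -> dict[str, tuple[float, float]]:
    out = {}
    for name, (young, old) in DEFAULT_MIS_TABLE.items():
        if max(young, age_lo) < min(old, age_hi):
            out[name] = (young, old)
    return out


def generate_occupations(
    stack: ClimateStack,
    config: SyntheticConfig,
    elevation: xr.DataArray | None = None,
    curve: SeaLevelCurve | None = None,
    radius_km: float = 50.0,
) -> tuple[list[OccupationRecord], dict]:
    """Place dated occupations on land with planted biome/toolkit structure.

    Returns the records plus a ``truth`` dict of the generating parameters
    (focal biome, preference logit, effect tools and betas, per-occupation
    standardized buffer-mean precipitation) for recovery tests.
    """
    if elevation is None or curve is None:
        elevation, curve = generate_bathymetry_sealevel(config)
    rng = np.random.default_rng([int(config.seed), 17])
    ages = stack.ages
    age_lo, age_hi = float(ages.min()), float(ages.max())
    if age_hi <= age_lo:
        raise InvalidConfigError("stack must span more than one slice age")

    stages = _stage_table_for_span(age_lo, age_hi)
    if not stages:
        stages = {"ALL": (age_lo, age_hi)}
    stage_names = sorted(stages, key=lambda s: stages[s][0])
    overlaps = np.array(
        [min(stages[s][1], age_hi) - max(stages[s][0], age_lo) for s in stage_names]
    )
    weights = overlaps / overlaps.sum()

    # focal biome = modal biome of the mid-stack slice (unless configured)
    mid_slice = stack.data.isel(age=len(ages) // 2)
    if config.focal_biome is not None:
        focal = int(config.focal_biome)
    else:
        vals, counts = np.unique(
            np.asarray(mid_slice["biome"].values, int), return_counts=True
        )
        focal = int(vals[np.argmax(counts)])

    n = config.n_occupations
    records_meta = []
    used_cells: set[tuple[int, int]] = set()
    for i in range(n):
        stage = stage_names[i] if i < len(stage_names) else rng.choice(stage_names, p=weights)
        young, old = stages[stage]
        lo = max(young, age_lo) + 0.5
        hi = min(old, age_hi) - 0.5
        if hi <= lo:
            lo, hi = max(young, age_lo), min(old, age_hi)
        mid = float(rng.uniform(lo, hi))
        w_max = min(8.0, mid - age_lo, age_hi - mid)
        w = float(rng.uniform(min(1.0, w_max / 2), max(w_max, 1e-3)))

        sl = stack.slice_at(mid)
        biome = apply_sealevel_mask(sl["biome"], elevation, curve, mid)
        bvals = np.asarray(biome.values, float)
        land_i, land_j = np.nonzero(np.isfinite(bvals))
        avail = [
            (a, b) for a, b in zip(land_i, land_j) if (a, b) not in used_cells
        ]
        if not avail:
            raise InfeasiblePlacementError(
                f"no unused land cells left at {mid:.1f} ka "
                f"(placed {i} of {n} occupations)"
            )
        logits = np.array(
            [config.biome_preference_logit * (bvals[a, b] == focal) for a, b in avail]
        )
        p = np.exp(logits - logits.max())
        p /= p.sum()
        a, b = avail[int(rng.choice(len(avail), p=p))]
        used_cells.add((a, b))
        records_meta.append(
            {
                "cell": (a, b),
                "lon": float(stack.data["lon"].values[b]),
                "lat": float(stack.data["lat"].values[a]),
                "mid": mid,
                "w": w,
                "biome_at_site": int(bvals[a, b]),
            }
        )

    # buffer-mean precipitation at each site's mid-age slice (masked)
    precip_means = np.empty(n)
    for i, m in enumerate(records_meta):
        sl = stack.slice_at(m["mid"])
        grid = apply_sealevel_mask(sl["bio12"], elevation, curve, m["mid"])
        rows, cols = buffer_cells(grid, m["lon"], m["lat"], radius_km)
        precip_means[i] = float(np.nanmean(np.asarray(grid.values, float)[rows, cols]))
    sd = precip_means.std(ddof=1) if n > 1 else 0.0
    z_precip = (precip_means - precip_means.mean()) / sd if sd > 0 else np.zeros(n)

    effect_tools = list(range(config.n_effect_tools))
    records = []
    for i, m in enumerate(records_meta):
        toolkit = rng.integers(0, 2, size=N_TOOL_TYPES)
        for t in effect_tools:
            p_t = expit(config.tool_effect_beta * z_precip[i])
            toolkit[t] = int(rng.random() < p_t)
        records.append(
            OccupationRecord(
                site=f"site_{i // 2 + 1:02d}",
                occ_id=f"occ_{i + 1:03d}",
                lon=m["lon"],
                lat=m["lat"],
                age_min=m["mid"] - m["w"],
                age_max=m["mid"] + m["w"],
                site_type=int(rng.integers(0, 2)),
                method=int(rng.integers(0, 2)),
                toolkit=toolkit,
                raw_material=rng.integers(0, 2, size=N_RAW_MATERIALS),
            )
        )
    truth = {
        "focal_biome": focal,
        "biome_preference_logit": config.biome_preference_logit,
        "tool_effect_beta": config.tool_effect_beta,
        "effect_tools": [f"tool_{t + 1:02d}" for t in effect_tools],
        "precip_buffer_mean": precip_means.tolist(),
        "precip_z": z_precip.tolist(),
        "biome_at_site": [m["biome_at_site"] for m in records_meta],
        "seed": config.seed,
    }
    return records, truth


def write_bundle(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Generate and write the full synthetic input bundle to ``outdir``.

    Climate stack and elevation as NetCDF, sea-level curve and occupation
    table as CSV, generating truth as JSON. Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack = generate_climate_stack(config)
    elevation, curve = generate_bathymetry_sealevel(config)
    records, truth = generate_occupations(stack, config, elevation, curve)

    paths = {
        "stack": str(outdir / "climate_stack.nc"),
        "elevation": str(outdir / "elevation.nc"),
        "sea_level": str(outdir / "sea_level.csv"),
        "occupations": str(outdir / "occupations.csv"),
        "truth": str(outdir / "truth.json"),
        "config": str(outdir / "synthetic_config.json"),
    }
    stack.to_netcdf(paths["stack"])
    elevation.to_dataset(name="elevation").to_netcdf(paths["elevation"], engine="scipy")
    curve.to_csv(paths["sea_level"])
    records_to_frame(records).to_csv(paths["occupations"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2)
    return paths
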