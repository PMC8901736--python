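"""End-to-end orchestration of the analysis.

``run_full_analysis`` consumes a configuration pointing at a climate stack,
an occupation table, bathymetry and a sea-level curve (plus an optional
precomputed cost-path matrix), runs every stage in order — buffer
extraction, climate-space intervals and clustering, biome profiles and
availability tests, phased habitability maps, Mantel/BH and MMRR tables,
per-tool Firth regressions — and writes one artifact family per stage into
the output directory together with a JSON manifest recording the package
version, configuration, seeds and content hashes of all inputs and outputs
(sufficient for exact replay).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__
from .biomes import (
    availability_counts,
    biome_profile,
    chisq_independence,
    occupied_proportion,
    profiles_to_frame,
    regional_availability,
    two_proportion_test,
)
from .climatespace import (
    central_interval,
    climate_distance,
    cluster_occupations,
    cluster_summary,
    scale_points,
)
from .errors import InvalidConfigError, UndefinedStatisticError
from .extraction import (
    DEFAULT_MIS_TABLE,
    RAW_COLUMNS,
    TOOL_COLUMNS,
    OccupationRecord,
    buffer_cells,
    read_occupations,
    summaries_to_frame,
    summarize_buffer,
    summarize_values,
)
from .firthglm import effect_sign_summary, tool_response_models
from .grids import ClimateStack, SeaLevelCurve, apply_sealevel_mask, resample
from .habitability import (
    MODES,
    habitability_map,
    persistence_summary,
    phase_envelope,
)
from .matstats import (
    DistanceMatrix,
    binary_attribute_distance,
    composition_distance,
    geographic_distance,
    mantel_table,
    mmrr,
    numeric_distance,
)

log = logging.getLogger("paleohab")


@dataclass
class AnalysisConfig:
    """Everything needed to run the full analysis from files."""

    stack_path: str
    occupations_path: str
    bathymetry_path: str
    sea_level_path: str
    out_dir: str
    cost_matrix_path: str | None = None
    radius_km: float = 50.0
    resample_factor: int = 12  # 30 arc-min -> 2.5 arc-min
    n_perm: int = 999
    seed: int = 0
    mis_table: dict[str, tuple[float, float]] | None = None
    composition_metric: str = "jaccard"
    linkage: str = "complete"
    k_max: int = 10
    apply_sealevel: bool = True

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise InvalidConfigError("radius_km must be positive")
        if self.n_perm < 99:
            raise InvalidConfigError("n_perm must be >= 99")
        if self.resample_factor < 1:
            raise InvalidConfigError("resample_factor must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "mis_table" in raw and raw["mis_table"] is not None:
            raw["mis_table"] = {
                k: (float(v[0]), float(v[1])) for k, v in raw["mis_table"].items()
            }
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _mean_pairwise_absdiff(values: np.ndarray) -> float:
    """Mean |e_i - e_j| over all cell pairs, via the sorted-order identity."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    if n < 2:
        return 0.0
    i = np.arange(n)
    return float(2.0 * np.sum((2 * i - n + 1) * v) / (n * (n - 1)))


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every stage and write the artifact bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mis_table = config.mis_table or DEFAULT_MIS_TABLE

    stack = ClimateStack.from_netcdf(config.stack_path)
    elevation = xr.load_dataset(config.bathymetry_path, engine="scipy")["elevation"]
    curve = SeaLevelCurve.from_csv(config.sea_level_path)
    records = read_occupations(config.occupations_path)
    cost = (
        DistanceMatrix.from_csv(config.cost_matrix_path, kind="geographic")
        if config.cost_matrix_path
        else None
    )
    elev_args = (
        {"elevation": elevation, "curve": curve} if config.apply_sealevel else {}
    )
    artifacts: dict[str, str] = {}

    def write_csv(df: pd.DataFrame, name: str, **kw) -> None:
        path = out / name
        df.to_csv(path, index=kw.pop("index", False), **kw)
        artifacts[name] = str(path)

    # ---- stage 1: buffer extraction -------------------------------------
    log.info("stage extraction: %d occupations", len(records))
    summaries = []
    for occ in records:
        for var in ("bio01", "bio12"):
            summaries.append(
                summarize_buffer(
                    stack,
                    occ,
                    var,
                    radius_km=config.radius_km,
                    resample_factor=config.resample_factor,
                    **elev_args,
                )
            )
    write_csv(summaries_to_frame(summaries), "buffer_summaries.csv")

    means = {
        (s.occ_id, s.variable): s.mean for s in summaries
    }
    points = pd.DataFrame(
        {
            "occ_id": [r.occ_id for r in records],
            "temp_mean": [means[(r.occ_id, "bio01")] for r in records],
            "precip_mean": [means[(r.occ_id, "bio12")] for r in records],
        }
    )

    # ---- stage 2: climate space ----------------------------------------
    log.info("stage climatespace")
    interval_rows = []
    for var, col in (("bio01", "temp_mean"), ("bio12", "precip_mean")):
        lo, hi, n_in = central_interval(points[col].to_numpy(), 0.6827, "normal")
        interval_rows.append(
            {"variable": var, "coverage": 0.6827, "lo": lo, "hi": hi,
             "n_within": n_in, "n": len(points)}
        )
    write_csv(pd.DataFrame(interval_rows), "central_intervals.csv")

    D_clim = climate_distance(points)
    X = scale_points(points)
    solution = cluster_occupations(
        D_clim, X, k_max=min(config.k_max, len(records) - 1),
        linkage=config.linkage, seed=config.seed,
    )
    clusters = points.copy()
    clusters["cluster_kmeans"] = solution.kmeans_labels
    clusters["cluster_tree"] = solution.tree_labels
    write_csv(clusters, "clusters.csv")
    write_csv(
        pd.DataFrame(
            {"k": list(solution.silhouette_by_k),
             "avg_silhouette": list(solution.silhouette_by_k.values())}
        ),
        "silhouette_profile.csv",
    )
    write_csv(cluster_summary(points, solution), "cluster_summary.csv")
    if not solution.agreement:
        log.warning("k-means and dendrogram partitions disagree at k=%d", solution.k)

    # ---- stage 3: biomes ------------------------------------------------
    log.info("stage biomes")
    profiles = [
        biome_profile(
            stack, occ, radius_km=config.radius_km,
            resample_factor=config.resample_factor, **elev_args,
        )
        for occ in records
    ]
    write_csv(profiles_to_frame(profiles), "biome_profiles.csv")

    phase_slices: dict[str, list[float]] = {}
    stack_ages = set(stack.ages.tolist())
    for r in records:
        mis = r.mis(mis_table)
        young, old = mis_table[mis]
        ages = sorted(a for a in stack_ages if young < a <= old)
        if ages:
            phase_slices[mis] = ages
    availability = regional_availability(stack, phase_slices, **elev_args)
    write_csv(availability, "availability.csv")

    # occupied vs available for the most commonly accessed biome
    access_counts: dict[int, int] = {}
    for p in profiles:
        for b in p.accessible:
            access_counts[b] = access_counts.get(b, 0) + 1
    focal = max(access_counts, key=lambda b: (access_counts[b], -b))
    x1, n1 = occupied_proportion(profiles, focal)
    pooled = availability.groupby("biome").apply(
        lambda g: np.average(g["fraction"], weights=g["n_cells"]),
        include_groups=False,
    )
    frac_avail = float(pooled.get(focal, 0.0))
    n2 = int(availability["n_cells"].sum() / max(len(phase_slices), 1))
    x2 = int(round(frac_avail * n2))
    try:
        z, p_prop = two_proportion_test(x1, n1, x2, n2)
    except UndefinedStatisticError:
        z, p_prop = np.nan, np.nan
    write_csv(
        pd.DataFrame(
            [{"focal_biome": focal, "x_occupied": x1, "n_occupied": n1,
              "x_available": x2, "n_available": n2, "Z": z, "p": p_prop}]
        ),
        "proportion_test.csv",
    )

    counts = availability_counts(availability)
    if counts.shape[0] >= 2 and counts.shape[1] >= 2:
        keep = counts.loc[:, counts.sum(axis=0) > 0]
        chi2, dof, p_chi = chisq_independence(keep.to_numpy())
    else:
        chi2, dof, p_chi = np.nan, 0, np.nan
    write_csv(
        pd.DataFrame([{"chi2": chi2, "df": dof, "p": p_chi}]),
        "biome_change_chisq.csv",
    )

    # ---- stage 4: habitability -----------------------------------------
    log.info("stage habitability")
    occ_by_mis: dict[str, list[OccupationRecord]] = {}
    for r in records:
        occ_by_mis.setdefault(r.mis(mis_table), []).append(r)
    sum_by_occ = {(s.occ_id, s.variable): s for s in summaries}
    hab_maps = []
    envelope_rows = []
    for mis, occs in sorted(occ_by_mis.items()):
        if mis not in phase_slices:
            continue
        env = {}
        for var in ("bio01", "bio12"):
            member = [sum_by_occ[(o.occ_id, var)] for o in occs]
            env[var] = phase_envelope(member, mis, var)
            envelope_rows.append(
                {"mis": mis, "variable": var, "lo": env[var].lo, "hi": env[var].hi,
                 "n_occupations": len(occs)}
            )
        for mode in MODES:
            hm = habitability_map(
                stack, env, phase_slices[mis], mode=mode, **elev_args
            )
            hab_maps.append(hm)
    write_csv(pd.DataFrame(envelope_rows), "envelopes.csv")
    hab_ds = xr.Dataset(
        {f"{hm.mis}_{hm.mode}": hm.grid for hm in hab_maps}
    )
    hab_path = out / "habitability_maps.nc"
    hab_ds.to_netcdf(hab_path, engine="scipy")
    artifacts["habitability_maps.nc"] = str(hab_path)
    write_csv(persistence_summary(hab_maps), "habitability_summary.csv")

    # ---- stage 5: distance matrices & matrix statistics ----------------
    log.info("stage matstats")
    idx = pd.Index([r.occ_id for r in records], name="occ_id")
    table = pd.DataFrame(
        {
            "mid_age": [r.mid_age for r in records],
            "site_type": [r.site_type for r in records],
            "method": [r.method for r in records],
            "lon": [r.lon for r in records],
            "lat": [r.lat for r in records],
        },
        index=idx,
    )
    toolkit = pd.DataFrame(
        [r.toolkit for r in records], index=idx, columns=list(TOOL_COLUMNS)
    )
    rawmat = pd.DataFrame(
        [r.raw_material for r in records], index=idx, columns=list(RAW_COLUMNS)
    )

    # altitude & roughness of the logistical landscape from the bathymetry,
    # at the analysis resolution
    elev_fine = (
        resample(elevation, config.resample_factor, "bilinear")
        if config.resample_factor > 1
        else elevation
    )
    alt_rows = []
    rough = []
    for r in records:
        grid = elev_fine
        if config.apply_sealevel:
            grid = apply_sealevel_mask(elev_fine, elev_fine, curve, r.mid_age)
        rows_, cols_ = buffer_cells(grid, r.lon, r.lat, config.radius_km)
        vals = np.asarray(grid.values, float)[rows_, cols_]
        alt_rows.append(summarize_values(r.occ_id, "altitude", vals))
        rough.append(_mean_pairwise_absdiff(vals))
    table["altitude"] = [s.mean for s in alt_rows]
    table["roughness"] = rough
    table["temp"] = points["temp_mean"].to_numpy()
    table["precip"] = points["precip_mean"].to_numpy()

    D_tool = composition_distance(toolkit, config.composition_metric)
    D_raw = composition_distance(rawmat, config.composition_metric)
    predictors: dict[str, DistanceMatrix] = {
        "temperature": numeric_distance(table["temp"]),
        "precipitation": numeric_distance(table["precip"]),
        "age": numeric_distance(table["mid_age"]),
        "altitude": numeric_distance(table["altitude"]),
        "roughness": numeric_distance(table["roughness"]),
        "site_type": binary_attribute_distance(table["site_type"]),
        "method": binary_attribute_distance(table["method"]),
        "cost_path": (
            geographic_distance(mode="supplied", supplied=cost, labels=list(idx))
            if cost is not None
            else geographic_distance(table[["lon", "lat"]])
        ),
    }
    # a predictor whose triangle has zero variance carries no information and
    # would make Mantel r undefined; drop it rather than abort the family
    for name in list(predictors):
        if predictors[name].triangle().std() == 0:
            log.warning("dropping zero-variance predictor %r", name)
            del predictors[name]

    for path_name, D in (("toolkit", D_tool), ("raw_material", D_raw)):
        D.to_csv(out / f"distance_{path_name}.csv")
        artifacts[f"distance_{path_name}.csv"] = str(out / f"distance_{path_name}.csv")

    mantel_frames = []
    for resp_name, Dy in (("toolkit", D_tool), ("raw_material", D_raw)):
        mt = mantel_table(
            Dy, predictors, n_perm=config.n_perm, seed=config.seed
        )
        mt.insert(0, "response", resp_name)
        mantel_frames.append(mt)
    write_csv(pd.concat(mantel_frames, ignore_index=True), "mantel_tests.csv")

    mmrr_rows = []
    for resp_name, Dy in (("toolkit", D_tool), ("raw_material", D_raw)):
        res = mmrr(Dy, predictors, n_perm=config.n_perm, seed=config.seed)
        for name in res.coefficients:
            mmrr_rows.append(
                {"response": resp_name, "term": name,
                 "coef": res.coefficients[name], "t": res.coef_t[name],
                 "p": res.coef_p[name], "F": res.F, "r_squared": res.r_squared,
                 "p_model": res.p_model}
            )
    write_csv(pd.DataFrame(mmrr_rows), "mmrr.csv")

    # ---- stage 6: per-tool Firth regressions ---------------------------
    log.info("stage firthglm")
    firth_table = pd.concat([table, toolkit], axis=1)
    firth_predictors = [
        "temp", "precip", "mid_age", "altitude", "roughness", "site_type", "method",
    ]
    constant = [p for p in firth_predictors if table[p].nunique() < 2]
    if constant:
        log.warning("dropping constant site-level predictors %s", constant)
        firth_predictors = [p for p in firth_predictors if p not in constant]
    firth_results = tool_response_models(firth_table, firth_predictors)
    write_csv(firth_results, "firth_tool_models.csv")
    signs = effect_sign_summary(firth_results)
    write_csv(signs.reset_index(), "firth_effect_signs.csv")

    # ---- manifest -------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: _sha256(Path(p))
            for name, p in (
                ("stack", config.stack_path),
                ("occupations", config.occupations_path),
                ("bathymetry", config.bathymetry_path),
                ("sea_level", config.sea_level_path),
            )
        },
        "artifacts": {name: _sha256(Path(p)) for name, p in sorted(artifacts.items())},
        "optimal_k": solution.k,
        "focal_biome": int(focal),
    }
    manifest["bundle_hash"] = hashlib.sha256(
        json.dumps(manifest["artifacts"], sort_keys=True).encode()
    ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
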