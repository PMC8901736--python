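"""Property-based evaluation of the whole pipeline on synthetic worlds.

The study's printed statistics come from external archives and are not
reproducible from first principles, so the package is validated by
properties instead: oracle equivalence on small instances, closed-form
identities, calibration of permutation nulls, recovery of planted effects
at the study's sample size (n = 80 occupations), habitability-construction
invariants, clustering recovery, and end-to-end determinism. Each function
here rebuilds its inputs from scratch from a seed and returns measured
quantities; the acceptance script and the acceptance test suite both call
these.
"""

from __future__ import annotations

import itertools
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest

from .biomes import chisq_independence, two_proportion_test
from .climatespace import cluster_occupations
from .errors import PaleohabError
from .extraction import TOOL_COLUMNS, buffer_cells, haversine_km, records_to_frame
from .firthglm import _penalized_loglik, firth_fit
from .grids import resample
from .habitability import Envelope, habitability_map
from .matstats import (
    DistanceMatrix,
    bh_adjust,
    binary_attribute_distance,
    composition_distance,
    geographic_distance,
    mantel,
    mmrr,
    numeric_distance,
)
from .pipeline import AnalysisConfig, run_full_analysis
from .synth import (
    SyntheticConfig,
    generate_bathymetry_sealevel,
    generate_climate_stack,
    generate_occupations,
    write_bundle,
)


def _study_config(seed: int, n_occupations: int = 80, **kw) -> SyntheticConfig:
    """Replicate-scale study conditions: the generator's default
    eastern-Africa extent on a coarser 24 x 32 grid, over the late-MSA span
    (130-29 ka) so every replicate covers MIS 3-5."""
    base = dict(
        grid_nlat=24,
        grid_nlon=32,
        n_slices=102,
        age_start=130.0,
        n_occupations=n_occupations,
        seed=seed,
    )
    base.update(kw)
    return SyntheticConfig(**base)


# ---------------------------------------------------------------------------
# 1. oracle equivalence


def mantel_exact_vs_enumeration(seed: int) -> dict:
    """Exact Mantel p on n = 4 against independent brute-force enumeration."""
    rng = np.random.default_rng(seed)
    labels = [f"o{i}" for i in range(4)]
    D1 = DistanceMatrix(labels, squareform(pdist(rng.normal(size=(4, 3)))))
    D2 = DistanceMatrix(labels, squareform(pdist(rng.normal(size=(4, 3)))))
    res = mantel(D1, D2, exact=True)
    i, j = np.tril_indices(4, k=-1)
    t1 = D1.values[i, j]
    stats = [
        np.corrcoef(t1, D2.values[np.ix_(p, p)][i, j])[0, 1]
        for p in itertools.permutations(range(4))
    ]
    r_obs = np.corrcoef(t1, D2.values[i, j])[0, 1]
    p_oracle = float(np.mean(np.asarray(stats) >= r_obs - 1e-12))
    return {"p_package": res.p, "p_oracle": p_oracle, "abs_err": abs(res.p - p_oracle)}


def buffer_oracle_agreement(seed: int, n_sites: int = 20) -> dict:
    """Buffer cell sets and means vs a full-grid haversine scan (2.5' grid)."""
    step = 1.0 / 24.0
    lats = -1.25 + (np.arange(60) + 0.5) * step
    lons = 35.0 + (np.arange(60) + 0.5) * step
    rng = np.random.default_rng(seed)
    vals = rng.normal(20.0, 3.0, size=(60, 60))
    grid = xr.DataArray(
        vals, coords={"lat": lats, "lon": lons}, dims=("lat", "lon"), name="bio01"
    )
    matches = 0
    max_mean_err = 0.0
    for _ in range(n_sites):
        lat = float(rng.uniform(lats[6], lats[-6]))
        lon = float(rng.uniform(lons[6], lons[-6]))
        rows, cols = buffer_cells(grid, lon, lat, 50.0)
        got = set(zip(rows.tolist(), cols.tolist()))
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        d = haversine_km(lon, lat, glon, glat)
        expected = set(zip(*np.nonzero(d <= 50.0)))
        matches += got == expected
        mean_pkg = vals[rows, cols].mean()
        idx = np.array(sorted(expected))
        mean_oracle = vals[idx[:, 0], idx[:, 1]].mean()
        max_mean_err = max(max_mean_err, abs(mean_pkg - mean_oracle))
    return {
        "match_fraction": matches / n_sites,
        "max_mean_abs_err": max_mean_err,
        "n_sites": n_sites,
    }


def toy_statistics() -> dict:
    """Hand-computable statistics on the printed toy tables."""
    z, _ = two_proportion_test(8, 10, 4, 10)
    chi, df, _ = chisq_independence([[20, 10], [10, 20]])
    bh1 = bh_adjust([0.01, 0.02, 0.03])
    bh2 = bh_adjust([0.001, 0.5, 0.9])
    return {
        "two_prop_z": z,
        "chisq": chi,
        "chisq_df": df,
        "bh_first_of_close_triple": float(bh1[0]),
        "bh_smallest_adjusted": float(bh2[0]),
    }


# ---------------------------------------------------------------------------
# 2. closed-form / limit agreement


def closed_form_checks(seed: int) -> dict:
    rng = np.random.default_rng(seed)

    # bilinear on a planar field is exact
    lats = 0.25 + np.arange(6) * 0.5
    lons = 30.25 + np.arange(6) * 0.5
    la, lo = np.meshgrid(lats, lons, indexing="ij")
    g = xr.DataArray(
        3.0 * lo - 2.0 * la + 0.5,
        coords={"lat": lats, "lon": lons},
        dims=("lat", "lon"),
        name="bio01",
    )
    out = resample(g, 4, "bilinear")
    la2, lo2 = np.meshgrid(out["lat"].values, out["lon"].values, indexing="ij")
    planar_err = float(np.max(np.abs(out.values - (3.0 * lo2 - 2.0 * la2 + 0.5))))

    # single-predictor MMRR R^2 = (Mantel r)^2
    labels = [f"o{i}" for i in range(12)]
    D1 = DistanceMatrix(labels, squareform(pdist(rng.normal(size=(12, 3)))))
    D2 = DistanceMatrix(labels, squareform(pdist(rng.normal(size=(12, 3)))))
    res = mmrr(D1, {"x": D2}, n_perm=99, seed=seed)
    r = mantel(D1, D2, n_perm=99, seed=seed).r
    r2_err = float(abs(res.r_squared - r**2))

    # Firth on a saturated 2x2 equals the half-cell-corrected log odds ratio,
    # cross-checked against direct numerical penalized-likelihood maximization
    a, b, c, d = 6, 4, 3, 7
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, float)
    x = np.array([0] * (a + b) + [1] * (c + d), float)
    X = np.column_stack([np.ones_like(x), x])
    fit = firth_fit(y, X)
    haldane = float(np.log(((c + 0.5) * (b + 0.5)) / ((d + 0.5) * (a + 0.5))))
    num = minimize(
        lambda bb: -_penalized_loglik(y, X, bb),
        np.zeros(2),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
    )
    firth_err = float(max(abs(fit.coef[1] - haldane), abs(fit.coef[1] - num.x[1])))

    # complete separation: finite, converged
    xs = np.array([-2.0, -1.5, -1.0, -0.5, 0.5, 1.0, 1.5, 2.0])
    ys = (xs > 0).astype(float)
    sep = firth_fit(ys, np.column_stack([np.ones_like(xs), xs]))
    separation_ok = bool(sep.converged and np.all(np.isfinite(sep.coef)))

    return {
        "bilinear_planar_max_err": planar_err,
        "mmrr_r2_identity_err": r2_err,
        "firth_2x2_max_err": firth_err,
        "firth_separation_finite": separation_ok,
    }


# ---------------------------------------------------------------------------
# 3. null calibration


def _replicate_world(config: SyntheticConfig):
    stack = generate_climate_stack(config)
    elevation, curve = generate_bathymetry_sealevel(config)
    records, truth = generate_occupations(stack, config, elevation, curve)
    return stack, elevation, curve, records, truth


def null_calibration(seed: int, n_rep: int = 500, n_perm: int = 199) -> dict:
    """With all planted effects at zero, permutation p-values are uniform."""
    ps_mantel = []
    ps_mmrr = []
    for rep in range(n_rep):
        cfg = SyntheticConfig(
            grid_nlat=16,
            grid_nlon=16,
            lon_min=30.0,
            lon_max=46.0,
            lat_min=-8.0,
            lat_max=8.0,
            n_slices=30,
            age_start=60.0,
            n_occupations=20,
            tool_effect_beta=0.0,
            biome_preference_logit=0.0,
            seed=seed + rep,
        )
        stack, elevation, curve, records, truth = _replicate_world(cfg)
        df = records_to_frame(records).set_index("occ_id")
        D_tool = composition_distance(df[list(TOOL_COLUMNS)], "jaccard")
        D_precip = numeric_distance(
            pd.Series(truth["precip_buffer_mean"], index=df.index)
        )
        ps_mantel.append(
            mantel(D_tool, D_precip, n_perm=n_perm, seed=seed + 7 * rep + 1).p
        )
        res = mmrr(
            D_tool,
            {"precip": D_precip, "age": numeric_distance(df["mid_age_ka"])},
            n_perm=n_perm,
            seed=seed + 7 * rep + 2,
        )
        ps_mmrr.append(res.coef_p["precip"])
    z_equal, _ = two_proportion_test(5, 10, 10, 20)
    return {
        "mantel_ks_p": float(kstest(ps_mantel, "uniform").pvalue),
        "mmrr_ks_p": float(kstest(ps_mmrr, "uniform").pvalue),
        "two_prop_z_at_equal_proportions": z_equal,
        "n_rep": n_rep,
    }


# ---------------------------------------------------------------------------
# 4. parameter recovery


def effect_recovery(
    seed: int, n_rep: int = 100, beta: float = 2.0, n_occupations: int = 80,
    n_perm: int = 999,
) -> dict:
    """Power to recover the planted precipitation effect at the study scale.

    Per replicate: MMRR of toolkit dissimilarity on precipitation distance
    (controlling age, geography and site type) and a Firth logistic fit of a
    designated tool's presence on standardized buffer-mean precipitation.
    """
    hits_mmrr = 0
    hits_firth = 0
    for rep in range(n_rep):
        cfg = _study_config(seed + rep, n_occupations=n_occupations,
                            tool_effect_beta=beta)
        stack, elevation, curve, records, truth = _replicate_world(cfg)
        df = records_to_frame(records).set_index("occ_id")
        D_tool = composition_distance(df[list(TOOL_COLUMNS)], "jaccard")
        precip = pd.Series(truth["precip_buffer_mean"], index=df.index)
        predictors = {
            "precipitation": numeric_distance(precip),
            "age": numeric_distance(df["mid_age_ka"]),
            "geographic": geographic_distance(df[["lon", "lat"]]),
            "site_type": binary_attribute_distance(df["site_type"]),
        }
        res = mmrr(D_tool, predictors, n_perm=n_perm, seed=seed + 13 * rep + 3)
        if res.coefficients["precipitation"] > 0 and res.coef_p["precipitation"] <= 0.05:
            hits_mmrr += 1

        z = np.asarray(truth["precip_z"], float)
        X = np.column_stack([np.ones_like(z), z])
        tool = truth["effect_tools"][0]
        fit = firth_fit(df[tool].to_numpy(float), X)
        if fit.coef[1] > 0 and fit.wald_p[1] <= 0.05:
            hits_firth += 1
    return {
        "mmrr_power": hits_mmrr / n_rep,
        "firth_power": hits_firth / n_rep,
        "n_rep": n_rep,
        "beta": beta,
        "n_occupations": n_occupations,
    }


# ---------------------------------------------------------------------------
# 5. habitability construction


def habitability_properties(seed: int) -> dict:
    cfg = _study_config(seed, n_occupations=40)
    stack, elevation, curve, records, truth = _replicate_world(cfg)
    from .extraction import summarize_buffer

    by_mis: dict[str, list] = {}
    for r in records:
        by_mis.setdefault(r.mis(), []).append(r)
    ages_all = stack.ages
    contained = 0
    total = 0
    conjunction_ok = True
    monotone_ok = True
    for mis, occs in by_mis.items():
        summaries = {
            var: [summarize_buffer(stack, o, var) for o in occs]
            for var in ("bio01", "bio12")
        }
        env = {
            var: Envelope(
                mis, var,
                min(s.mean for s in summaries[var]),
                max(s.mean for s in summaries[var]),
            )
            for var in ("bio01", "bio12")
        }
        for var in ("bio01", "bio12"):
            for s in summaries[var]:
                contained += env[var].lo <= s.mean <= env[var].hi
                total += 1
        from .extraction import DEFAULT_MIS_TABLE

        young, old = DEFAULT_MIS_TABLE[mis]
        slices = [a for a in ages_all if young < a <= old]
        hm_c = habitability_map(stack, env, slices, mode="combined")
        hm_t = habitability_map(stack, env, slices, mode="temperature")
        hm_p = habitability_map(stack, env, slices, mode="precipitation")
        conjunction_ok &= bool(
            np.all(hm_c.grid.values <= hm_t.grid.values + 1e-12)
            and np.all(hm_c.grid.values <= hm_p.grid.values + 1e-12)
        )
        wide = {
            var: Envelope(mis, var, env[var].lo - 5.0, env[var].hi + 5.0)
            for var in env
        }
        hm_w = habitability_map(stack, wide, slices, mode="combined")
        monotone_ok &= bool(np.all(hm_w.grid.values >= hm_c.grid.values - 1e-12))

    full = {
        "bio01": Envelope("ALL", "bio01", -1e9, 1e9),
        "bio12": Envelope("ALL", "bio12", -1e9, 1e9),
    }
    some_ages = list(ages_all[:10])
    hm_full = habitability_map(stack, full, some_ages, mode="combined")
    disjoint = {
        "bio01": Envelope("ALL", "bio01", 1e6, 2e6),
        "bio12": Envelope("ALL", "bio12", 1e6, 2e6),
    }
    hm_zero = habitability_map(stack, disjoint, some_ages, mode="combined")
    return {
        "containment_pct": 100.0 * contained / total,
        "monotone_ok": monotone_ok,
        "conjunction_ok": conjunction_ok,
        "full_envelope_pct_min": float(hm_full.grid.values.min()),
        "disjoint_envelope_pct_max": float(hm_zero.grid.values.max()),
    }


# ---------------------------------------------------------------------------
# 6. clustering recovery


def clustering_recovery(seed: int, n_rep: int = 100) -> dict:
    """Planted 3-cluster climate data at 10:1 separation: silhouette-optimal
    k = 3 and exact partition recovery."""
    hits = 0
    for rep in range(n_rep):
        rng = np.random.default_rng(seed + rep)
        centres = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels_true = np.repeat([0, 1, 2], 20)
        X = centres[labels_true] + rng.normal(0.0, 1.0, size=(60, 2))
        D = DistanceMatrix(
            [str(i) for i in range(60)], squareform(pdist(X))
        )
        try:
            sol = cluster_occupations(D, X, k_max=8, seed=seed + rep)
        except PaleohabError:
            continue
        ok = sol.k == 3
        if ok:
            for got in (sol.kmeans_labels, sol.tree_labels):
                mapping: dict[int, int] = {}
                for g, t in zip(got, labels_true):
                    if mapping.setdefault(g, t) != t:
                        ok = False
                        break
        hits += ok
    return {"recovery_rate": hits / n_rep, "n_rep": n_rep}


# ---------------------------------------------------------------------------
# 7. end-to-end determinism


def end_to_end_determinism(seed: int, workdir: str | None = None) -> dict:
    """Full pipeline at the study scale, run twice; outputs must be
    byte-identical and the total runtime is recorded."""
    t0 = time.time()
    tmp_ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(workdir) if workdir else Path(tmp_ctx.name)
    try:
        cfg = SyntheticConfig(n_occupations=80, seed=seed)
        paths = write_bundle(cfg, base / "inputs")
        manifests = []
        for run in ("a", "b"):
            ac = AnalysisConfig(
                stack_path=paths["stack"],
                occupations_path=paths["occupations"],
                bathymetry_path=paths["elevation"],
                sea_level_path=paths["sea_level"],
                out_dir=str(base / run),
                resample_factor=3,
                n_perm=199,
                seed=seed,
            )
            manifests.append(run_full_analysis(ac))
        identical = manifests[0]["artifacts"] == manifests[1]["artifacts"]
        for name in manifests[0]["artifacts"]:
            identical &= (base / "a" / name).read_bytes() == (base / "b" / name).read_bytes()
        return {
            "byte_identical": bool(identical),
            "runtime_s": time.time() - t0,
            "optimal_k": manifests[0]["optimal_k"],
            "n_artifacts": len(manifests[0]["artifacts"]),
        }
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()
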