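"""Buffer extraction and climate-space clustering.

Summarises temperature and precipitation within each occupation's 50 km
logistical landscape at its mid-age slice, reports the 68% central interval
of the inhabited conditions, and clusters the occupations in scaled
temperature-precipitation space with the number of groups chosen by the
average-silhouette criterion.
"""

import pandas as pd

from paleohab import (
    SyntheticConfig,
    central_interval,
    climate_distance,
    cluster_occupations,
    generate_bathymetry_sealevel,
    generate_climate_stack,
    generate_occupations,
    summarize_buffer,
)
from paleohab.climatespace import cluster_summary, scale_points

config = SyntheticConfig(n_occupations=60, seed=7)
stack = generate_climate_stack(config)
elevation, curve = generate_bathymetry_sealevel(config)
records, _ = generate_occupations(stack, config, elevation, curve)

rows = []
for occ in records:
    t = summarize_buffer(stack, occ, "bio01", radius_km=50.0,
                         elevation=elevation, curve=curve)
    p = summarize_buffer(stack, occ, "bio12", radius_km=50.0,
                         elevation=elevation, curve=curve)
    rows.append({"occ_id": occ.occ_id, "temp_mean": t.mean, "precip_mean": p.mean})
points = pd.DataFrame(rows)

lo, hi, n_in = central_interval(points["temp_mean"], 0.6827, "normal")
print(f"inhabited temperature, 68% interval: {lo:.1f}-{hi:.1f} degC "
      f"({n_in} of {len(points)} occupations inside)")
lo, hi, n_in = central_interval(points["precip_mean"], 0.6827, "normal")
print(f"inhabited precipitation, 68% interval: {lo:.0f}-{hi:.0f} mm "
      f"({n_in} of {len(points)} occupations inside)")

D = climate_distance(points)
solution = cluster_occupations(D, scale_points(points), k_max=10, seed=0)
print(f"silhouette-optimal number of climate clusters: k = {solution.k}")
print(f"k-means and dendrogram partitions agree: {solution.agreement}")
print(cluster_summary(points, solution).round(1).to_string(index=False))
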