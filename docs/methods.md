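# Methods

This note documents the models and procedures the package implements, the
conventions and numerical choices they rest on, and what the synthetic test
bed does and does not demonstrate.

## Grids, time slices, and the palaeocoastline

All grids are regular lon/lat rasters with **cell-centre registration**:
coordinate arrays hold cell centres, and a grid's extent is the rectangle
of outer cell edges. A climate stack is an xarray Dataset with dimensions
`(age, lat, lon)` at 1-kyr age spacing (ages in ka BP) and variables
`bio01` (°C), `bio12` (mm) and `biome` (integer categories stored as
floats; NaN encodes masked/sea cells uniformly across variables).

*Slice selection.* An occupation's mid-age `(age_min + age_max)/2` is
rounded to the nearest integer kyr; ties (x.5 ka) round **away from zero**.
The convention is arbitrary but deterministic and documented; it matters
only for mid-ages landing exactly on half-kyr boundaries.

*Resampling.* Downscaling by an integer factor keeps the outer extent and
divides the step: the refined axis is `edge_lo + (i + ½)·step/factor`.
Bilinear interpolation uses the four surrounding input cell centres, with
linear extrapolation in the outer half-cell rim so that planar fields are
reproduced exactly everywhere (the alternative — edge clamping — would
bias the rim). Nearest-neighbour resampling clamps into the centre hull,
so rim cells copy the nearest edge cell; it is mandatory for the
categorical biome layer.

*Sea-level masking.* A cell is sea at age *t* when
`elevation ≤ sea_level(t)`; the coastline tie counts as **sea**
(conservative land mask). Sea level is linearly interpolated in the curve;
queries outside the tabulated span are errors, never extrapolations. For
stage-level maps the "stage-mean sea level" is the trapezoidal average of
the piecewise-linear curve over the stage interval. For occupation-level
extraction the per-slice interpolated level is used (masking before buffer
summarisation is the default and can be switched off).

## Logistical landscapes

The 50 km radius represents a hunter-gatherer group's routine foraging and
raw-material procurement range. Membership is by **cell centre** within
great-circle distance ≤ radius, haversine on a sphere of radius
6371.0088 km (the mean Earth radius; error vs an ellipsoid is well under
0.5% at 50 km). The containing cell is always included, so a radius
smaller than the cell size still yields a one-cell buffer. Standard
deviations use the **sample (n−1)** convention everywhere; a single-cell
buffer reports SD 0.

Marine Isotope Stage boundaries default to the standard benthic-stack
chronology (MIS 3: 29–57, MIS 4: 57–71, MIS 5: 71–130, MIS 6: 130–191,
MIS 7: 191–243, MIS 8: 243–300, MIS 9: 300–337 ka) and are configurable.
A boundary age belongs to the **younger** stage (a mid-age of exactly
71 ka is MIS 4); the youngest tabulated stage also owns its young edge.

## Climate space

The 68% central interval defaults to mean ± z·SD with z the normal
quantile for the requested two-sided coverage (z = 1.0000 at 68.27%);
an empirical-quantile mode is available. Occupation dissimilarity is the
Euclidean distance on per-variable z-scores, giving temperature and
precipitation equal weight. Clustering computes the average silhouette
width of k-means solutions for k = 2..k_max (25 restarts, fixed seed),
takes the argmax (ties break toward smaller k), and cuts an agglomerative
tree built on the distance matrix into the same number of groups. Linkage
defaults to `complete` (configurable: `average`, `ward`); both the k-means
and the dendrogram labellings are returned, and the pipeline logs when
they disagree rather than hiding one. Degenerate inputs (all points
identical, zero-variance variables) raise rather than returning a silent k.

## Biomes, availability and tests

A biome profile counts cells per category inside the buffer on the
nearest-neighbour-resampled biome layer; the accessible set is every
category with ≥1 cell and a landscape with ≥2 accessible categories is
ecotonal (accessibility is monotone in radius by construction). Regional
availability per occupational phase pools the phase's deduplicated
occupied slices **with equal weight**: the phase fraction of a biome is
the mean over slices of that slice's land-cell fraction, so slices
contribute equally regardless of exposed land area. The occupied-vs-
available comparison uses the pooled two-proportion Z test (pooled
variance, two-sided normal p, optional continuity correction); the
availability side's n is the pooled land-cell count, which is large and
makes the test anti-conservative — this follows the simple pooled rule and
is logged as a caveat. Change of availability through time uses the
Pearson chi-square test on per-phase cell counts; pooling makes counts
non-integer, so they are rounded to the nearest integer (logged).

## Habitability persistence

Per stage and variable the envelope is the `[min, max]` of the member
occupations' buffer means — by construction every member lies inside its
own envelope. The in-range test is **inclusive** of the endpoints (the
envelope is built from realized values). Persistence is evaluated on raw
cell values, not 50-km-smoothed values (switchable). The combined mode is
a **per-slice conjunction**: a slice counts only when temperature and
precipitation are both in range in that slice, so the combined map is
cell-wise ≤ both marginal maps; the overlay alternative (cell-wise minimum
of the two maps) can be obtained by composing the marginals. Widening an
envelope can only increase a cell's percentage (monotonicity), and a
spanning/disjoint envelope gives 100%/0% everywhere — these invariants are
tested directly.

## Matrix statistics

Composition dissimilarity defaults to Jaccard on presence/absence flags
(Hamming available); the Jaccard distance between two empty assemblages is
defined as 0. Numeric attributes enter as absolute pairwise differences,
binary attributes as 0/1 mismatch matrices, geography as haversine
distance or a validated user-supplied cost-path matrix. Terrain roughness
defaults to the mean pairwise absolute elevation difference within the
buffer — a terrain-ruggedness stand-in for energetic-cost formulations;
precomputed roughness values can be supplied instead.

The Mantel statistic is the Pearson correlation of lower triangles; the
null jointly permutes rows and columns of one matrix. All permutation
p-values use the "+1" estimator `p = (1 + #{null ≥ obs}) / (1 + n_perm)`,
so p is never zero and has granularity 1/(n_perm+1); for n ≤ 8 an
exhaustive enumeration over all n! permutations is available. Families of
Mantel tests against one response are BH-adjusted together. MMRR fits OLS
on the unfolded triangles (intercept included; predictor standardization
optional, off by default so coefficients stay in response units) and
assesses each coefficient's |t| and the model F against the same
row/column permutation null. Near-collinear predictor sets (condition
number > 1e8) trigger a warning and a pseudo-inverse fit. With a single
predictor, R² equals the squared Mantel r identically. Permutation seeds
are recorded in every result for exact replay.

## Firth regression

Per-tool presence models use Firth's bias-reduced logistic regression
(penalty ½ log det of the Fisher information), which keeps estimates
finite under the complete separation that presence/absence data at n ≈ 80
produce routinely. Estimation is Newton iteration on the modified score
with step-halving on the penalized log-likelihood; convergence is max-norm
of the modified score ≤ 1e-8 within 100 iterations, and non-convergence is
flagged, not hidden. Inference is Wald. Note one property the penalty does
*not* have: duplicating every observation doubles the likelihood but adds
only a constant to the penalty, so the duplicated-data estimate moves
toward the unpenalized MLE — shrinkage weakens with information, as
intended for a bias correction. Continuous predictors are standardized by
default; constant tool columns are skipped with a recorded reason.

## The synthetic world

The generator emulates the *structure* of the real inputs, not their
physics. Climate fields are white noise convolved with a Gaussian kernel
(periodic spatial boundaries keep the field stationary; temporal smoothing
sigma 2 slices) and standardized to the configured mean/SD; the kernel
width is set so the field's spatial correlogram crosses 0.5 at
`autocorr_length_km` (σ = L / 2√ln2). Defaults describe an
eastern-Africa-sized domain: 60×80 cells at 0.5°, 300 slices (300–1 ka),
temperature 20 ± 4 °C, precipitation 900 ± 450 mm (clipped at 0),
autocorrelation length 250 km, 10 biome categories, 84 occupations (the
scale of the assemblage database). The biome layer is a fixed-threshold
function of (bio01, bio12): each variable is cut at normal quantiles of
its configured mean/SD and the bin pair indexes a category — climate and
vegetation are therefore coherent by construction. Bathymetry is smoothed
noise (500 ± 450 m) with an eastern ocean-margin ramp so that a
continental shelf floods and drains as the 100-kyr cosine sea-level cycle
(0 to −120 m) moves. Occupations are placed on distinct land cells at
their mid-age, with stage-stratified ages so every stage in the span is
represented, placement probability tilted toward a focal biome by
`biome_preference_logit`, and designated tool types drawn from
`P(present) = σ(β·z)` with z the standardized buffer-mean precipitation.
The generating truth is returned alongside for recovery tests.

What this test bed does **not** show: realistic climate dynamics, orbital
pacing, realistic biome legends, dating uncertainty, taphonomic or
research-intensity bias in site discovery, and spatial sampling artifacts
of real archaeological survey. Passing tests demonstrate the *machinery* —
extraction, statistics and inference are correct and calibrated — not that
the scientific conclusions drawn from any real dataset are right.

## Validation design and problem sizes

Replicate studies run on a coarsened copy of the default domain (24×32
cells over the same extent, 102 slices spanning 130–29 ka so MIS 3–5 are
all populated) chosen to keep hundreds of replicates inside desk-scale
runtimes; the full-resolution configuration (60×80, 300 slices, n = 80,
downscale factor 3, 199 permutations) is exercised end-to-end twice to
verify byte-identical reproduction. Null calibration uses 500 replicates
of a 16×16-cell world with all planted effects at zero (199 permutations;
the "+1" discreteness of the p-grid is far below the KS resolution at 500
samples). Recovery power uses 100 replicates at the study scale
(n = 80, β = 2, 999 permutations); the measured rates — ~0.9 for the MMRR
precipitation coefficient and ~1.0 for the per-tool Firth slope — are the
package's regression fixtures. Clustering recovery plants three clusters
at 10:1 between/within separation and demands exact partition recovery.

## Known limitations

- Only regular lon/lat grids; no reprojection, no GeoTIFF I/O (grids
  round-trip as NetCDF, tables as CSV).
- No propagation of dating uncertainty into extraction; the mid-age is a
  point estimate.
- Least-cost paths are consumed, never computed; the great-circle matrix
  is the fallback.
- The proportion test's availability n follows the simple pooled-cell rule
  and is anti-conservative (see above).
- Partial Mantel tests are out of scope.
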