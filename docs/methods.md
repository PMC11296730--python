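# Methods

This note documents the models, parameter choices, and numerical decisions
behind `rxfire`. It is written for users who want to know what the package
assumes, what its synthetic validation does and does not demonstrate, and
where the genuinely open design choices were made.

## Record model and geodesy

A fire record is a point location (WGS84), a local calendar date, a burned
area in acres, and a burn type (`UNKNOWN` until resolved; transitions only
`UNKNOWN → {PRESCRIBED, AGRICULTURAL, WILDFIRE, INVALID}`). Dates are local
calendar dates with no time-zone arithmetic: all temporal logic (duration,
matching) operates on whole days. The internal area unit is acres
(permit-native); satellite areas are converted on read with
1 acre = 4046.8564224 m² exactly, so conversion round-trips to machine
precision.

All inter-record distances are great-circle (haversine) distances on a
sphere of radius 6 371 008.8 m. Gridding and raster sampling need planar
coordinates; since analyses run on sub-state domains, a local
equirectangular projection tangent at a reference point is used (error well
under a percent at the ~100 km scale, negligible against 4 km cells and
30 m raster pixels). The projection is part of every grid definition, and
two gridded fields are only comparable when their definitions match.

Permit cleaning removes records with missing or non-positive burned area,
then records outside the region boundary; each removal is attributed to
exactly one reason, in that order. Points exactly on the boundary edge are
kept (closed polygon test, shapely `covers`).

## Burn typing

**Land-cover rule.** A burn's footprint is modeled as an axis-aligned
square in the raster CRS, side √(area), centered on the reported point.
The modal class among 30 m cells whose centers fall inside the square is
the burn's land cover; a footprint too small to contain a cell center falls
back to the cell under the point. Modal ties break toward non-agriculture
groups first, then the lowest class code — a deterministic rule that is
conservative against over-flagging agricultural burns. Orientation of the
square is immaterial at 30 m resolution for typical burn sizes. The default
class grouping maps 81 (pasture/hay) and 82 (cultivated crops) to
AGRICULTURE, 11 (open water) to WATER, 31 to BARREN, everything else to
OTHER; whether pasture/hay belongs in the agricultural-burn group is
genuinely ambiguous, so the grouping is configuration. Raster vintages
serve the years from their release until the next one (a fire in year Y
uses the latest vintage ≤ Y; years before the first vintage use the
earliest).

**Wildfire rule.** Prescribed burns start and end the same day; persistence
across days indicates a wildfire. Detections are linked when they occur on
the same date within the spatial clustering distance (default 1000 m) or on
dates exactly one day apart within the temporal clustering distance
(default 800 m); events are connected components of this graph, found by
union-find over BallTree neighbor queries. Multi-day reach arises only by
chaining day-to-day links, so a missed middle day splits an event — a known
failure mode of duration-based typing (a three-day fire observed on its
first and last days looks like two one-day burns). Every member of an event
spanning ≥ 2 days is typed WILDFIRE. Agricultural classification runs
first, and only `UNKNOWN` records participate in clustering, so cropland
burns cannot seed wildfire chains; the pipeline wrapper fixes this order.

**Elbow tuning.** Both distances are chosen at the knee of the cluster
count versus distance curve: after min–max normalization of both axes, the
knee is the interior candidate maximizing the discrete second difference
(non-uniform spacing handled by the three-point formula). A flat or
perfectly linear curve has no knee and raises an error rather than
returning an arbitrary candidate. Single-predicate modes (same-day links
only / consecutive-day links only) tune one distance at a time; joint mode
takes (spatial, temporal) pairs varied together.

## Matching

Fire-to-fire matchers are greedy sequential assignments, not optimal
bipartite matching: candidates pass hard gates, then the globally best
remaining pair is accepted and both records retired. For nearest matching
the gates are same date and distance ≤ threshold, and "best" is smallest
distance; for relaxed matching the gates are distance ≤ threshold and
|date difference| ≤ a day budget, and "best" is smallest burned-area
difference, with distance then record ids breaking ties. Tie rules form a
total order, so results are independent of input record order, and the
matchers reproduce exhaustive sequential enumeration exactly on small
instances (tested).

Grid matching assigns each record's full area to the single 4 km cell
containing its point (half-open intervals, lower-left origin: a point on an
interior edge belongs to the higher-index cell), conserving total in-domain
area exactly. Pairs are cell values on dates where **both** sources report
burning. The 3×3 moving mean (edge windows truncated to in-domain cells, so
constants are preserved and values stay non-negative) is exposed as an
optional post-step; raw-vs-raw is the default comparison.

## Burned-area adjustment

On grid-matched pairs (x = permit area, y = satellite area) the
through-origin slope b = Σxy/Σx² is the scaling factor; 100·(1−b) is the
implied percent change in satellite burned area. R² for the through-origin
fit uses the uncentered total sum of squares (the standard no-intercept
convention). A with-intercept OLS fit is provided alongside; a positive
intercept indicates under-detection of small burns.

**Robust confidence intervals.** Burned-area errors are multiplicative —
the absolute discrepancy on a matched pair scales with the size of the
burn — and burned areas are heavy-tailed. Under those conditions the
classical homoscedastic OLS interval for a through-origin slope is
structurally anti-conservative: its variance estimate is too small by
roughly E[x⁴]/E[x²]² (for log-normal areas with log-sd σ, a factor
e^{4σ²} ≈ 55 at σ = 1), independent of the noise level, and simulated
coverage of a nominal 95% interval falls near 40%. Both fits therefore
report HC3 sandwich (heteroscedasticity-robust) 95% intervals; point
estimates are unchanged, and Monte-Carlo coverage is 93–95% across the
area distributions used here. The implementation is statsmodels OLS; tests
verify slopes, R², and the HC3 intervals against explicit closed-form
normal-equation and sandwich formulas.

The scaling factor applies uniformly to all PRESCRIBED records (the
adjustment is derived from pooled multi-state pairs); per-region factors
can be applied by subsetting, since the sign of the bias can differ by
state.

## Activity files and emissions

Neither permits nor satellite products report burn hours, so prescribed
burns are assumed to ignite at 11:00 local time and end before 18:00.
Duration is a step function of burned area; the shipped default table
(≤10 acres → 1 h, ≤50 → 2 h, ≤100 → 3 h, ≤500 → 4 h, ≤1000 → 5 h, above →
7 h) is plain configuration and should be overridden where a calibrated
table exists. The 7 h ceiling is what the 11:00–18:00 window allows.

Emissions per record and species follow the inventory form
E_s [kg] = area [m²] × fuel_load [kg/m²] × combustion_completeness ×
EF_s [g/kg] / 1000, with parameters per land-cover group. The shipped
factor table contains placeholder literature-style magnitudes (forest-like
and cropland-like rows for CO, PM2.5, PM10) — it exists so the machinery
is testable, makes no claim about any operational product, and must be
replaced for fidelity runs. Emissions are exactly linear in burned area,
so scaling areas by b scales every species mass by b (tested to machine
precision). Comparison utilities pair two emission sets by record id, by
calendar date (summing within days), or by grid cell and date, and
summarize each species with a through-origin fit.

## Synthetic scenarios

The generator produces a ground truth and two observed views on a generated
landscape (background forest with rectangular cropland, water, and barren
patches at 30 m):

* prescribed burns: single-day points on background land, log-normal areas
  (median 25 acres, log-sd 1.0 — most burns tens of acres, occasional
  hundreds);
* agricultural burns: points inside cropland patches (median 20 acres,
  log-sd 0.7);
* wildfires: 2–4-day chains whose daily centers step 300–700 m (below the
  800 m temporal link distance, so a fully observed chain is one event),
  1–3 detections per day scattered ≤ 40 m around the daily center.

The permit view covers prescribed and agricultural truth burns with 300 m
location jitter, ±1 day date error (permits record planned days), and
unbiased multiplicative area noise (log-sd 0.15 — manager estimates are
fairly accurate). The satellite view detects each burn with a logistic
probability in log-area (midpoint 5 acres, steepness 2 — small fires are
missed), applies 200 m location jitter, multiplies areas by the configured
bias (default 0.66) with log-sd 0.25 noise, and splits burns above 100
acres into up to 3 fragments whose areas sum to the observed total,
placed within the footprint's half-diagonal. Everything is deterministic
given the scenario seed (two integer-indexed generator streams: one for
truth, one for observation).

**What the validation shows — and what it does not.** Under the
*bias-recovery conditions* (`ScenarioConfig.bias_recovery`: complete
detection, true permit dates, no segmentation; area noise and location
jitter on) the full chain's fitted slope is a consistent estimator of the
configured bias and its robust 95% CI covers the truth in ≈95% of
replicates. Under the *full default discrepancy structure* the fitted slope
attenuates by several percent: segmentation pushes fragments across 4 km
cell borders and partial detection removes satellite mass from matched
cells, so matched cells systematically hold more permit mass than satellite
mass. That attenuation is a property of grid-based matching itself, not an
implementation artifact; the acceptance script reports both numbers. The
generator also does not emulate real-data features such as cloud-cover
gaps, spatially correlated detection failures, realistic fuel maps, or
geocoding error concentrated in one state — passing tests say nothing about
those.

## Problem sizes and numerical details

Default validation scenarios use 500 prescribed burns, 100 agricultural
burns, and 10 wildfires over a 90-day season on a ~0.5°×0.5° domain
(≈1600×1850 raster cells, ≈170 4-km cells), giving a few hundred
grid-matched pairs per replicate; CI-coverage checks use 100 replicates per
configured bias. Brute-force clustering oracles run at n ≤ 200. Degenerate
inputs fail loudly rather than silently: empty vintage lists, < 4 elbow
candidates, knee-less curves, all-zero regressors, constant x with an
intercept, non-positive scaling factors, and unknown land-cover groups in
the emission table all raise errors naming the problem.
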