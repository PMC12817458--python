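# Methods

This note documents the models and procedures implemented in `aedplace`,
the assumptions behind them, and the choices made where the design was
genuinely open.

## Spatial substrate

The city is an undirected graph of walkable road segments with lengths in
metres; all computation is planar. Geographic (lon/lat) inputs are projected
once at read time with a local azimuthal equidistant projection about the
layer centroid (spherical Earth, R = 6,371,008.8 m). At city scale (< 10 km)
this preserves distances to well under 0.1 %, which the I/O tests verify
against a haversine oracle; no external CRS database is needed.

**Candidates** are nodes of degree ≥ 3. Degree-2 nodes are geometric bends
of a single road rather than junctions, so they are excluded; this is a
modelling choice, since "intersection" has no unique graph-theoretic
definition in street data.

**Isochrones** are Dijkstra balls: the set of nodes whose shortest-path
distance from the origin is at most budget × speed. The defaults are a
3-minute budget at walking speed 1.65 m/s (297 m) for candidate
characterization and removal, and 5 minutes (495 m) for risk decay. The
speed is configurable — volunteer responders often run — but every default
radius in the package derives from 1.65 m/s.

**Point-in-isochrone membership.** Routing-engine isochrones are polygons;
here the extent of an isochrone is its reached node set, and a point
(population tile, POI, alert) is inside iff it lies within a snap tolerance
(default 50 m) of a reached node. This is reproducible without a routing
engine and is exact for point layers that sit on or near streets, which is
how address-level population and POI data behave. A pure Euclidean-disc
mode (radius = budget × speed around the origin) exists for degenerate or
tiny test networks. The tolerance is configurable; 50 m is roughly half a
short block and was fixed before any downstream evaluation.

## Risk areas and the regression tree

Alert counts per candidate isochrone over the observation window are
converted to alerts/year using 365.25 days per year (the window spans leap
years) and binned into the ordinal risk area 1..9 with right-closed
intervals: 0 → 1, (0–1] → 2, (1–2] → 3, (2–3] → 4, (3–4] → 5, (4–5] → 6,
(5–10] → 7, (10–20] → 8, > 20 → 9. Binning stabilises a target that is
otherwise dominated by zeros and small counts.

**Screening.** Collinear predictors are removed by iterative
variance-inflation-factor elimination (drop the worst until all VIF ≤ 10,
the conventional cut-off; zero-variance columns count as infinitely
inflated). Survivors are kept only if a one-way ANOVA F-test of the feature
grouped by risk level gives p < 0.05. A per-feature ANOVA was chosen over a
regression F-test because the target is the binned ordinal level. The
calibration test confirms a pure-noise feature survives at ≈ the α rate.

**Model.** The risk area is regressed as a number 1..9 with a CART
regression tree (scikit-learn `DecisionTreeRegressor`, squared error). Data
are split 80/20; depth ∈ {2,…,6} and minimum leaf size ∈ {5, 10, 20} are
chosen by minimum five-fold CV MSE on the training split, with ties broken
toward the shallower tree and larger leaf (the simpler model). The grid is
searched with an explicit loop so the tie-break and the joint reporting of
CV MSE/MAE are deterministic. Predictions are rounded to the nearest level
and clamped to [1, 9]; the un-rounded score is kept as a deterministic
tie-break for placement. A linear-regression baseline is fitted on the same
split and reported for comparison only; model selection is fixed to the
tree. The age-structure feature is generated but excluded from the default
feature list (age data are often unavailable in practice); a flag restores
it.

## Greedy placement

Each iteration selects the remaining candidate with the maximal current
risk level — ties broken by larger un-rounded risk score, then smaller id —
removes all remaining candidates within 297 m network distance, and reduces
by the decay constant (default 2) the risk of those within 495 m, floored
at level 1 (the lowest defined level). Decay is cumulative across
iterations: the update is memoryless by construction. Termination is either
a fixed device count (with a logged warning if the pool runs out first) or
exhaustion of a minimum risk level. Pre-processing against installed AEDs
applies the same removal/decay radii from each 24/7-available device,
snapped to its nearest network node (snap distance logged). Removal and
decay use network-distance balls, consistent with the 297 m equivalence of
the 3-minute isochrone.

The removal rule guarantees > 297 m pairwise network separation of selected
sites; coverage is monotone in the device count because the selection is a
prefix-stable order. Both are asserted in tests, along with agreement with
an independent re-implementation of the loop and a ≤-bound against an
exhaustive-search oracle on small instances (greedy heuristics find local
optima; the observed mean greedy/optimal coverage ratio on random small
instances is ≈ 0.96).

## Coverage and scenarios

Coverage is the fraction of alerts with a 24/7 AED within 300 m straight
line (default) or within 297 m network distance between nearest nodes; both
readings of "3 minutes" are defensible, so both are first-class and the
mode is a flag. Percentages are rounded to one decimal.

Scenario semantics: 0 scores the installed set; 1 and 2 ignore it and place
the same device count using model-predicted respectively historically
binned risk, scoring only the new set (a fair like-for-like comparison);
A, B, C pre-process against the installed set, then add devices (A: +20 %;
B/C: until risk area 5/3 is exhausted) and score the union. Scenario 2
re-uses the same greedy machinery with the empirical rate as the risk
source and tie-break score.

## The synthetic city

The generator emulates the five inputs the analysis needs, at a scale a
laptop handles in seconds: a jittered 20×20 grid network (spacing 150 m,
~8.4 km², 396 candidate intersections), 40,000 inhabitants allocated
multinomially over road-adjacent tiles by a mixture of Gaussian hotspots,
POIs sampled per category by spatial Poisson processes (rates per km²)
concentrated near hotspots (industry near a corner anchor), an observation
window of 5.64 years, and 30 baseline AEDs sampled preferentially near the
densest hotspot — deliberately clustered, emulating unplanned historical
installation, not risk-ranked.

The planted alert intensity per candidate is
λᵢ = softplus(w·zᵢ − 1) · c, where zᵢ are z-scored isochrone features, the
weights are dominated by population (1.0, versus ≤ 0.3 for the
infrastructure counts) to reflect population density being the strongest
driver of alert risk, and c scales the expected total to ~1,000 alerts over
the window. Alerts are Poisson-drawn per candidate and scattered within
45 m of a uniformly chosen reached node (hence inside the extent by
construction), with timestamps uniform over the window.

Population tiles and POIs are placed as road-adjacent points (jitter ≤ 30
and 40 m around nodes) so that node-based membership sees them; this
mirrors address-level data but means the generator does not exercise
points far from any road. Other real-data features the generator does not
emulate: time-of-day population shifts, vertical (indoor) distances,
spatial autocorrelation beyond the hotspot mixture, and irregular street
topology. Passing tests therefore demonstrate the pipeline's correctness
and its qualitative behaviour under feature-driven risk, not absolute
coverage levels for any real city.

## Replication properties checked

Across 20 independently seeded synthetic cities, the suite asserts the
directional findings: model-guided re-siting beats the clustered status quo
on ≥ 90 % of seeds; placement from historical alerts is at least as good as
model-based placement in mean coverage; adding devices never reduces
coverage; the weaker risk-3 stop always needs at least as many devices as
the risk-5 stop; and baseline AEDs are more tightly clustered (smaller mean
pairwise distance) than greedy-placed ones. Parameter recovery requires
Spearman ρ ≥ 0.6 between predicted risk and planted intensity on the
~400-candidate city (observed ≈ 0.95).

## Numerical and degenerate-input choices

- Years denominator 365.25 days; window validity requires end > start.
- Equal-length shortest-path ties cannot change reached-set membership, so
  no tie-break is needed in Dijkstra.
- Empty population/POI layers yield all-zero features; zero persons gives
  sex ratio 0.
- A constant training target yields a single-leaf tree with a logged
  warning; a constant feature is dropped in screening; a single-level
  target or a fully eliminated feature set raises an error.
- Node deduplication on read merges coordinates within 0.5 m; writers stamp
  outputs with `crs: local-metres` so planar coordinates that happen to fit
  lon/lat ranges are never re-projected on round-trip.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; runs are bit-reproducible, including the
  greedy audit log and the fitted tree structure.

## Problem sizes

Tests and the acceptance script use the default city (396 candidates,
~1,000 alerts), 20 seeds for the replication study, 50 random small
instances (≤ 12 candidates, ≤ 4 devices) for the exhaustive-search bound,
100 random graphs (≤ 25 nodes) for the shortest-path oracle, and 200
replicates (n = 500) for the screening calibration — sizes chosen so the
statistical checks are well-powered while a full run stays in the minutes
range on one CPU.
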