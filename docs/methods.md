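# Methods

This note documents the models, the synthetic study region, the numerical
choices, and the limits of what the test suite demonstrates.

## Synthetic city

The generator builds a square region (default 24 km side) tiled by a 1000 m
fishnet; blocks are rectangular aggregations of cells (default 144) and
communities aggregations of blocks (default 36). Requested block/community
counts are realized as the most-square factor pair tiling the lattice, so a
count that does not factor into the grid is rejected at validation.

**Latent concentration.** The truth surface is a spatially varying
coefficient (SVC) model: per-cell PM2.5 equals a local linear function of
the five covariates plus a smooth residual field (1 µg/m³, 16 km scale) and
a diurnal cycle (±5 µg/m³, afternoon peak). Coefficient surfaces are sums of
random cosine modes with a single wavenumber shell; their default
correlation length (192 km) is much larger than the region, so local
coefficients drift gently across the city while still varying by several
µg/m³ end to end. The AOD slope carries the dominant spatial variation
(amplitude 8 on a mean of 25): the AOD-to-surface-PM2.5 link is the one
that varies most with regional boundary-layer conditions, while land-use
slopes are comparatively stable. This structure is also what makes local
regression identifiable — each covariate mixes an independent smooth field,
a weak radial trend, and substantial cell-scale heterogeneity, so the five
regressors are not collinear through a shared center–periphery gradient and
local windows contain genuine within-window covariate variation. Simulation
designs whose covariates are purely smooth functions of space leave local
slopes unidentifiable at any bandwidth; we verified this directly before
settling on the mixed design.

**Covariates.** AOD is daily (cell-scale sd 0.2 around ≈0.55); population
density is hourly (from the mobility model below); NDVI, road density and
distance to the industrial source (NE corner) are static. Units are
natural: NDVI unitless in [−1, 1], road in m/km², distances in metres.

**Population and mobility.** 500 000 residents are allocated to communities
with a center-weighted exponential profile. Age proportions follow radial
gradients — elderly 25 % at the center falling to 10 % at the edge, children
5 % rising to 15 % — matching the elderly-central / children-peripheral
geography the analysis is designed to probe. A configurable fraction of
workers (default 0.6) commutes; destinations are drawn multinomially with
center-weighted employment attractiveness. Hourly population is a
deterministic schedule-driven redistribution (workers at the workplace
8:00–18:00 Mon–Fri), which conserves the regional total exactly. Real
location-based-service counts are noisy and include non-commute trips;
that noise is deliberately absent, so tests on the generator say nothing
about measurement error in phone-derived population fields.

**Stations and facilities.** Stations sit at uniform random positions and
observe the truth of their cell plus Gaussian noise (default 1 µg/m³).
Facilities (ten categories, 40 each) are placed with half-normal
center-weighted radii.

Randomness flows from one seed through named child streams (fields,
covariates, stations, flows, facilities, ages), so identical configurations
reproduce byte-identical outputs and subsystems can be varied independently.

## Concentration surfaces

GWR is fitted per hour at station locations by kernel-weighted least
squares (Gaussian kernel default; bisquare available). The bandwidth is
chosen by leave-one-out cross-validation over a 10-point log-spaced grid,
restricted to bandwidths whose smallest effective local sample (sum of
kernel weights at any station) is at least 3·(p+1) — an identifiability
floor that prevents the CV from selecting windows too small to support a
six-parameter local fit. If no candidate passes (e.g. a 10-station
network), the largest candidate is used: with a sparse network the model
honestly degrades toward global OLS, which is also the exact infinite-
bandwidth limit used as an oracle in the tests. Singular local designs fall
back to a small ridge with a warning.

Coefficients move from stations to fishnet cells by inverse-distance
weighting (power 2; a cell coincident with a station takes that station's
coefficients); cell predictions are the interpolated coefficients dotted
with the cell covariates, with negative values clamped to zero and counted.
Refitting GWR at every cell is the alternative reading of the source
procedure; IDW transfer is the default because it is cheaper and exact in
the colocated limit.

Ordinary kriging uses a variogram fitted to binned empirical semivariances
by pair-count-weighted least squares (exponential model default, "effective
range" parametrization γ(h) = c₀ + c·(1 − e^(−3h/a))). The kriging system
is solved with the Lagrange unbiasedness constraint; coincident data points
are collapsed to their mean, and constant data yield a flagged pure-nugget
model. Because ordinary kriging is exact at data points, kriging fishnet
predictions back onto the same lattice is the identity; the hourly pipeline
therefore skips that step by default, and `krige` is used when predicting
onto finer or offset targets. Block concentrations are area-weighted means
of intersecting cells (exact cell-membership means in the pipeline, where
blocks tile whole cells); a block intersecting no cell takes the nearest
cell's value with a logged warning.

## Exposure statistics

Exposure intensity is the hourly sum Σₕ conc·density over hours whose
concentration exceeds the threshold (no threshold by default, so NT is the
full series length). The weighted concentration `POD` treats hour bins as
half-open [h, h+1): work bins are 8..17, Monday–Friday, i.e. 50 of 168
weekly bins. The week is normalized per person-day — the population-
weighted mean over groups of (home-hours + work-hours concentration sums)
divided by 24·n_days — which makes `POD` a convex combination of the hourly
concentrations a group actually experiences (bounds asserted in tests). A
worker group whose workplace is unknown to the concentration table falls
back to its home series (conservative). Zero-population communities are
excluded and flagged. Decile tables sort communities ascending by age-group
proportion into ten equal-count bins, remainder to the lowest bins, and
report population-weighted mean `POD` per bin.

## Walkability

The facility weight table (total 16) and the two street-form decay tables
are encoded once as frozen dataclasses and round-trip through configuration
unchanged. Only the nearest facility of each category contributes —
consistent with a fixed 16-point ceiling; a per-count accumulation variant
(as in some commercial walkability products) is deliberately out of scope.
Distance bands are half-open [lo, hi), so exactly 500 m falls in the 25 %
band; beyond 1500 m the attenuation is total. Street-form decay adds the
block-length and intersection-density percentages (each ≤5 %, combined
≤10 %). Intersection density is kept in the table's native per-square-mile
units with a per-km² conversion helper (×2.58999). Distances are
straight-line; network distances can be supplied by precomputing the
per-category nearest distances externally.

## Classification

Tertile scores are equal-count thirds with the remainder going to lower
classes; runs of equal values always share the class of their lowest-sorted
member, so a constant vector scores all 1 and assignments are invariant to
input order. Jenks natural breaks are computed by exact dynamic programming
over sorted values with O(1) prefix-sum class costs — not a k-means
heuristic — and are verified against exhaustive partition search for all
n ≤ 12, k ≤ 4. Both 3×3 typologies (block: exposure × walkability;
community: POD × age proportion) emit all nine labels with observed
frequencies; no labels are merged, so a seven-category outcome arises
empirically when two cells of the grid are unoccupied. A constant axis
collapses to a single class with a logged warning.

## Equity metrics

The Gini coefficient sorts units ascending by per-capita exposure (POD),
builds the Lorenz curve of cumulative vulnerable-population share against
cumulative burden share (burden = POD × head count), and integrates by
trapezoid; this equals the grouped pairwise mean-absolute-difference
formula to machine precision (tested at 1e−9). An "exposure share of the
top q of the population" reading is provided as a view of the same curve.

Spatial weights default to queen contiguity (any shared boundary point),
row-standardized; rook and k-nearest-neighbour (k=6, for point-represented
units) are available. Islands keep empty rows with a warning.

Bivariate Moran's I follows the Anselin form with z-standardized variables
(population denominator n): global I = zₓᵀWz_y/n, local Iᵢ = zₓᵢ(Wz_y)ᵢ, so
the global statistic equals the mean of the local ones (asserted to 1e−12).
Global inference permutes y wholesale; local pseudo p-values use
conditional permutation (unit i fixed, neighbour values drawn from the
remaining n−1). p-values are two-sided with the +1 correction,
(#{|I*|≥|I|}+1)/(n_perm+1); n_perm defaults to 999 and a seed is mandatory.
Type-I error under an independent-pairs null is calibrated in the tests
(rejection rate within [0.03, 0.07] at α = 0.05 over 500 replicates).
Significant units are labelled HH/HL/LH/LL by the quadrant of (zₓᵢ, lag of
z_y). The exact normalization used by desktop GIS packages differs in minor
details (variance denominator, permutation scheme); the form here is the
standard published one and is documented rather than matched to any tool.

## Pipeline

Stages run in fixed dependency order from one config; each stage reads and
writes CSV/GeoJSON artifacts in the run directory, fails fast naming the
producing stage of any missing input, and records SHA-256 checksums and
wall-clock in `manifest.json`. The master seed fans out to per-stage
substreams (city seed, permutation seed), so identical configs give
identical checksums for every deterministic stage. The default problem
sizes — 24 km region, 576 cells, 144 blocks, 36 communities, 168 hours, 10
stations (200 for the recovery experiment) — keep a full run and the whole
test suite in the tens of seconds while leaving every statistic
well-populated.

## What passing tests do and do not show

The generator realizes the geography the method targets (center-polluted,
elderly-central, children-peripheral, centerward commuting), so the
qualitative findings on synthetic data — dynamic exposure exceeding the
static baseline, positive elderly–PM2.5 spatial association — are
demonstrations that the pipeline detects structure that is present by
construction, not evidence about any real city. Gini values on the default
city are small (~0.02) because simulated POD varies by only a few percent
across communities; real metropolitan inequality is far larger. In-transit
(path) exposure during commuting is out of scope, as are satellite AOD
retrieval, space–time kernel GWR, and universal kriging with drift.
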