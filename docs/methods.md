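# Methods

`migraseed` simulates how a partially migratory herbivore population spreads
plant propagules (seeds) across a landscape during seasonal migration. The
pipeline has five stages, each of which can be calibrated from empirical data
and each of which is exercised on a fully synthetic study system shipped with
the package.

## 1. Seasonal ranges from telemetry

Per-individual utilization distributions (UDs) are Gaussian kernel density
estimates of daily GPS fixes, with the reference (Silverman) bandwidth. The
isopleth region (default 95%) is extracted on a raster over the padded
bounding box of the fixes: pixels are ranked by density and retained until
they hold the requested mass, and the retained pixels are unioned into a
polygon. Tracks with fewer than 30 fixes fall back to a convex hull with a
warning; tracks whose fixes are all identical are rejected (degenerate
kernel). The population-level seasonal range is the convex hull of the union
of that season's UDs, converted to presence/absence on an equal-area
hexagonal grid (default cell area 1.18 km², the scale at which connectivity
is solved) by centroid-in-hull membership.

Net squared displacement (NSD) — squared distance of each fix from the
track's first fix — is provided for migration screening, together with a
reproducible helper that flags sustained-NSD-increase windows. Interactive
segmentation of migrations is deliberately out of scope: the pipeline accepts
pre-segmented tracks (a `phase` column).

All computation is metric. Geographic lon/lat inputs are projected through a
spherical transverse Mercator centred on the data; for study areas tens of
kilometres across the projection error is far below GPS error. An EPSG
selector is not exposed — the local frame is always used.

## 2. Migratory connectivity as optimal transport

Energy available to the population in each seasonal range is taken
proportional to max(NDVI, 0) × cell area and rescaled so each side sums to
the migrating population size N (default 1000). Connectivity is the solution
of the Monge–Kantorovich transportation problem: minimise Σ c_ij f_ij subject
to non-negative flows, row sums ≤ highland weights, column sums ≤ lowland
weights, and total flow = min(Σ supply, Σ demand). The cost c_ij is the
centroid-to-centroid distance in km (the natural proxy for relocation cost);
no distance threshold is applied. The LP is solved exactly with HiGHS via
`scipy.optimize.linprog`; instance sizes (tens of cells per side) are trivial
for an exact solver, so no approximate EMD is used. Tests certify optimality
against an independent network-simplex oracle and an exhaustive integer
enumeration on small instances.

Optimal flows are integerised into per-individual origin–destination
assignments by largest-remainder rounding (deterministic; every count within
1 of its fractional flow, totals exact). A multinomial alternative is
available behind a flag.

## 3. Trajectory simulation (conditional empirical random walk)

Each individual's migration is simulated as a fixed-length daily walk between
its assigned endpoints that preserves the geometry of a randomly chosen
template track. A fitted movement kernel stores, from the daily-thinned
template: step-length and turning-angle histograms (Freedman–Diaconis step
bins with per-bin empirical means, 36 fixed angular bins), the lag-1
conditional distributions of steps and turns, and the step–turn joint.
Proposals at each simulated step are the observed (step, turn) pairs,
reweighted by

    P(s | s_prev) · P(θ | θ_prev) / (P(s) · P(θ))   ×   pull(k, r)

where the first factor imposes the template's serial structure on atoms drawn
from the empirical joint, and the pull factor is the probability density that
an unconstrained walk from the same kernel covers the remaining distance r in
the remaining k steps (tabulated from 500 pre-simulated free walks per
kernel). The product behaves like a discrete mean-reverting
(Ornstein–Uhlenbeck-type) bridge while every realised step and turn stays
inside the empirical support. The number of steps is
max(2, round(distance / median daily displacement)).

Convergence: the walk must end within ε = half the kernel's median daily
displacement of the destination (it is then snapped exactly). On
non-convergence — including dead ends where no proposal can still reach the
destination — a new template is drawn uniformly at random, up to 100 attempts
per individual before a hard error. Coastlines/barriers are not enforced
during simulation; stops that fall outside the grid are skipped with a
warning during the dispersal stage.

## 4. Gut retention and seed deposition

Gut retention time follows a right-skewed normal distribution: the
Fernandez–Steel two-piece skew-normal density standardised to mean 12 days,
sd 8 days, skewness ξ = 2, truncated at d_max = 28 days. The daily excretion
weight R_d is the density evaluated at the integer day d (not integrated over
the day bin — only this convention reproduces the model's reference value
R_5 = 0.05378286). Given a binary feeding history F over the preceding d_max
days, the excretion probability is P_g = Σ R_d F_d / Σ R_d; it is monotone in
feeding and reaches 1 only when every day fed.

Each simulated day the individual visits `stops_per_day` ∈ {1, 2, 4} stops
(extra stops interpolate the day's movement segment). If any stop's cell
carries the source plant the day's feeding flag is set; each stop draws an
independent Bernoulli(P_g) excretion, and on success a seed count is sampled
from a truncated normal (μ = 1443, σ = 2057, truncated below at 1, rounded).
Histories are initialised with i.i.d. Bernoulli(0.21) entries — the fraction
of the highland range covered by the source plant — representing feeding
during pre-migration residence. For the same reason the origin day itself is
not a deposition stop: deposition starts with the first migration stop, and
after arrival the individual keeps feeding/excreting at the destination for
`settle_days` (default d_max) so late-ingested seeds can still be deposited;
`settle_days=0` reproduces a strict migration-only reading. Excretion does
not clear the feeding history (the probability conditions on past feeding
only).

Events summed per cell over individuals and stochastic repeats (default 25)
form the seed-rain map, with per-repeat layers retained for the stochastic
envelope. Seed fate is the elementwise product of seed rain with a binary
establishment-suitability mask supplied as an input layer (fitting the
underlying species distribution model is out of scope). Conservation is
exact: the seed-rain grand total equals the sum of sampled event counts.

## 5. Validation statistics

Elevation distributions of simulated versus observed seed-bearing dung piles
are compared with the two-sample Kolmogorov–Smirnov test (`scipy`'s
asymptotic p-value; the D statistic is cross-checked in tests against an
exhaustive ECDF-jump oracle to 1e-12). Deposition is additionally summarised
by landcover class, management zone and 50-m elevation bins. Stop-frequency
sensitivity compares runs at 1, 2 and 4 stops/day sharing landscape,
connectivity and trajectories, pooled over repeats.

## The synthetic island

The generator emulates the structure the pipeline assumes, not any real
island: a radially symmetric volcanic island (26 km across) with
piecewise-linear hypsometry — a steep summit cone holding the highland
seasonal range (350–480 m), a gentle coastal apron holding the lowland range
(20–140 m, confined to a 60°-wide southern sector), and a flat coastal
fringe. NDVI decreases with elevation plus noise; landcover is banded by
elevation; the zone layer labels the highland "agricultural" and the rest
"park"; suitability excludes the upper slopes plus 10% scattered cells. The
source plant is placed on an exact 21% of highland cells (sampled without
replacement). Seventeen template tracks — residency, migration, residency,
phase-labelled, daily fixes — use gamma step lengths (shape 5, scale 90 m)
and an AR(1) wrapped-normal heading deviation around the bearing to a
stratified destination; generator parameters are recorded in the bundle for
recovery tests. "Observed" dung piles are produced by one small dispersal
simulation at the island seed, subsampled, plus piles without the source
plant at random visited stops.

Geometry rationale: the highland sits on a steep slope and the lowland on a
gentle one so that migrants cross the source zone in a few days and then
spend the bulk of the 12-day-mean retention tail on the low slopes — the
regime in which endozoochorous deposition peaks below the source belt.
Residency centres are angle-stratified so that population convex hulls
recover the generator's bands (Jaccard ≥ 0.8 at default settings). What
passing tests on this system show is that the pipeline's machinery behaves
correctly under its stated assumptions; they do not validate the behaviour of
any real population, real NDVI seasonality, coastline barriers, or
GPS-error-contaminated tracks, none of which the generator emulates.

## Numerical choices and problem sizes

- Transport LP tolerance: constraints verified to 1e-6; optimality tested to
  1e-8 relative against an independent oracle.
- Hex-grid point lookup uses exact axial cube rounding; cell areas are equal
  by construction.
- UD raster resolution 128×128 over the padded bounding box.
- eRTG pull tables: 500 free walks per kernel, 24 distance bins per horizon,
  with a small floor so the pull density is strictly positive on support.
- Default test-suite and example problem sizes (population 200, 5 repeats for
  sensitivity analyses; 500 trajectories for fidelity checks) were chosen so
  the whole suite runs in well under a minute while keeping Monte-Carlo error
  far below the tested tolerances; the pipeline defaults remain the
  full-scale settings (1000 migrants, 25 repeats).
- Determinism: every stochastic component takes a `numpy` Generator; the
  pipeline derives per-stage substreams from the master seed via
  `SeedSequence.spawn`, and run manifests hash every artifact.

## Known limitations

- No habitat-dependent step selection, hourly movement, energy budgets, or
  barrier masking during trajectory simulation.
- Seed viability is unchanged by gut passage; no phenology of fruit
  availability; single plant species.
- The asymptotic KS p-value is inaccurate for tiny samples (both samples are
  required to have n ≥ 5).
- Convex-hull ranges cannot represent strongly non-convex seasonal
  distributions; this is inherited from the hull-based range definition.
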