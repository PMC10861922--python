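# Methods

This note documents the models and procedures implemented in `shearshift`,
the choices made where the design was genuinely open, and what the synthetic
tests do and do not establish.

## 1. Threshold light-level geolocation (`geolocate`)

**Model.** A daily position is recovered from the times ambient light crosses
a fixed threshold (10 lx). Sunrise and sunset are upward/downward crossings
with the crossing instant linearly interpolated between samples; strict
inequalities are used, so samples exactly at the threshold (plateaus) never
produce a crossing. Given the sun-elevation angle `a` assumed at a crossing
(default −4.5°):

* longitude from local apparent noon: the sun crosses the meridian of
  longitude `L` at UTC `12h − E − L/15`, where `E` is the equation of time,
  so `L = 15·(12 − E_h − t_mid)` with `t_mid` the twilight midpoint (UTC
  hours);
* latitude from day length: the half-day hour angle `H` satisfies
  `cos H = (sin a − sin φ sin δ) / (cos φ cos δ)`, solved for `φ` by Brent
  root-finding on (−89°, 89°), with `δ` the solar declination at the
  midpoint.

Declination and the equation of time come from the standard NOAA truncated
Fourier series (accuracy ≲ 0.3°, verified in tests against published
solstice/equinox and equation-of-time extrema).

**Refinement.** The closed form above treats `δ` and `E` as constant over the
day; their within-day drift biases longitude by up to ~0.1° away from the
solstices. By default the closed-form estimate seeds a two-equation solve
requiring solar elevation to equal `a` exactly at both crossing instants
(`scipy.optimize.root`). This uses the same information — two twilights plus
the assumed elevation angle — with no approximation error; on noise-free
1-minute light curves the median round-trip error is ~0.001° in longitude and
~0.004° in latitude.

**Degeneracy.** Near the equinoxes day length is ~12 h at every latitude and
the latitude bracket has no sign change; such fixes carry an `equinox` flag
and an undefined latitude. Longitude is unaffected.

**Filters.** Three fix-level passes, in fixed order: (1) fixes within ±15 d
of either equinox (a configurable window; the nominal dates Mar 20 / Sep 22
suffice at day precision) or with undefined latitude; (2) an iterative speed
filter — scanning forward, a fix whose implied great-circle speed from the
previous retained fix exceeds 55 km/h is removed and the scan re-anchors,
i.e. the *later* fix of an offending pair is deleted; (3) a bounding box
(22°W–42°E, 30–60°N). Track-level QC rejects tracks with fewer than 100
retained fixes or any gap > 61 d whose interval overlaps the first 244 d
("2 months within 8 months") after deployment. Two consecutive wild fixes can
evade any later-fix deletion rule (their mutual speed is moderate); the
filter inherits this property by construction.

## 2. Migration segmentation (`segment`)

Positions are smoothed with a centered rolling mean over 3 fixes (ends shrink
to 2). Each smoothed position is labelled against a buffer corridor spanning
the Strait of Gibraltar and western Europe: west of it = Atlantic, east =
Mediterranean, inside = ambiguous. Ambiguous labels inherit the preceding
unambiguous label (leading ambiguities backfill from the first unambiguous
one), giving hysteresis: a single fix wandering into the corridor never
creates a crossing. Crossing times are midpoints of the flanking fix
timestamps, which also dates crossings that fall inside multi-day gaps.

The packaged corridor is a hand-specified hexagon: a 4°-wide meridional band
over the strait below 36°N, slanting northeast to 60°N. It is ≥ 222 km wide
east–west at every latitude (minimum spec 170 km), spans 30–60°N
(≥ 555 km), and splits the study box into exactly one Atlantic and one
Mediterranean region (verified by a flood-fill test). Any user GeoJSON
polygon satisfying the same contract can replace it.

The longest Atlantic run (by duration between its flanking crossings; ties to
the earlier run) is the core migration. A track that never enters the
Atlantic yields "no migration" (a value, not an error); a run reaching the
end of the track is flagged open-ended with no return date. The core run is
split at the **apex**, the fix closest to the 98th linear-interpolation
percentile of migration latitudes (earliest on ties) — robust to a single
extreme outlier fix, unlike the maximum. Fixes before the apex are outbound;
the apex itself opens the return section, so return speed is measured from
the apex onward.

## 3. Movement metrics (`metrics`)

All distances use a sphere of radius 6371.0 km (one constant). Section speed
is summed consecutive haversine distance over elapsed clock time (UTC
contract; timestamps' representation cannot change speeds). The
initial-return speed uses fixes within the first 25% of the apex→return
*time* interval — time-based rather than fix-count so irregular dropout
cannot bias it (a count-based mode exists for sensitivity checks). The band
speed uses the maximal contiguous run of return fixes with latitude in
[35°N, 45°N]; each statistic is undefined (NaN, flagged) below 2 usable
fixes.

**Sea-route distance.** The land mask is rasterized on its bounding box; a
cell is ocean when its center is not inside any land polygon. Nodes are ocean
cell centers; edges are 16-neighbour moves (8 king + 8 knight) weighted by
haversine length; knight moves are blocked unless both flanking cells are
ocean, so routes cannot corner-cut across land. 16-connectivity keeps the
grid-metric distortion at ~2.8% (vs ~8% for 8-connectivity); the default
resolution is 0.25°, both exposed. The shortest path is found by A* with the
great-circle distance to the goal as heuristic — admissible because no
over-water path is shorter than the great circle — so the result equals plain
Dijkstra exactly (asserted against a networkx Dijkstra oracle in tests).
Endpoints snap to the nearest ocean cell within 2 cells; disconnected ocean
components raise an error naming the endpoints.

## 4. Inference (`infer`)

**SST proxy.** The climate covariate is the mean July–August SST over a fixed
box (12°W–1°W, 38–51°N), one scalar per year. The box mean is an unweighted
cell mean by default (cos-latitude weighting available); with a
latitude-gradient field centered on the box the two coincide.

**Area classification.** Median migration latitudes are strongly bimodal.
Tracks are grouped into three-year batches (2010–12, 2013–15, 2016–18 by
default) — a single pooled fit would blur a moving distribution, single years
give too few tracks — and a two-component univariate Gaussian mixture is
fitted per batch by EM: initialization at the 25th/75th percentiles plus 10
random restarts (pairs of observed values), tolerance 1e−8 on the
log-likelihood, best likelihood kept. The EM log-likelihood is asserted
non-decreasing on every fit. Each track joins the component with the higher
responsibility; the larger-mean component is "north". Zero-variance
components trigger a restart and, failing every start, an error; batches
under 4 tracks are an error.

**Subject-centering.** A predictor is decomposed exactly into each
individual's mean over its tracked years (between component) and the yearly
deviations (within component, zero for singletons); between + within
reconstructs the raw value identically (property-tested).

**Mixed models.** Gaussian responses: `statsmodels` MixedLM with one random
intercept per individual, maximum likelihood (not REML), so fits can enter
likelihood-ratio tests and AICc comparisons; optimizer falls back
lbfgs→bfgs→powell, and a boundary (~0) random-intercept variance is retained
with a warning. Binomial responses: a logit-link random-intercept model
maximized in-package by Gauss–Hermite quadrature (31 nodes; the approximation
used is recorded on the fitted object), with the fixed-effect covariance from
the numerical Hessian. Both routes are cross-checked against lme4
(`lmer`/`glmer` via Rscript) on small fixtures in the test suite. Note the
area-choice model is intrinsically weakly identified when every individual
keeps one area across years: the random intercept can absorb the outcome
entirely, inflating its variance and shrinking slopes — the analysis reports
it, but its CIs are expected to be wide.

**Tests and comparisons.** LRT: `χ² = 2(ℓ_full − ℓ_null)` with df the
difference in fixed-effect count, requiring nesting and identical data; its
type-I error is verified ≈ 0.05 by a 1000-replicate null simulation. AICc =
AIC + 2k(k+1)/(n−k−1) with k counting fixed effects plus variance parameters;
undefined (error) for n ≤ k+1. Non-nested comparisons (year vs SST;
beeline vs route distance) report ΔAICc.

**Bootstrap.** Parametric: draws of the fixed-effect vector from
N(β̂, Cov(β̂)) (SVD sampling, so degenerate covariances collapse the CI to
the point estimate), percentile 2.5/97.5 CIs, and the between-minus-within
difference CI computed on *paired* draws. Seeded and deterministic.

**First-track trend.** OLS of median latitude on year plus area, sex and
island, using each individual's first migration only (avoiding
pseudoreplication and age effects); reports the whole-model F and per-term
p-values, plus the AICc comparison against the rival model with SST in place
of year when an SST table is supplied.

## 5. Synthetic data (`synthetic`)

The generator draws the statistical core first (`simulate_summaries`): yearly
SST = base + trend·(year − start) + noise; individuals enter in a uniform
year and are retracked with geometric retention (mean 2 tracks); each
individual keeps one area, drawn with P(north) logistic in its mean SST;
destination latitude = area mean + individual intercept + β_B·(mean SST) +
β_W·(SST deviation) + residual. Return speed and return date follow the same
between/within structure in maximum latitude, plus outbound-speed coupling
and area/island offsets; departure date has an area offset only. Defaults are
the study conditions: area means 38.5/47.5°N, latitude slopes 0.662/1.421 °
per °C, speed slopes 0.207/0.227 km/h per °, phenology slopes 4.4/5.4 d per
°, SST base 18 °C with 0.15 °C/yr trend and 0.3 °C noise (a plausible
decade-scale warming of the eastern North Atlantic summer), individual sd
1.0°, residual sd 0.7° (keeping each area's marginal sd ≤ 1.5° so the
destination distribution is clearly bimodal).

`simulate_track` lays a migration out as daily noon fixes along a
coast-hugging piecewise path (colony → Gibraltar → southwest corner → up the
Iberian west coast → Biscay for northern birds), at the true outbound/return
speeds, with colony and destination residence; the path model is the simplest
shape making buffer crossings and route/beeline divergence realistic — no
foraging, wind or current. In the track model the return speed follows the
spec'd route-length rule (intercept + 0.0713 km/h per 100 km). Observation
noise is independent Gaussian per fix with latitude sd (1.0°) > longitude sd
(0.5°), mimicking the anisotropy of threshold geolocation, without temporal
autocorrelation; days drop out independently (p = 0.05). The mean radial
displacement this induces is ~100 km at study latitudes (the Monte-Carlo
expectation; longitude degrees shrink with cos φ), matching the order of
published geolocator errors. Ground-truth departure/return dates for
segmentation scoring are the times the *noise-free* path leaves the buffer
corridor on the Atlantic side and re-enters Mediterranean waters — the
corridor-edge events the estimator is defined to date; the phenology model's
dates are the Gibraltar passages, a constant offset that cancels in slopes.

`simulate_light_series` emits lux = 10·exp(0.8·(elevation + 4.5)), capped at
10⁴ lx — smooth, monotone in solar elevation and crossing 10 lx exactly at
−4.5° — sampled at a fixed interval from each day's true position.
`make_toy_coastline` provides Iberia, a northern-Mediterranean "Europe"
block joined across the Pyrenees, a Brittany promontory and an Africa block
leaving a 0.5°-wide Strait-of-Gibraltar channel; polygon edges deliberately
avoid half/quarter-degree lines so cell centers never sit exactly on a
boundary at common rasterization resolutions.

**What this does not emulate:** spatially/temporally autocorrelated
geolocation error, weather-dependent shading, stopovers and staging,
irregular coastlines, age effects, or tag failure modes. Passing tests show
the estimators are correct and calibrated under this model, not that field
data satisfy it.

## 6. Problem sizes and numerical settings

The test suite and acceptance script run at sizes chosen to make the
statistical checks sharp while staying lightweight: 50 round-trip positions
at 1-minute light sampling; 100 noise-free tracks for date recovery; a 1°
grid for the exhaustive Dijkstra equivalence (the A*/Dijkstra identity is
resolution-independent); 150-individual cohorts (≈ 290 migrations — the
study's scale) for slope recovery, with 100 replicates for CI coverage and
1000 null replicates for LRT calibration; 600-individual cohorts for the
reported point estimates. Bootstrap draws default to 1000 (500 inside
replicated studies). All randomness flows from explicit seeds; identical
(config, seed) reruns are bitwise identical.

## 7. Known limitations

* The buffer corridor and toy coastline are idealized; real-data runs should
  supply a real coastline GeoJSON and, if desired, the original buffer.
* The binomial area model's between-effect is weakly identified when areas
  are individually fixed (see above) — a property of the design, not the
  fitter.
* Route distance is a grid shortest path; its value depends (mildly, ~3%)
  on resolution and connectivity, which are exposed parameters.
* The speed filter's later-fix deletion rule cannot catch consecutive
  outliers; the equinox window (±15 d) is a convention, configurable.
* `paper_mode` locks the analysis constants; it does not bundle any field
  data, so estimating coefficients for a real population requires the
  corresponding tracking dataset plus a real coastline and SST product.
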