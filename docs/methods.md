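# Methods

This note records the models, the synthetic data-generating process, the
numerical choices and the known limits of what the tests demonstrate.

## Measurement model

Raw data are tower connection records `(phone_id, tower_id, timestamp,
event)` with `event ∈ {connect, disconnect, service}`. Dwell attribution:
each inter-event interval belongs to the tower of its opening event; a
disconnect opens an ownerless gap; a service record renews the current
tower; the final interval of a phone is clipped at the stream end. Hour `t`
denotes the interval `(t−1:00, t:00]`, implemented as the half-open window
`[t−1:00, t:00)` so no second is counted twice. Positions are dwell-weighted
tower centroids — a convex combination of tower coordinates, invariant to
rescaling dwell. Homes pool night dwell (0:00–6:00, all days of the raw
period); phones without night dwell are excluded and counted.

Sample selection keeps phones with ≥ 20 records and a first-to-last span
≥ 96 h, applied to the raw stream (both thresholds configurable). Distance
from home uses the 501-interval scheme: edges `[0,100], (100,200], …,
(49900,50000], (50000,∞)` meters; a boundary value `100k` falls in the lower
interval, `d = 0` in the first; the value carried forward is the interval
midpoint, pinned to 50,000 m (censored) beyond 50 km. Coordinates are planar
meters throughout; `io.equirectangular` and `io.haversine` adapt real
lon/lat inputs, since projection error at city scale is far below
tower-spacing measurement error.

Labelling precedence is home > park > mall > other: home when the raw
(unbinned) distance is strictly below 500 m; park/mall when dwell summed
over the union of that kind's tagged towers strictly exceeds 40 min of the
hour. The park-before-mall order is configurable and conflicts (both
criteria met) are counted in the run log. A phone-hour spanning cities is
assigned the city with maximal dwell, ties to the lexicographically smallest
id. City bounding regions for Voronoi clipping default to the tower bounding
box padded by one median nearest-neighbour spacing.

## Choice model

Utilities are `w = γ_{jyl} + δ_{tl} + X_{jyt}β_l + η_{jytl} + υ` for
`l ∈ {m,p,o}` and `w = υ` for home (the normalization), with i.i.d. Gumbel
`υ`. Aggregation gives log-odds linear in parameters, estimated by three
independent OLS fits sharing one design: intercept, city-day dummies and
hour dummies (first category of each omitted — reference coding is
arbitrary and effects are invariant to it), plus air-quality covariates.
Log-odds are computed as `ln(n_l / n_h)`: the ratio form is exactly
invariant in floating point to rescaling all counts by a common factor,
which is what makes multi-phone ownership (k phones per user) harmless for
this stage. Zero cell counts are a hard error by default; an `add_half`
continuity correction (0.5 added to all four counts of affected rows, rows
counted) and a `drop` policy exist because desk-scale panels otherwise
break. A level dummy never observed in the data is removed from the design
(and a counterfactual asking for that level raises).

Counterfactual shares include the estimated cell residuals η̂ by default, so
the observed scenario reproduces observed shares exactly and the level
switch is evaluated row by row with all other variables at observed values;
a fitted-only mode exists for smooth prediction. The percent change is the
averaged difference over the averaged baseline share (one headline percent
per location), not an average of ratios. The continuous-AQI marginal effect
is the analytic derivative of the inverted logit at sample-mean shares,
verified in tests against central finite differences; the four-location
derivative vector sums to zero identically.

Bootstrap CIs are percentile, seeded, with two resampling units: panel rows
(city-day-hour cells — the i.i.d. index of the cell shocks, used for the
calibration study) and city-day blocks (the applied default, respecting
within-day dependence). Replicates that fail (e.g. a resample with no
pollution-level contrast) are dropped and counted; more than 10% failures is
an error.

## Distance model

Latent distance is linear in the same covariate structure with normal error;
the observed midpoint is censored at 0 and 50,000 m. The log-likelihood sums
the normal density for interior observations and tail probabilities for
censored ones; the gradient is analytic (inverse-Mills terms computed in log
space for stability); σ is parameterized as `log σ` for unconstrained BFGS
from an OLS start. Convergence requires the gradient sup-norm below
`1e-6·max(1, |ℓ|)`; the iteration trace is stored and tested to be monotone.
Standard errors come from the inverse numerical Hessian of the analytic
gradient. With midpoint binning the smallest observed value is 50 m, so the
lower limit effectively binds only for recorded zeros — documented, and the
limits are configurable. Midpoints are treated as exact values; an
interval likelihood is out of scope. Both a latent effect (coefficient
contrast averaged over rows) and an expected-observed effect (mean change of
the doubly-censored normal mean, `E[d] = L·Φ(a) + μ(Φ(b)−Φ(a)) +
σ(φ(a)−φ(b)) + U(1−Φ(b))`) are always reported, since they answer different
questions and coincide only without censoring. The city-day-hour shock of
the distance model cannot be separated from the individual error at this
fixed-effect resolution and is folded into ε.

## Synthetic world

Defaults are the study conditions: 6 cities, 4 days, 16 analysed hours
(7:00–22:00), AQI confined to 25–225 with a "wave" pattern — a Gaussian bump
in time peaking ~70% into the period with city-index-proportional lags
(emulating a pollution wave sweeping across cities). Towers sit on a
jittered m×m grid (default 49/city over a 10 km square, ±12% jitter); parks
and malls are axis-aligned squares placed uniformly; homes are uniform.
Night hours are generated at the true home for every day plus one trailing
morning, making the raw span ≈ 102 h so the 96-h filter is satisfiable and
home inference is identifiable by construction.

Baseline choice-utility levels target clean-air shares near home 40%,
other 55%, park 2.5%, mall 1.5% — the observed orders of magnitude (park
and mall are low-single-digit shares). The default AQI response is negative
for all away-from-home options and strongest for parks
(−0.0020/−0.0012/−0.0010 log-odds per index point for p/m/o), sized so a
Good → Heavily Polluted swing (~150 points) moves several percentage points
of population home. City-day popularity shifts have SD 0.10, cell shocks SD
0.05. Choices can be drawn per user by Gumbel-argmax or per cell by
multinomial on the closed-form probabilities — distributionally identical;
`gen_panel_counts` is the fast aggregate path for estimator studies.

Tower-assignment noise splits each hour across the k = 3 nearest towers
with weights ∝ exp(−distance/λ) (λ defaults to half the tower spacing),
optionally perturbed by a Dirichlet draw whose concentration controls noise;
connection duration is assumed to *decay* with distance (i.e. to grow with
proximity), the only monotone reading under which the weighted centroid
tracks the phone. Intended distances for non-home hours follow the latent
linear model with location-type base distances (mall 2.5 km, park 2 km,
other 1.8 km), σ = 1.2 km, censored below at zero; "other" hours are placed
at that distance on a uniform bearing (clipped to the extent), park/mall
hours at a uniform point inside a same-city facility polygon, whose implied
geometric distance supersedes the draw — this keeps facility labelling
testable while the distance stage remains correctly specified in the
direct Tobit simulations.

The `substitution` parameter s ∈ [0,1] makes utilities respond to
`AQI − s·(city-day mean AQI)`: with s = 1 a uniform daily shift leaves every
hour's choice (hence the daily mean share) unchanged — perfect intra-day
rescheduling; s = 0 is pure cancellation; intermediate s yields daily/hourly
effect ratios near 1−s. Because the daily mean is absorbed by the city-day
fixed effects, the hourly regression recovers the same coefficients in every
regime.

What the generator does not emulate: road networks, trip chaining,
persistent individual day-to-day trajectories, tower capacity constraints,
or pollution-correlated measurement error. Passing tests therefore show the
estimators are correct for the assumed DGP and robust to its noise — not
that real operator data satisfy those assumptions.

## Problem sizes and numerics

Recovery studies run at 5,000 users/city (choice stage, 384-cell panel),
n = 100,000 with ~20% upper censoring (Tobit, 200 replicates), 10⁶
stratified sample points (Voronoi Monte-Carlo check — a jittered 1000×1000
grid, whose stratification cuts the per-cell variance of the area estimate
well below the 2% check tolerance), B = 200 bootstrap with 100 replicates
for the coverage study. The end-to-end log-level pipeline runs at a few
hundred users/city, which keeps raw streams near 10⁶ records; all stages
are vectorized. These sizes are the package's chosen desk-scale study
conditions and are stated in the relevant docstrings.

Degenerate inputs: duplicate tower coordinates, all-censored Tobit samples,
rank-deficient designs (named columns), empty panel cells, unknown AQI
levels, negative distances and zero-dwell phone-hours all raise with
specific messages rather than propagating NaNs.

## Known limitations

- The aggregated regression needs every cell count positive; very small
  panels need the continuity correction, which introduces a small bias.
- Percentile bootstrap with 384 rows and ~45 parameters is slightly
  conservative/liberal depending on the estimand; the calibration study
  checks only the home-share level-switch effect.
- The Tobit treats binned midpoints as exact; with 100 m bins the grouping
  error is negligible relative to σ ≈ 1 km but would matter for finer
  targets.
- The "official daily AQI" has no public construction rule; the daily mean
  stands in and is labelled as such.
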