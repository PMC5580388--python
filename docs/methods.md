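# Methods

## Data model and conventions

Telemetry fixes are timestamped planar positions in projected meters; the
reader refuses coordinate tables that look like longitude/latitude degrees
(values inside the lon/lat bounds with sub-degree extent) and asks the user
to project first. Timestamps are naive local clock time, matching a field
protocol in which all arithmetic happens in one time zone; minute resolution
is sufficient. Fixes are held as pandas DataFrames (one row per fix), the
idiomatic container for movement data in scientific Python; the documented
invariants (strictly increasing timestamps per frog, finite coordinates,
carried tadpole counts in [0, 25] when known) are enforced at read time.
Unknown tadpole counts and behaviors stay missing; they are never coerced to
zero.

## Phase segmentation

A full track splits into tadpole transport (TT), from the first observed fix
through the fix at the last deposition event, and homing (HT), from that
same fix to the first fix within `r_home` of the territory centroid. Choices
behind that rule:

* **Territory centroid.** The centroid of capture locations flagged with
  territorial behavior (calling, courtship, aggression); an unweighted
  arithmetic mean. No home-range polygon is estimated.
* **Return rule.** "Returned" is operationalized as the first fix within
  `r_home` = 7 m of the centroid — the radius of a disc with the species'
  average defended area of ≈ 151 m². Configurable.
* **Shared split fix.** The fix ending the last deposition visit belongs to
  both phases, so `duration(TT) + duration(HT) = duration(full)` and
  distances partition exactly. If the tadpole count drops during a visit,
  every stationary fix at the pool up to actual departure is part of that
  visit, hence of the TT; homing starts with the first step away from the
  pool.
* **Incomplete homing.** A frog that never re-enters the `r_home` disc
  yields an HT flagged `complete=False`, never a silently truncated one.

## Durations, speeds, interpolated starts

Tracking is confined to the 07:00–19:00 daylight window, so the active
duration of a track is the elapsed time minus 12 h per night spanned
(equivalently, the summed overlap with the daily window — the test suite
checks this identity against a brute-force per-day computation). Fixes
stamped outside the window are treated as clock drift and clamped to the
window edge with a warning, because the protocol precludes true night fixes.
Mean speed is path length over active duration; per-step speeds use
night-excluded step durations. Because transports are usually detected in
progress, the untracked beginning is approximated by the straight chord from
the territory centroid to the first fix — an explicit minimum-distance
estimate that can never exceed the true path (a seeded test verifies the
bound on simulated pre-encounter walks).

## Precision statistics

Three per-trajectory statistics, all invariant under rigid motions of the
coordinate system:

* **Straightness coefficient.** Ideal route length over realized path
  length. The ideal route for a TT is the piecewise chord from the first fix
  through the visited deposition sites in visit order; for an HT it is the
  single chord from the last deposition site to the territory centroid.
  During a multi-pool transport each fix's goal is the deposition site
  visited next (chronological attribution). With positional noise on a
  near-straight path the chord can marginally exceed the measured path, so
  SC > 1 is clipped to 1; a warning is emitted when the excess exceeds
  numerical tolerance (1e-9), since that indicates measurement noise rather
  than rounding.
* **Angular deviation.** Per non-final fix, the absolute circular difference
  between the bearing to the current goal and the realized step bearing,
  wrapped to [0°, 180°]; zero-length steps are skipped and a fix coinciding
  with its goal is skipped with a warning (its ideal direction is
  undefined). The per-trajectory value is the mean; study-level summaries
  average per-trajectory means (grand mean of track means), with pooling
  available.
* **Perpendicular deviation.** Distance from each fix to the infinite line
  through its current ideal chord segment — "distance from the straight
  path" — with clamped-segment distance available as an option.

Directionality is tested with the Rayleigh statistic `Z = nR̄²` and the
series approximation
`p = e^{-Z}[1 + (2Z−Z²)/(4n) − (24Z−132Z²+76Z³−9Z⁴)/(288n²)]`, clamped to
[0, 1]; the suite checks it against a 20,000-draw Monte Carlo null (max
error < 0.01 for n in [5, 50]) and its type-I error at n = 22 (0.047 at
α = 0.05 over 10,000 replicates). The pipeline runs the test on
goal-relative step angles (each step rotated so its ideal direction is 0°)
pooled per phase; raw absolute step headings are exposed for any other
convention. Trajectories with ≤ 3 locations are excluded from directionality
analysis.

## Pool visits and depositions

Field studies classify visits by direct observation; with positional data a
proxy is required: a maximal run of consecutive fixes within `r_visit` of a
pool center is one visit, the nearest pool winning where radii overlap, and
a single out-of-radius fix shorter than 30 min is merged back (tracking
noise). `r_visit` defaults to 1 m for real data and should be set to a few
multiples of the telemetry error (2.5 m is used for the synthetic data,
whose jitter sd is 0.5 m). Deposition is inferred if and only if the pool
was available and the carried count strictly dropped across the visit
(last known count at arrival vs first known count after departure); a count
increase is a validation error, and unknown counts leave the flag unknown.
Visit detection is monotone in the radius (tested), and exploration after
complete deposition is flagged as any visit arriving with a known count of
zero.

## Mixed models and model selection

The comparisons the pipeline runs — average speed per trajectory vs
tadpoles-present, and the three precision responses vs whether an
unavailable pool was encountered — are random-intercept mixed models with
frog identity as the grouping factor (repeated trajectories per
individual). statsmodels has no gamma or beta GLMMs, so the marginal
likelihood is implemented directly: the random intercept is integrated out
with 25-node Gauss–Hermite quadrature (closed form for the Gaussian
family), and the likelihood is maximized with L-BFGS-B followed by a
deterministic Nelder–Mead polish (gradient tolerance 1e-8, 500 iterations,
starting values from the fixed-effect GLM). Standard errors come from the
finite-difference Hessian. Fits are checked against statsmodels MixedLM
(Gaussian, agreement to ~1e-5) and against frozen glmmTMB 1.1.9 maximum
likelihood fits of seeded datasets (gamma and beta; coefficients agree to
~2e-3, log-likelihoods to ~0.01, the residual being Laplace vs quadrature).

Family/link choices: speeds and deviations are strictly positive and use the
gamma family with a log link; a logit link is sometimes quoted for such
models but has no usable inverse image on (0, ∞), so requesting it emits a
warning and the log link is used. Straightness coefficients live in (0, 1]
and use the beta family with a logit link; exact 1s are handled with the
standard boundary squeeze `y' = (y(n−1) + 0.5)/n`, applied only when
boundary values are present. The parameter count `k` for AICc includes the
fixed effects, the dispersion/scale parameter and the random-intercept
variance, matching lme4/glmmTMB conventions. Non-converged fits are flagged
and excluded from selection with a warning; a random-effect variance at the
optimization boundary is flagged singular but retained.

The weather analysis is a configured instance of the same machinery:
per-interval speeds (distance moved within each 3-h daylight block over the
covered time, with steps apportioned across blocks in proportion to time —
the totals conserve path length and active duration exactly) are merged with
the interval weather series and modelled with a gamma GLMM; all subsets of
{tadpoles present, time of day, temperature, rain} are ranked by AICc
(`tadtraj.pipeline.weather_speed_selection`).

Model comparison follows the information-theoretic workflow: a full model is
reported over its null only when ΔAICc = AICc(null) − AICc(full) > 2; with
several candidate terms, every subset is fitted (all-subset modeling),
models within ΔAICc ≤ 2 of the best are retained, and coefficients are
model-averaged with Akaike weights renormalized within the subset. The
default is the full (zero-substitution) average, with the conditional
average as an option; averaged standard errors use the
`Σ w √(se² + (β−β̄)²)` form.

## Synthetic study generator

The generator reproduces the study design so that every stage has ground
truth: 13 pools in a cross at 20 m spacing (one center pool, three per arm);
"every second pool removed" is realized by removing the center and the 40 m
ring — the only alternating pattern on this geometry that leaves 8 pools
available. Territory centers are drawn uniformly in a 10–60 m annulus around
the array, at least 12 m from any pool. Each frog carries a truncated-normal
tadpole load (mean 8.5, sd 4.9, clipped to 1–25), visits an itinerary of 1–4
pools (probabilities 0.2/0.35/0.3/0.15, mean 2.4; nearest-unvisited pool
with probability 0.7, otherwise a random known pool; removed pools may be
visited, the last pool must be available) and splits its load across the
available pools of the itinerary, each receiving at least one tadpole.

Movement is a two-state Markov walk at the fix cadence (intervals uniform in
30–60 min; the clock skips from 19:00 to 07:00 with the frog stationary).
In the move state the heading is von Mises around the bearing to the current
goal with concentration κ (default 8) and the step length is gamma(shape 2)
with mean `step_rate_move × interval × 1.41` while tadpoles are carried (the
transport speed factor) times a lognormal per-frog factor (sd 0.15) that
gives the random-intercept models something to absorb. Step speeds are
capped at 70 m/h while transporting and 20 m/h while homing — homing is
rest-dominated in this system (tens of meters over ~10 h) and never a
sprint. Transport uses move/pause transition probabilities 0.75/0.2; homing
0.2/0.8. With these defaults a 200-frog run gives mean transport speed
≈ 9.7 m/h vs homing ≈ 7.6 m/h, homing duration ≈ 10.5 h, and per-phase
straightness ≈ 0.71/0.93 — the qualitative structure of the system (faster,
directed transport; slow, direct homing).

Observation noise is a 0.5 m-sd Gaussian jitter tied to the true position: a
pausing frog is re-recorded at identical coordinates, so step speeds include
exact zeros, as real stop-and-go telemetry does. Three geometric constraints
make ground truth recoverable from fixes alone, encoding the fact that field
visits were classified unambiguously by direct observation: travel fixes are
rejected (redrawn, up to 40 attempts, else the frog pauses) within 4.5 m of
any non-goal pool; visit fixes sit at the pool center; and homing travel
fixes stay outside a 9.5 m clearance ring around the territory, a step
ending inside the ring settling the frog at 4.5 m from the center. With
r_visit = 2.5 m and r_home = 7 m these margins are ≥ 4 jitter standard
deviations on both sides, so radius-based detection reproduces itineraries,
phase labels and deposit conservation exactly (verified over 100 seeded
studies). Disabling the pool-avoidance constraint (`pool_exclusion_m = 0`)
recovers the unconstrained walk, under which κ = 0 gives the exact 90° mean
deviation expectation.

Frogs that do not finish transport and homing within 5 simulated days are an
error from `simulate_transport`; at the study level they are kept as
truncated tracks flagged incomplete (the field study likewise had animals
that never finished). Randomness is organized as named substreams spawned
from the seed (landscape, covariates, one per frog), so adding frogs or
operations never perturbs existing tracks; equal configurations give
byte-identical CSV fixtures.

The covariate generator provides a sinusoidal daily temperature cycle with
Gaussian noise and zero-inflated-gamma rainfall per 3-h daylight interval
(07–10, 10–13, 13–16, 16–19), plus two observation-table generators for
model-recovery experiments: gamma per-trajectory speeds at the observed
phase means (10.16 vs 7.22 m/h, shape 5, 16 frogs × 2 phases) and a
standardized-covariate Gaussian table for all-subset selection experiments.

### What the generator does and does not emulate

It emulates the sampling design (fix cadence, daylight window, night gaps,
encounter-trimmed transport starts), the landscape, goal-directed
stop-and-go movement with the transport/homing asymmetry, load-splitting
deposition, and positional observation noise. It does not emulate habitat
heterogeneity, pool choice driven by pool quality, serially correlated
behavior beyond the two-state chain, true telemetry error structure
(unreported for this method), or disturbance by the observer. Passing
round-trip tests therefore show the pipeline is internally correct under
unambiguous conditions; on real data, visit classification inherits the
uncertainty of the radius proxy, which is why `r_visit` is configurable and
reported in the run log.

## Problem sizes used in the checks

The acceptance-style tests run at the sizes their guarantees are stated at:
1,000 random tracks for oracle equivalence, 20 angle sets × 20,000 Monte
Carlo draws for the Rayleigh p, 10,000 replicates for its type-I error, 200
completed single-pool transports per κ ∈ {0.5, 2, 8, 32} for metric
monotonicity, 200 datasets of 16 frogs for speed-ratio recovery, 200
all-subset replicates (n = 200, one true 1-sd effect among four candidates)
and 500 no-effect replicates for the selection error rates, and 100 seeded
three-frog studies for exact round trips. The κ-monotonicity experiment uses
single-pool itineraries so the concentration effect is measured on a fixed
goal geometry, and resimulates the rare tracks that do not finish within the
5-day cap (completed-transport sampling, mirroring the admission rule that
only finished transports enter the precision analysis).

## Known limitations

* The GLMM fitter supports a single random intercept (the designs here need
  nothing more); no random slopes or crossed effects.
* The Rayleigh p series approximation is used as published tooling does; for
  n < 5 the test refuses rather than approximates.
* The simulator's arrival/clearance constraints slightly bias realized
  headings near pools and the territory; metric-level tests that need the
  pure heading distribution switch those constraints off.
* AICc with very small n (n − k − 1 ≤ 2) is dominated by the correction
  term; the pipeline reports it as defined, and `aicc` refuses
  n ≤ k + 1 outright.
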