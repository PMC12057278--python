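# Methods

This note documents the models, conventions and design choices behind
motuskit, in the spirit of a statistical package's model documentation:
what is computed, under which assumptions, and what the synthetic-data
tests do and do not demonstrate.

## Detection model and filtering

A coded tag emits one burst every `burst_interval_s` (default 12.7 s).
Runs are maximal chains of bursts of one tag at one receiver whose gaps
are within `gap_tolerance` (default ±1.0 s) of an integer multiple
m ≤ 1 + `max_missed` (default 2) of the burst interval. The tolerance is
required for real receiver clocks; the multiple allows missed bursts
inside a pass. Runs of fewer than `min_run_length` = 3 bursts are removed
as probable noise. The impossible-location filter is deliberately
declarative: a hard ground-speed cap (150 km/h between successive run
midpoints — generous for a ~50 g thrush even with strong wind support)
plus user-supplied region × date exclusion rules, because "impossible" is
ultimately expert knowledge about a species' timing and routes. Both
filters partition their input and log removals with reason codes
(`short_run`, `speed`, `rule:<name>`), and both are idempotent.

## Solar timing

Sunset is the NOAA solar-position algorithm at zenith 90.833° (geometric
horizon + standard refraction), converged with two fixed-point passes;
agreement with an independently transcribed NOAA-spreadsheet oracle is
well under 2 min across the study domain (41–44°N, Aug–Oct). A *night*
runs from local sunset to the next local noon, with "local" defined by a
fixed UTC offset (default −4 h, correct for the study region in fall);
this avoids a timezone-database dependency and only has to bin
detections, not compute sun positions. `minutes_after_sunset` refers any
timestamp to the sunset opening its night, so post-midnight departures
measure from the previous evening. Sunset is evaluated at the receiver
that made the detection (territory vs tower differences are < 1 min at
these scales, but the convention is fixed).

## Departure events

The committed reading of "not detected at the origin again" is
region-based: the last in-window night with a post-sunset origin-region
detection, with no origin-region detections later that calendar year.
Birds whose origin detections continue past the window, or that are only
detected before sunset, yield no event — absence is a valid outcome
(death, tag failure, residency). The time-of-night outlier rule is
flag-and-exclude with both criteria exposed: an absolute cutoff (300 min)
and a gap cutoff (60 min beyond the next-latest bird). Flagged events are
excluded only from time-of-night analyses; their departure dates remain.

## Peak passage and crossing speed

Passage time is the vertex of an OLS quadratic of signal (dB) on time.
"Clear peak" is operationalized as: negative curvature, vertex strictly
inside the run's span, r² ≥ 0.5, ≥ 5 bursts. Runs failing any criterion
are excluded from speed estimation with a reason, mirroring the exclusion
of birds without a usable peak; they still carry their midpoint time for
pace bookkeeping. Near-linear signals can place the algebraic vertex
astronomically far away; the fit then reports the run midpoint with
`clear = False`. Distances are great-circle on the IUGG sphere
(R = 6371.0088 km); against WGS-84 geodesic references the error is
≤ 0.17% in-domain, far below the biological signal. Crossing records
require north and south peaks on the same night, in order; the speed is a
straight-line lower bound, as the flight path between towers is unknown.

## Wind and tailwind

Wind is a single pressure level (925 mb ≈ 675–825 m, typical nocturnal
thrush flight altitude), u toward 090°, v toward 000°. Interpolation is
linear in time and bilinear in space (trilinear overall); out-of-range
queries raise errors naming the axis. Direction is the direction the wind
blows *toward*, so cos(β) = 1 is a following wind and the tailwind metric
is positive when the bird benefits — with bearing 180°, a due-north flow
(v = −10) gives +10 m/s. The trigonometric form Vw·cos(β) and the vector
form u·sin(θ) + v·cos(θ) are both computed and asserted equal at every
call. Tailwind is evaluated at the departure tower at the event's
first-detection time; nearest-node versus bilinear interpolation was an
open choice and bilinear is declared.

## Pace sections

Sections join successive detections of one bird at distinct towers in the
corridor/south-shore regions. The km/day denominator uses fractional
elapsed days between endpoint times (peak time when clear, run midpoint
otherwise); the integer calendar-day difference is kept separately as the
`days_between` covariate. Same-day and consecutive-day sections are
excluded: they measure a single overnight flight, not stopover-inclusive
pace. Midpoint latitude is the arithmetic mean of the two tower
latitudes.

## Model selection and averaging

Four responses, four global models:

| response | family | global terms |
|---|---|---|
| departure day-of-year | Gaussian LM | age + sex + year + age:sex |
| minutes after sunset | Gamma GLM (log) | age + sex + year |
| crossing speed (km/h) | Gaussian LM | age + sex + year + tailwind |
| pace (km/day) | Gaussian LMM (bird RI) | age + sex + year + midpoint lat + distance + days between + departure day |

Coding: age adult = 1, sex male = 1, year numeric. All candidates are
subsets of the global terms (marginality: the interaction requires both
mains), always including the intercept-only model. Every fit is full ML:
OLS log-likelihood for LMs; for the Gamma GLM the coefficients come from
IRLS (they do not depend on the dispersion) and the shape is then
profiled out by a bracketed 1-D ML solve, entering the reported
log-likelihood and k; LMMs use ML rather than REML so that AICc is
comparable across fixed-effect structures. k counts every estimated
parameter: coefficients + 1 (residual variance or Gamma dispersion), + 2
for the LMM (random-intercept + residual variance). At the
variance boundary the LMM collapses to OLS; such fits are flagged
`singular` and, when the optimizer's covariance degenerates, the
OLS-equivalent estimates and likelihood are reported (they are the ML
solution there). With all-singleton groups the split between
random-intercept and residual variance is not identifiable; fixed effects
and the total likelihood — the quantities model ranking uses — are.

Support rule: ΔAICc ≤ 2 **and** ≥ 2 AICc better than intercept-only.
Weights are `exp(−Δ/2)` normalized over the full candidate set. The
uninformative-parameter screen flags any term whose presence in a
supported model costs AICc relative to the nested model lacking only that
term; flags are reported, never auto-applied. Averaging is full
(zero-substitution) over the supported set with renormalized weights and
the unconditional SE (within-model variance plus between-model spread);
conditional averaging and small-sample CI adjustments were open choices —
full averaging and ±1.96·SE are declared. The companion pooled-variance
two-sample t test is provided for descriptive group contrasts.

## The synthetic study generator

The generator emulates the study conditions end to end and is the ground
truth for every test:

* **Cohort**: 60 adults + 82 juveniles over 2016–2019. Departure
  day-of-year ~ Normal(271 adult / 262 juvenile, sd 8), truncated to
  Aug 25 – Oct 15; the sd is back-computed from the reported group
  standard errors. Nocturnal delay ~ Gamma(shape 4) with means 72 (adult)
  / 93 (juvenile) min. Airspeed ~ Normal(43, 5) km/h.
* **Wind selectivity**: each bird departs on the first night (from its
  drawn date, capped at 14 nights and the window end) whose 925 mb
  tailwind at the origin, bearing 180°, meets its age-class threshold
  (+1 m/s adults, −6 m/s juveniles). This is the *only* pathway by which
  age affects speed: groundspeed = airspeed + 3.6 × tailwind, so adults
  are faster across the barrier purely because they pick better nights.
* **Geometry**: 13-tower origin cluster near (42.69, −80.49), two
  south-shore towers 0.6° latitude across the water barrier, four
  corridor towers ~240–300 km apart down to 33°N. Birds fly due south
  with small per-leg longitude drift; a pass is detected when the track
  passes within `detection_radius_km` (3.2 km) of a tower, with the arc's
  peak signal attenuating toward the radius edge so that marginal passes
  lack a clear peak. Radius, drift (0.12°/leg) and corridor alignment
  were set once so the default cohort yields ≈ 30 clear crossings and
  ≈ 30 pace sections from ≈ 23 birds — the scale of the study being
  emulated — and are not tuned per test.
* **Signals**: s(t) = peak − curvature·(t − t_pass)² + N(0, 3 dB),
  bursts every 12.7 s above an absolute threshold, each burst dropped
  with probability 0.05; the departure arc's first burst is pinned to the
  true departure instant (it *is* the event). Short false runs (1–2
  bursts, real or phantom tag ids) are injected at 0.02 runs per
  tower-day.
* **Pace**: post-crossing legs draw per-leg pace ~ Normal(71.6 adult /
  47.3 juvenile, sd 15) km/day; elapsed time to the next tower is
  distance/pace, which realizes the stopover-day contrast between ages.
* **Determinism**: every stage draws from substreams keyed by
  (seed, purpose), so identical configs reproduce byte-identical files.

What the generator does **not** emulate: radio propagation physics
(antenna patterns, polarization, topography), tag clock drift beyond the
gap tolerance, partial-season tag failure, curved flight paths, regional
pre-migratory movements, or spatially structured wind beyond an AR(1)
field with a domain-wide nightly component. Passing recovery tests
therefore demonstrate the *pipeline's* correctness under the stated
motion/signal model, not robustness to every pathology of field data.

## Numerical choices

* Quadratic peak fits center time before `polyfit` for conditioning.
* Gamma shape ML uses Brent root-finding on the profile score in
  [1e-6, 1e8] with an exact-fit guard.
* AICc requires n > k + 1 and raises otherwise; candidate sets whose
  largest model violates this are skipped with a log entry.
* Truncated-normal draws use rejection sampling with a zero-mass
  configuration check up front.
* Wind components are clipped to ±40 m/s.
* Problem sizes in the test suite: the replicated recovery study uses 50
  seeds at the full study scale; structural tests use a 24-bird cohort.

## Known limitations

* The departure rule cannot see true take-off, only first detection; the
  generator pins these together, real data cannot.
* Crossing speed is a straight-line lower bound on track speed.
* Pace blends stopover and flight by construction; it is a proxy, not a
  flight-speed measurement.
* With ≤ 4 birds contributing multiple sections, the random-intercept
  variance is weakly identified and frequently boundary-singular; the
  reporting treats that as expected, not as an error.
* The Gamma GLM requires strictly positive timing values; non-positive
  rows (possible if a detection precedes sunset) are dropped with a
  logged count.
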