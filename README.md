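# motuskit

Automated radio-telemetry (Motus-style) migration analysis for songbirds
tracked from their breeding/natal region: from raw coded-tag detections to
age-class comparisons of **fall departure date**, **nocturnal departure
time after sunset**, **barrier-crossing flight speed** with a tailwind
covariate, and **southbound migration pace** — plus a synthetic-study
generator that provides ground truth for every stage.

## Who this is for

Movement ecologists working with automated VHF telemetry networks, where
all tags share one frequency and carry unique burst codes (one burst every
~12.7 s here). Receivers log every decoded burst, including false
detections from radio noise and tag collisions, so the analysis starts at
the filtering layer and ends at multi-model inference.

## The analysis

1. **Detection filtering.** Bursts are grouped into *runs* (consecutive
   bursts of one tag at one receiver, allowing a bounded number of missed
   bursts). Runs shorter than 3 bursts are treated as noise; runs implying
   impossible movement (> 150 km/h between receivers, or matching declared
   region × date exclusions) are removed, each with a logged reason.
2. **Departure events.** A bird's fall departure night is the last night in
   the migratory window (Aug 25 – Oct 15) with a post-sunset detection at
   an origin-region receiver and no origin detections afterwards that
   year. Nocturnal timing is minutes from local refraction-corrected
   sunset (NOAA solar-position algorithm, zenith 90.833°) to the first
   detection that night; extreme late values are flagged by an absolute
   (> 300 min) and a gap (> 60 min past the next-latest bird) rule.
3. **Barrier-crossing speed.** A tag passing a receiver traces a parabolic
   signal-strength arc; the OLS quadratic vertex estimates peak passage
   time. Crossing speed = great-circle distance between the last
   north-shore and first south-shore tower ÷ time between their peaks,
   for birds detected on both shores the same night with *clear* peaks
   (negative curvature, interior vertex, r² ≥ 0.5, ≥ 5 bursts).
4. **Tailwind.** Gridded 925 mb u/v wind is interpolated (linear in time,
   bilinear in space) to the departure tower and time; the tailwind
   component is `Vw·cos(β)` = `u·sin(θ) + v·cos(θ)` for flight bearing
   θ = 180°, positive when the wind follows the bird.
5. **Migration pace.** Successive detections of a bird at distinct towers
   south of the barrier form sections; km/day = tower-to-tower
   great-circle distance ÷ elapsed time, excluding same/consecutive-day
   sections (those measure single flights, not stopover-inclusive pace).
6. **Model selection.** Per response: all subsets of a global model
   (respecting marginality for the age×sex interaction) are fitted by full
   maximum likelihood — Gaussian LM for date and speed, Gamma GLM with log
   link for time-of-night, random-intercept (bird) LMM for pace — and
   ranked by `AICc = −2LL + 2k + 2k(k+1)/(n−k−1)`. Models with
   ΔAICc ≤ 2 that beat the intercept-only model by ≥ 2 AICc are
   *supported*; supported models are screened for uninformative
   parameters, and coefficients are model-averaged (full averaging,
   unconditional SE, 95% CI).

## Worked example

Simulate a default study (60 adults, 82 juveniles, 2016–2019, adults
departing ~9 days later in the season but ~21 min earlier at night and
demanding more tailwind before leaving) and run the full pipeline against
the generator's ground truth:

```python
from motuskit import SimulationConfig, simulate_and_run
out = simulate_and_run(SimulationConfig(seed=42))
print(out["summary"])
```

yields (seed 42):

```
n_birds 142, n_detected 142, night_exact_frac 1.0,
median_abs_minutes_err ~7e-12, n_crossings 31, max_abs_speed_rel_err 0.030,
n_pace_sections 34
supported models (speed): year + tailwind; age + year + tailwind
```

Every simulated departure night is recovered exactly, timing to numerical
precision, and crossing speeds within 3%. The averaged speed coefficients
show the designed structure — tailwind strong, age weak:

```
coefficient   estimate      se        lo95     hi95
year            1.79      0.74       0.34     3.23
tailwind        3.50      0.21       3.08     3.92
age             0.64      1.14      -1.60     2.88
```

The tailwind coefficient sits at 3.5–3.6 km/h per m/s because the
generator builds groundspeed as airspeed + 3.6 × tailwind; its CI excludes
zero while age's includes zero — age influences speed only through
departure-night wind selectivity, and the model selection detects exactly
that.

The same stages run from the shell:

```bash
motuskit simulate --out study/ --seed 42
motuskit run --detections study/detections.csv --deployments study/deployments.csv \
             --towers study/towers.csv --wind study/wind.csv --out study/out
motuskit recover --seed 42          # simulate + run + truth comparison
```

`run` writes `departures.csv`, `crossings.csv`, `pace_sections.csv`,
`model_ranks.csv`, `averaged_coefficients.csv` and a `run_log.csv` with
one structured line per excluded record.

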