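# Methods

This note records the models, conventions and design choices behind
`firestops`, in the order the pipeline runs them.

## Spatial substrate and conventions

All grids live in a projected equal-area planar frame (meters, x east,
y north), row-major with a top-left origin; the synthetic world uses a local
frame labelled `local-planar`, while real data should arrive in an
equal-area projection of the user's choice. Layers keep their native
resolution (30 m tree cover beside 345 m land cover) and are looked up
nearest-cell, never resampled; a point exactly on a cell edge belongs to the
cell that starts there (floor convention), which makes every lookup
deterministic. Pixel centers, not corners, carry coordinates.

## Fire stops

Fire events are spatiotemporal connected components on the day-of-burn
grid: burned pixels join iff Queen-adjacent (8-neighbour) and their burn
dates differ by at most `max_gap_days` (default 14). Fires smaller than 6
contiguous 300 m pixels (0.54 km²) are dropped — their perimeters are
dominated by detection noise. Stops are the unburned pixels Queen-adjacent
to a fire, emitted per fire (a pixel wedged between two fires yields two
stops). Each stop's `last_burn_date` is the date of the nearest burned
pixel; among equidistant candidates the *latest* date wins, because the stop
records where spread last halted. The outward direction is the unit vector
from the centroid of the fire's pixels in the 3×3 window to the stop center;
a symmetric surround falls back to the single nearest burned pixel, and a
still-degenerate stop is excluded from the wind and ellipse analyses (it
keeps its weather fuel-moisture tests, which need no direction).

## Fire-weather attribution

The 10-day window holds 120 hourly values up to and including hour 23 of the
burn day and 120 after; day boundaries follow the weather cube's time
coordinate (UTC in practice). VPD uses the Magnus/Tetens saturation curve
over water with WMO constants (0.6112 kPa, 17.62, 243.12 °C); any
saturation formula agreeing to < 1 % would do, and supersaturated inputs
within 0.5 °C are clamped (reanalysis round-off) while larger violations
propagate as missing. WFSI is the wind vector's scalar projection on the
outward direction — the minimal index that is positive when wind pushes into
unburned fuel, negative when opposing, and scales with wind speed.

The t-test is Welch's by default (`equal_var=False`); the pooled Student
form is available but the unequal-variance form is the safer default when
one half contains a weather regime change. Hourly samples are serially
correlated, which inflates the nominal significance of the t stage; the
pipeline deliberately tests hourly values (the calibration experiments
quantify the resulting false-flag rate, and the second-stage timing gate is
what keeps it low). A daily-mean mode is not provided because the breakpoint
stage needs the hourly resolution anyway.

Breakpoints come from exact dynamic programming over piecewise-constant
means: for each candidate number of breaks m ≤ 5, the partition minimising
total within-segment RSS subject to segments ≥ ⌈0.15·n⌉ (36 h at n = 240) is
found globally — unlike greedy binary segmentation, the m-break optimum need
not contain the (m−1)-break one — and m is selected by BIC,
n·log(RSS/n) + (2m+1)·log n (each segment costs a mean plus a break date).
Note the min-segment constraint means RSS is *not* necessarily monotone in
m; BIC's strictly increasing penalty guarantees it never selects an m whose
RSS exceeds the m−1 optimum. Missing values up to 10 % are linearly
interpolated. The break-date confidence interval is the conservative
±⌈min-segment/2⌉ hours (±18 h at defaults) rather than the asymptotic
break-date distribution; it is wider than the asymptotic interval in the
clean-break regime, which only makes the timing gate harder to pass. A flag
requires the *entire* interval inside [start of day −1, end of day +2]
around the burn date.

## Landscape attribution

The sampling ellipse (900 m × 450 m at 300 m spacing) is centred midway
between the stop and its nearest burned pixel and oriented along the outward
direction. The 100 m sample grid is aligned with the ellipse axes and
anchored at the center with integer-step offsets along the major axis and
half-step offsets along the minor axis; points strictly inside the ellipse
are kept. The half-step shift keeps rows off the center line, giving 32
points for the default geometry — a sampled-area-to-ellipse-area ratio of
1.006, against 37 points (ratio 1.16, oversampling the area budget) for a
fully center-anchored grid. On a straight perimeter 14/32 points fall on
the burned side.

Burn history arrives as years-since-last-fire and is converted to a
fuel-reduction fraction by a linear recovery over R = 25 years,
clip(1 − years/R, 0, 1); R is configurable because the true recovery rate is
ecosystem-specific (boreal larch forests recover flammable surface fuels
within one to a few decades, and recent scars < 6 years old are the
strongest stops). The sentinel 9999 (no recorded fire) maps to zero
reduction.

χ² tests drop classes absent from both groups; 2×2 tables use the Yates
continuity correction (the common tooling default, configurable) and are
skipped when any expected count is below 1. Direction gates: road/water
presence must be higher outside; for land cover the class with the largest
share gain outside must differ from the modal class inside. The downslope
slope is arctan(Δmean elevation / Δmean along-axis position) of the two
groups, signed outward; flagging needs significance *and* slope ≤ −5°, the
experimental threshold below which downslope substantially limits spread.

## Decision tree and accounting

Fuel moisture, WFSI and downslope are physically independent and always
pass through. The five fuel-related landscape drivers describe the same
underlying fact (no fuel outside) and are resolved by fixed priority:
water > road > burn_history > fuel_load > land_cover — hard barriers first,
then the driver that causally precedes the others (a past fire changes both
fuel load and land cover), then the directional fuel-load signal over the
merely-different land-cover signal. The hierarchy is a configurable ordered
list. At most 4 drivers survive per stop. Contributions are 1/|flags| per
surviving driver; unexplained stops carry `unknown` = 1, so totals are
conserved exactly. A stop excluded from one analysis (incomplete weather
window, undefined direction, one-sided ellipse) can still be flagged by the
other; `explained` reflects surviving flags only, and summaries report both
the raw flag percentages and the normalized shares to prevent misreading.

## The synthetic world

The generator emulates the semantics of the real archives, not their
content: fires flood-fill one Queen ring per day from deterministic ignition
points until the spread schedule ends (top-down causes: the weather series
steps at hour 0 of the day after the last spread day) or a planted barrier
blocks them (bottom-up causes: a half-plane landscape edge whose first
blocked pixel column becomes the stop line). Weather is an hourly sinusoidal
diurnal cycle plus white noise plus the planted step; soil moisture is a
bounded baseline-plus-white-noise series rather than a random walk, because
the null-calibration experiment requires a stationary null — a random walk
would make the measured false-flag rate reflect the generator, not the
tests. Noise defaults (VPD 0.15 kPa, soil moisture 0.01 m³/m³, wind 0.5 m/s
per component, tree cover 4 %, biomass 4 Mg/ha, elevation 0.5 m) put the
default planted effects at ≥ 3 noise SDs: VPD step 1.0 kPa, soil-moisture
step 0.08, wind reversal at 5 m/s, tree cover 45→26 % with biomass
48→23 Mg/ha (the contrast typical of real fuel-load stops), a 3-year-old
burn scar, a −10° ramp. The planted road corridor is 300 m wide (road plus
verges): a bare 30 m line cannot reach p < 0.01 at the 100 m sampling
density, which is a genuine resolution limit of the method, not of the
generator. The downslope ramp starts 450 m before the barrier line so the
whole sampling ellipse lies on the ramp; a ramp starting at the line would
halve the group-mean slope estimate and park a −10° ramp exactly at the −5°
threshold. Ground-truth labels attach to stops within 450 m of a planted
feature (and roughly facing it), and to all final-day stops for synchronous
weather steps; a deliberately mistimed step gets no labels. All randomness
flows from the single config seed through one generator.

What the generator does **not** emulate — and what passing tests therefore
do not demonstrate about real data: satellite detection noise and omission
errors, multi-product burned-area disagreement, spatially varying weather
within a fire, correlated landscape layers (real water implies no trees),
fuel-bed heterogeneity, and physically realistic spread. Weather noise is
drawn per reanalysis cell, so stops sharing a cell share a series: a single
unlucky realization can flag a whole flank together. This clustering is
faithful to per-cell reanalysis semantics and is visible in the experiments
(e.g. an isolated year with a spurious fuel-moisture share in the trend
demo); it widens the sampling variability of measured rates without biasing
them.

## Experiment sizes

The standing experiments are sized for a single CPU: null calibration pools
1080 stops from three 27 km scenarios with nine fires each; planted recovery
runs one 12 km single-cause scenario per cause kind (249 affected stops
across the suite) plus a stacked-barrier scenario for the hierarchy; the DP
oracle comparison uses 200 series of n ≤ 60 against exhaustive enumeration.
Measured at these sizes: every weather driver's null false-flag rate is
≤ 5 % (typically 0, occasionally a correlated-cell cluster), every landscape
driver's ≤ 2 % (fuel_load highest at ~1 %, being two pooled one-sided
tests), suite recovery 99.2 %, and hierarchy suppression leak-free. The
known failure mode is the land-cover edge at corner stops, where the rotated
ellipse straddles 345 m cells and the contingency contrast dilutes below
p < 0.01 (2 of 17 stops in the standard scenario).

## Known limitations

* The WFSI projection matches the index's stated properties (sign semantics,
  wind-speed scaling) but other scalings satisfying the same properties
  exist; the projection is the minimal one.
* The per-fire stop convention means perimeters of nearly touching fires
  each get their own stops; no cross-fire merging is attempted.
* Hourly serial correlation makes the first-stage t-test anticonservative in
  isolation; the two-stage composition is calibrated empirically, not
  analytically.
* No active-suppression driver exists: stops caused by firefighting will be
  attributed to whatever co-occurring driver passes, or left unexplained.
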