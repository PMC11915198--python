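# firestops

**What finally stops a wildfire?** Along the outer perimeter of every burned
area there are *fire stops* — unburned 300 m pixels adjacent to burned ones —
and each marks a place and a time where fire spread halted. `firestops`
attributes each stop to top-down **fire-weather** drivers (a drop in vapor
pressure deficit, a rise in surface soil moisture, a decline in the wind fire
spread index) and/or bottom-up **landscape** drivers (surface water, roads,
recent burn scars, fuel load, land-cover transitions, downslope terrain),
then aggregates the normalized driver contributions over space and time.

The package is aimed at fire ecologists and geospatial analysts working with
burned-area products (day-of-burn rasters with fire-event identifiers),
hourly reanalysis weather, and mixed-resolution landscape layers. Because
those archives are large and external, the package ships a
**synthetic-scenario generator** that emulates all of them with planted,
labelled cessation causes, so the entire pipeline is testable — and its
false-flag and recovery rates measurable — without downloading anything.

## Method

For a stop with last recorded burn date *t₀* (the burn day of the nearest
burned pixel):

**Fire weather (change over time).** Extract 240 hourly values of VPD, WFSI
and soil moisture spanning the 5 days up to and including *t₀* and the 5
days after, from the reanalysis cell containing the stop. VPD uses the
Magnus form, e_s(T) = 0.6112·exp(17.62·T/(243.12+T)) kPa, VPD = e_s(T) −
e_s(T_d); WFSI is the wind vector projected on the stop's outward spread
direction **n̂** (positive = wind pushing into unburned fuel): WFSI = u·n̂ₓ +
v·n̂ᵧ. A driver is flagged only if it passes *two* gates:

1. a Welch two-sample t-test between the two 120-hour halves, p < 0.01,
   with the change in the stopping direction (VPD ↓, soil moisture ↑, WFSI ↓);
2. a structural break — piecewise-constant-mean segmentation by exact
   dynamic programming (minimum segment 15 % of the series, model order by
   BIC) — whose confidence interval lies entirely between 1 day before and
   2 days after *t₀*.

`fuel_moisture` is the composite VPD-decline ∨ soil-moisture-rise (a fuel
rewetting event).

**Landscape (change over space).** An ellipse (major axis 3× the 300 m stop
spacing, minor 1.5×) is oriented along **n̂** and centred midway between the
stop and its nearest burned pixel, so it straddles the perimeter. Layers are
sampled inside it on a 100 m grid at native resolution and the burned vs
unburned groups compared: Welch t-tests for tree cover, aboveground biomass
and burn history (years since fire → fuel-reduction fraction via a linear
25-year recovery); χ² contingency tests for land cover, road and water
presence; and a terrain rule flagging `downslope` only when the decline is
significant *and* the outward slope is ≤ −5°. Every test carries a direction
gate (e.g. water must be *more* frequent outside).

**Decision tree.** `fuel_moisture`, `wfsi` and `downslope` pass through
independently; among the interdependent fuel-related landscape drivers only
the highest-priority significant one survives: water > road > burn_history >
fuel_load > land_cover. A stop carries at most 4 drivers; each flagged
driver gets weight 1/|flags| so stacked shares sum to 100 % (unexplained
stops count as `unknown`). Summaries are emitted both as raw flag
percentages (which may sum past 100) and as normalized shares, on equal-area
grids (e.g. 20/40 km), as annual series, and as OLS trends.

## Worked example

The numbered scripts under `analysis/` form the demonstration pipeline: a
synthetic fire grows for 8 days, is stopped by a river on its eastern flank,
and a region-wide 1.0 kPa VPD drop quenches the rest of the perimeter.

```bash
python analysis/01_simulate_scenario.py
python analysis/02_extract_stops.py
python analysis/03_attribute_drivers.py
```

Step 03 prints:

```
fire stops analysed: 60
explained: 100.0% (p < 0.01, any driver)
...
relative shares (sum to 100, incl. unknown):
  fuel_moisture    71.7%
  wfsi              5.0%
  water            23.3%
  ...
planted-cause check: river stops recovered 100% (17 stops),
fuel-rewetting stops recovered 100% (47 stops)
```

i.e. every stop got an attribution; the 17 stops pressed against the planted
river all carry `water`, the rest carry `fuel_moisture` from the planted VPD
step, and the normalized shares split accordingly. Scripts 04–06 then
measure false-flag rates under a pure-noise null (every weather driver
≤ 5 %, every landscape driver ≤ 2 % of 1080 stops), recovery of all nine
planted cause kinds (99.2 % of 249 affected stops), and spatial/temporal
aggregation with OLS trends on an 11-year synthetic regime shift.

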