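"""Calibration and recovery experiments on the synthetic world.

Two standing experiments quantify the attribution pipeline's error rates
under known truth:

* **null calibration** — scenarios with no planted causes: every raised flag
  is a false positive; rates are measured per driver over ≥ 1000 stops;
* **planted recovery** — one scenario per cause kind with an effect well
  clear of the noise floor (≥ 3 SD): the fraction of truth-labelled stops
  whose final flags contain the planted cause, plus checks that the decision
  tree never lets two fuel-related drivers through and rarely flags a
  fuel-related driver that was not planted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .attribution import FUEL_HIERARCHY, AttributionConfig, attribute_all
from .perimeter import extract_fire_stops
from .synthetic import (
    BARRIER_KINDS,
    WEATHER_KINDS,
    PlantedCause,
    ScenarioConfig,
    generate_scenario,
    null_scenario,
)

__all__ = [
    "WEATHER_FLAGS",
    "LANDSCAPE_FLAGS",
    "TRUTH_TO_DRIVER",
    "null_false_flag_rates",
    "planted_recovery",
    "stacked_barrier_suppression",
]

WEATHER_FLAGS = ("vpd_decline", "sm_increase", "wfsi_decline")
LANDSCAPE_FLAGS = ("water", "road", "burn_history", "fuel_load", "land_cover", "downslope")

#: planted cause kind -> the final driver expected to carry it
TRUTH_TO_DRIVER = {
    "vpd_drop": "fuel_moisture",
    "sm_rise": "fuel_moisture",
    "wfsi_drop": "wfsi",
    "water_edge": "water",
    "road_edge": "road",
    "burn_history_edge": "burn_history",
    "fuel_load_edge": "fuel_load",
    "landcover_edge": "land_cover",
    "downslope_edge": "downslope",
}


def _run(config: ScenarioConfig, attribution: AttributionConfig | None = None):
    scene, cube, stack, truth = generate_scenario(config)
    stops = extract_fire_stops(scene)
    records = attribute_all(stops, scene, cube, stack, attribution)
    return records.merge(truth.stops, on=["fire_id", "row", "col"], suffixes=("", "_truth")), truth


def null_false_flag_rates(
    seed: int,
    n_scenarios: int = 3,
    grid: tuple[int, int] = (90, 90),
    n_fires: int = 9,
    duration_days: int = 5,
) -> dict:
    """False-flag rate per driver under pure noise.

    Runs ``n_scenarios`` independent null scenarios (different noise seeds,
    identical geometry) and pools every stop. Returns the per-driver rates on
    the raw test flags (weather: the two-stage test; landscape: each
    inside-outside test) plus the pooled stop count.
    """
    frames = []
    for k in range(n_scenarios):
        config = ScenarioConfig(
            grid_shape=grid,
            n_fires=n_fires,
            duration_days=duration_days,
            seed=(seed * 1000 + k) % (2**31 - 1),
        )
        scene, cube, stack, _ = null_scenario(config)
        stops = extract_fire_stops(scene)
        frames.append(attribute_all(stops, scene, cube, stack))
    records = pd.concat(frames, ignore_index=True)
    out = {"n_stops": int(len(records))}
    for flag in WEATHER_FLAGS:
        out[flag] = float(records[flag].mean())
    for flag in LANDSCAPE_FLAGS:
        out[flag] = float(records[flag].mean())
    return out


def _recovery_config(kind: str, seed: int) -> ScenarioConfig:
    config = ScenarioConfig(grid_shape=(40, 40), n_fires=1, duration_days=8, seed=seed)
    return config.with_causes(PlantedCause(kind, flank="E", distance_px=6))


def planted_recovery(seed: int, kinds: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Recovery of each planted cause kind in a single-cause scenario.

    Returns one row per kind: the number of truth-labelled (affected) stops,
    the fraction recovered (planted cause present in the stop's final flags),
    the fraction of *all* stops carrying a fuel-related driver that was not
    planted, and the maximum number of fuel-related drivers ever flagged
    together (must be 1).
    """
    if kinds is None:
        kinds = WEATHER_KINDS + BARRIER_KINDS
    rows = []
    for i, kind in enumerate(kinds):
        records, _ = _run(_recovery_config(kind, (seed * 100 + i) % (2**31 - 1)))
        affected = records[records[f"truth_{kind}"]]
        driver = TRUTH_TO_DRIVER[kind]
        planted_fuel = driver if driver in FUEL_HIERARCHY else None
        unplanted_fuel = [d for d in FUEL_HIERARCHY if d != planted_fuel]
        rows.append(
            {
                "kind": kind,
                "n_affected": int(len(affected)),
                "recovered_frac": float(affected[f"final_{driver}"].mean()),
                "unplanted_fuel_frac": float(
                    records[[f"final_{d}" for d in unplanted_fuel]].any(axis=1).mean()
                ),
                "max_fuel_drivers": int(
                    records[[f"final_{d}" for d in FUEL_HIERARCHY]].sum(axis=1).max()
                ),
            }
        )
    return pd.DataFrame(rows)


def stacked_barrier_suppression(seed: int) -> dict:
    """Co-located water + fuel-load + land-cover edges: hierarchy check.

    All three fuel-related causes sit on the same barrier, so all three raw
    tests fire together; the decision tree must let only surface water (the
    hard barrier) through at every affected stop.
    """
    config = ScenarioConfig(grid_shape=(40, 40), n_fires=1, duration_days=8, seed=seed)
    config = config.with_causes(
        PlantedCause("water_edge", flank="E", distance_px=6),
        PlantedCause("fuel_load_edge", flank="E", distance_px=6),
        PlantedCause("landcover_edge", flank="E", distance_px=6),
    )
    records, _ = _run(config)
    affected = records[records["truth_water_edge"]]
    lower = affected[["final_fuel_load", "final_land_cover", "final_road", "final_burn_history"]]
    co_triggered = affected[["fuel_load", "land_cover"]].any(axis=1)
    return {
        "n_affected": int(len(affected)),
        "n_co_triggered_raw": int(co_triggered.sum()),
        "water_recovered_frac": float(affected["final_water"].mean()),
        "lower_priority_leaks": int(lower.to_numpy().sum()),
        "max_fuel_drivers": int(
            records[[f"final_{d}" for d in FUEL_HIERARCHY]].sum(axis=1).max()
        ),
    }
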