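#!/usr/bin/env python
"""Attribute every fire stop to fire-weather and/or landscape drivers.

Runs the two-stage weather tests (t-test + breakpoint timing), the ellipse
landscape tests, and the hierarchical decision tree; compares the outcome
against the planted ground truth; writes the per-stop records and a summary
report under results/.
"""

from pathlib import Path

import pandas as pd

import firestops as fs
from firestops import io as fio

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "scenario"
RESULTS = ROOT / "results"


def main() -> None:
    scene = fio.read_burn_scene(SCRATCH / "scene")
    stack = fio.read_landscape_stack(SCRATCH / "stack")
    cube = fio.read_weather_cube(SCRATCH / "weather.nc")
    stops = fio.read_stops(RESULTS / "fire_stops.csv")
    truth = pd.read_csv(RESULTS / "ground_truth_stops.csv")

    records = fs.attribute_all(stops, scene, cube, stack)
    records.to_csv(RESULTS / "attribution_records.csv", index=False)
    report = fs.run_report(records)
    (RESULTS / "attribution_report.txt").write_text(report)
    print(report)

    m = records.merge(truth, on=["fire_id", "row", "col"])
    water = m[m["truth_water_edge"]]
    rewet = m[m["truth_vpd_drop"]]
    print(f"planted-cause check: river stops recovered "
          f"{water['final_water'].mean() * 100:.0f}% ({len(water)} stops), "
          f"fuel-rewetting stops recovered "
          f"{rewet['final_fuel_moisture'].mean() * 100:.0f}% ({len(rewet)} stops)")
    print(f"records -> {RESULTS / 'attribution_records.csv'}")


if __name__ == "__main__":
    main()
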