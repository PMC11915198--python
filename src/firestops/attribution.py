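"""Hierarchical combination of weather and landscape flags per fire stop.

The two fire-weather drivers (fuel moisture, WFSI) and downslope are
independent and always pass through. The remaining landscape drivers all
describe the same physical fact — no fuel on the outside — so only the
highest-priority significant one survives, ordered from hard barriers to
subtle transitions: surface water > roads > burn history > fuel load > land
cover. A stop can therefore carry at most four drivers. For stacked
(relative) accounting each flagged driver receives weight 1/|flags|;
unexplained stops contribute weight 1 to an "unknown" category.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from .perimeter import BurnScene
from .landscape import LandscapeStack, attribute_landscape
from .fire_weather import extract_window, attribute_weather

__all__ = [
    "AttributionConfig",
    "FUEL_HIERARCHY",
    "INDEPENDENT_DRIVERS",
    "ALL_DRIVERS",
    "apply_decision_tree",
    "normalize_contributions",
    "attribute_all",
]

#: fuel-related landscape drivers, highest priority first
FUEL_HIERARCHY = ("water", "road", "burn_history", "fuel_load", "land_cover")
#: drivers that always pass through the tree independently
INDEPENDENT_DRIVERS = ("fuel_moisture", "wfsi", "downslope")
ALL_DRIVERS = INDEPENDENT_DRIVERS + FUEL_HIERARCHY


@dataclass
class AttributionConfig:
    """Shared knobs of the attribution pipeline, with the study defaults."""

    alpha: float = 0.01
    timing_window_days: tuple[int, int] = (-1, 2)
    min_segment_frac: float = 0.15
    max_breaks: int = 5
    equal_var: bool = False
    grid_step: float = 100.0
    major_mult: float = 3.0
    minor_mult: float = 1.5
    slope_threshold_deg: float = -5.0
    fuel_hierarchy: tuple[str, ...] = FUEL_HIERARCHY

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timing_window_days"] = list(self.timing_window_days)
        d["fuel_hierarchy"] = list(self.fuel_hierarchy)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AttributionConfig":
        d = dict(d)
        if "timing_window_days" in d:
            d["timing_window_days"] = tuple(d["timing_window_days"])
        if "fuel_hierarchy" in d:
            d["fuel_hierarchy"] = tuple(d["fuel_hierarchy"])
        return cls(**d)


def apply_decision_tree(
    raw_flags: dict, hierarchy: tuple[str, ...] = FUEL_HIERARCHY
) -> set[str]:
    """Final driver set of one stop from its raw test flags.

    ``raw_flags`` maps driver name → bool for the eight drivers. Independent
    drivers (fuel moisture, WFSI, downslope) survive as-is; of the
    fuel-related landscape drivers only the first significant one in
    ``hierarchy`` survives. Idempotent: applying the tree to its own output
    changes nothing.
    """
    final = {d for d in INDEPENDENT_DRIVERS if raw_flags.get(d, False)}
    for d in hierarchy:
        if raw_flags.get(d, False):
            final.add(d)
            break
    return final


def normalize_contributions(flags: set[str]) -> dict[str, float]:
    """Per-driver weights of one stop: 1/|flags| each, or unknown = 1."""
    if not flags:
        return {"unknown": 1.0}
    w = 1.0 / len(flags)
    return {d: w for d in sorted(flags)}


def attribute_all(
    stops: pd.DataFrame,
    scene: BurnScene,
    cube: xr.Dataset,
    stack: LandscapeStack,
    config: AttributionConfig | None = None,
) -> pd.DataFrame:
    """Run both analyses and the decision tree over every stop.

    Returns one record per stop: the stop identity columns, raw per-test
    statistics and flags, the surviving ``final_<driver>`` flags, the
    ``contrib_<driver>`` weights (including ``contrib_unknown``), the number
    of flags, and ``explained``. Stops excluded from one analysis (incomplete
    weather window, undefined direction, one-sided ellipse) can still be
    flagged by the other; the exclusion reason is recorded.

    Deterministic: identical inputs and config give identical tables.
    """
    if config is None:
        config = AttributionConfig()
    stack.validate_frame(scene)
    if cube.attrs.get("crs") != scene.day_of_burn.crs:
        raise ValueError(
            f"weather cube CRS {cube.attrs.get('crs')!r} does not match "
            f"burn scene CRS {scene.day_of_burn.crs!r}"
        )

    records = []
    for _, stop in stops.iterrows():
        rec: dict = {
            k: stop[k]
            for k in ("fire_id", "row", "col", "x", "y", "last_burn_date", "year")
        }
        rec["direction_defined"] = bool(stop["direction_defined"])

        window = extract_window(cube, stop)
        if window is None:
            rec["weather_excluded"] = "window-incomplete"
            raw_weather = {d: False for d in ("vpd_decline", "sm_increase",
                                              "wfsi_decline", "fuel_moisture")}
        else:
            raw_weather = attribute_weather(
                window,
                alpha=config.alpha,
                timing_window_days=config.timing_window_days,
                min_segment_frac=config.min_segment_frac,
                max_breaks=config.max_breaks,
                equal_var=config.equal_var,
            )
            rec["weather_excluded"] = ""
        rec.update(raw_weather)

        raw_landscape = attribute_landscape(
            stop,
            scene,
            stack,
            alpha=config.alpha,
            grid_step=config.grid_step,
            major_mult=config.major_mult,
            minor_mult=config.minor_mult,
            slope_threshold_deg=config.slope_threshold_deg,
        )
        rec.update(raw_landscape)

        raw_flags = {
            "fuel_moisture": bool(rec.get("fuel_moisture", False)),
            "wfsi": bool(rec.get("wfsi_decline", False)),
            "downslope": bool(rec.get("downslope", False)),
            **{d: bool(rec.get(d, False)) for d in FUEL_HIERARCHY},
        }
        final = apply_decision_tree(raw_flags, config.fuel_hierarchy)
        for d in ALL_DRIVERS:
            rec[f"final_{d}"] = d in final
        contrib = normalize_contributions(final)
        for d in ALL_DRIVERS + ("unknown",):
            rec[f"contrib_{d}"] = contrib.get(d, 0.0)
        rec["n_flags"] = len(final)
        rec["explained"] = len(final) > 0
        records.append(rec)

    return pd.DataFrame.from_records(records)
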