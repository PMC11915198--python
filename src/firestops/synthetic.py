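"""Synthetic burn scenes, weather cubes and landscape stacks with planted,
labelled cessation causes.

The generator stands in for the satellite archives: it emulates their
semantics (a 300 m day-of-burn grid, an hourly coarse weather cube, mixed-
resolution landscape layers) on a local planar equal-area frame, and plants
causes whose ground truth is known exactly, so every downstream stage can be
scored against what was actually put in.

Fires grow by flood fill — one Queen ring per day from an ignition pixel —
until they either run out of schedule (top-down causes: the weather series
steps at the end of the last spread day) or meet a planted barrier (bottom-up
causes: a landscape edge placed just outside the final perimeter segment).
This is deliberately not a fire-behaviour model; it produces realistic
perimeter geometry and burn-date gradients, which is all the attribution
stages consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .grids import RasterGrid
from .perimeter import QUEEN, BurnScene, extract_fire_stops
from .fire_weather import dewpoint_for_vpd, make_weather_cube
from .landscape import LandscapeStack

__all__ = [
    "CAUSE_KINDS",
    "WEATHER_KINDS",
    "BARRIER_KINDS",
    "PlantedCause",
    "NoiseConfig",
    "ScenarioConfig",
    "GroundTruth",
    "generate_scenario",
    "null_scenario",
]

WEATHER_KINDS = ("vpd_drop", "sm_rise", "wfsi_drop")
BARRIER_KINDS = (
    "water_edge",
    "road_edge",
    "burn_history_edge",
    "fuel_load_edge",
    "landcover_edge",
    "downslope_edge",
)
CAUSE_KINDS = WEATHER_KINDS + BARRIER_KINDS + ("none",)

#: flank → outward unit vector (x east, y north)
FLANKS = {"E": (1.0, 0.0), "W": (-1.0, 0.0), "N": (0.0, 1.0), "S": (0.0, -1.0)}

#: default planted magnitudes, in each cause's natural units
DEFAULT_MAGNITUDE = {
    "vpd_drop": 1.0,          # kPa step down
    "sm_rise": 0.08,          # m3/m3 step up
    "wfsi_drop": 5.0,         # wind speed (m/s); reversal => step of 2x on aligned stops
    "water_edge": 1.0,        # presence
    "road_edge": 1.0,         # presence
    "burn_history_edge": 3.0, # years since the prior fire, outside
    "fuel_load_edge": 1.0,    # scale of the tree-cover / biomass drop
    "landcover_edge": 2.0,    # class code outside
    "downslope_edge": 10.0,   # ramp steepness, degrees
    "none": 0.0,
}


@dataclass(frozen=True)
class PlantedCause:
    """One planted cessation cause.

    ``flank`` orients geometric causes (the side of the fire the barrier sits
    on, or the pre-break wind heading for ``wfsi_drop``). ``distance_px`` is
    the barrier distance from the ignition in 300 m pixels. ``offset_days``
    shifts a weather step away from the cessation date (0 = synchronous; a
    positive value plants a deliberately mistimed break that the timing gate
    must reject, so no truth label is attached).
    """

    kind: str
    magnitude: float | None = None
    flank: str = "E"
    distance_px: int = 6
    offset_days: int = 0
    fire_index: int | None = None  # None = applies to every fire

    def __post_init__(self):
        if self.kind not in CAUSE_KINDS:
            raise ValueError(f"unknown cause kind {self.kind!r}")
        if self.flank not in FLANKS:
            raise ValueError(f"unknown flank {self.flank!r}")
        mag = self.magnitude if self.magnitude is not None else DEFAULT_MAGNITUDE[self.kind]
        if not np.isfinite(mag):
            raise ValueError("cause magnitude must be finite")
        object.__setattr__(self, "magnitude", float(mag))


@dataclass(frozen=True)
class NoiseConfig:
    """Per-layer noise standard deviations (the study's 'weather' of the
    synthetic world). Zero everywhere gives the exactly reproducible null."""

    vpd: float = 0.15                 # kPa, hourly white noise
    sm: float = 0.01                  # m3/m3
    wind: float = 0.5                 # m/s per component
    tree_cover: float = 4.0           # percent points
    agb: float = 4.0                  # Mg/ha
    elevation: float = 0.5            # m
    burn_history_years: float = 0.5   # years

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic study scenario."""

    grid_shape: tuple[int, int] = (60, 60)
    pixel_size: float = 300.0
    n_fires: int = 1
    burn_start_doy: int = 180
    duration_days: int = 10            # spread schedule absent any barrier
    planted_causes: tuple[PlantedCause, ...] = ()
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    weather_cell_size: float = 3000.0  # ~coarse reanalysis cell in the local frame
    seed: int = 0

    # baseline landscape (homogeneous unless a cause plants an edge)
    tree_cover_mean: float = 45.0      # percent (burned-side level)
    agb_mean: float = 48.0             # Mg/ha
    elevation_mean: float = 200.0      # m
    base_land_cover: int = 1
    no_fire_years: float = 9999.0      # burn-history sentinel: no recorded fire

    def __post_init__(self):
        if min(self.grid_shape) <= 0 or self.pixel_size <= 0:
            raise ValueError("grid_shape and pixel_size must be positive")
        if self.n_fires < 1 or self.duration_days < 1:
            raise ValueError("need at least one fire and one spread day")
        object.__setattr__(self, "planted_causes", tuple(self.planted_causes))

    def with_causes(self, *causes: PlantedCause) -> "ScenarioConfig":
        return replace(self, planted_causes=tuple(causes))


@dataclass
class GroundTruth:
    """What was actually planted, resolved to the stop level.

    ``stops`` has one row per fire stop with boolean ``truth_<kind>`` columns
    and a ``truth`` string (comma-joined kinds, possibly empty). ``causes``
    records each planted cause with its resolved geometry/timing.
    """

    stops: pd.DataFrame
    causes: pd.DataFrame

    def truth_set(self, fire_id: int, row: int, col: int) -> set[str]:
        m = self.stops[
            (self.stops["fire_id"] == fire_id)
            & (self.stops["row"] == row)
            & (self.stops["col"] == col)
        ]
        if m.empty:
            raise KeyError(f"no stop ({fire_id}, {row}, {col}) in the truth table")
        t = m.iloc[0]["truth"]
        return set(t.split(",")) if t else set()


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ignition_points(config: ScenarioConfig) -> list[tuple[int, int]]:
    """Deterministic ignition pixels, spread over the grid on a k×k lattice."""
    nr, nc = config.grid_shape
    k = int(np.ceil(np.sqrt(config.n_fires)))
    sr, sc = nr // k, nc // k
    if sr < 3 or sc < 3:
        raise ValueError(f"grid {config.grid_shape} too small for {config.n_fires} fires")
    pts = []
    for i in range(config.n_fires):
        r = (i // k) * sr + sr // 2
        c = (i % k) * sc + sc // 2
        pts.append((r, c))
    return pts


def _along_flank(coord_x, coord_y, ignition_xy, flank: str):
    """Signed coordinate (m) along the flank direction, 0 at the ignition center."""
    fx, fy = FLANKS[flank]
    return (np.asarray(coord_x) - ignition_xy[0]) * fx + (np.asarray(coord_y) - ignition_xy[1]) * fy


def _barrier_mask(config: ScenarioConfig, grid: RasterGrid, cause: PlantedCause,
                  ignition_xy: tuple[float, float]) -> np.ndarray:
    """Burn-grid cells blocked by this cause's barrier (half-plane beyond it)."""
    nr, nc = grid.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cx, cy = grid.cell_center(rows, cols)
    s = _along_flank(cx, cy, ignition_xy, cause.flank)
    return s >= cause.distance_px * config.pixel_size - 1e-6


def _feature_line(config: ScenarioConfig, cause: PlantedCause) -> float:
    """Along-flank coordinate (m) of the barrier edge (last open / first
    blocked cell boundary), relative to the ignition center."""
    return (cause.distance_px - 0.5) * config.pixel_size


# ---------------------------------------------------------------------------
# fire growth
# ---------------------------------------------------------------------------

def _grow_fire(
    shape: tuple[int, int],
    ignition: tuple[int, int],
    start_doy: int,
    duration: int,
    blocked: np.ndarray,
) -> np.ndarray:
    """Day-of-burn grid of one fire: one Queen ring per day, barrier-aware."""
    dob = np.zeros(shape, dtype=int)
    if blocked[ignition]:
        raise ValueError(
            f"infeasible geometry: planted barrier covers the fire seed at {ignition}"
        )
    dob[ignition] = start_doy
    burned = dob > 0
    for day in range(1, duration):
        ring = ndimage.binary_dilation(burned, structure=QUEEN) & ~burned & ~blocked
        if not ring.any():
            break
        dob[ring] = start_doy + day
        burned |= ring
    return dob


# ---------------------------------------------------------------------------
# layer realization
# ---------------------------------------------------------------------------

def _coords_1d(n: int, step: float, offset: float = 0.0):
    return offset + (np.arange(n) + 0.5) * step


def _fine_grid(config: ScenarioConfig, res: float, rng, base: float, noise_sd: float,
               dtype=float) -> RasterGrid:
    nr = int(np.ceil(config.grid_shape[0] * config.pixel_size / res))
    nc = int(np.ceil(config.grid_shape[1] * config.pixel_size / res))
    data = np.full((nr, nc), base, dtype=float)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return RasterGrid(data.astype(dtype), pixel_size=res, origin=(0.0, 0.0))


def _paint_beyond(layer: RasterGrid, ignition_xy, flank: str, line_m: float,
                  value, band_m: float | None = None) -> None:
    """Set layer cells beyond the feature line (optionally within a band) to value."""
    nr, nc = layer.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cx, cy = layer.cell_center(rows, cols)
    s = _along_flank(cx, cy, ignition_xy, flank)
    sel = s >= line_m
    if band_m is not None:
        sel &= s < line_m + band_m
    layer.data[sel] = value


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_scenario(config: ScenarioConfig):
    """Realise one scenario.

    Returns ``(scene, cube, stack, truth)``: the labelled burn scene, the
    hourly weather cube, the landscape stack, and the stop-level ground
    truth. Identical configs (including the seed) give identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.grid_shape
    ps = config.pixel_size
    burn_grid_proto = RasterGrid(np.zeros((nr, nc), dtype=int), pixel_size=ps, origin=(0.0, 0.0))

    causes = [
        c if c.magnitude is not None else replace(c, magnitude=DEFAULT_MAGNITUDE[c.kind])
        for c in config.planted_causes
        if c.kind != "none"
    ]
    weather_causes = [c for c in causes if c.kind in WEATHER_KINDS]
    barrier_causes = [c for c in causes if c.kind in BARRIER_KINDS]

    # --- fires -------------------------------------------------------------
    ignitions = _ignition_points(config)
    ignition_xy = [burn_grid_proto.cell_center(r, c) for r, c in ignitions]
    dob = np.zeros((nr, nc), dtype=int)
    fid = np.zeros((nr, nc), dtype=int)
    for i, (ign, ixy) in enumerate(zip(ignitions, ignition_xy)):
        blocked = np.zeros((nr, nc), dtype=bool)
        for cause in barrier_causes:
            if cause.fire_index is None or cause.fire_index == i:
                blocked |= _barrier_mask(config, burn_grid_proto, cause, ixy)
        fire_dob = _grow_fire((nr, nc), ign, config.burn_start_doy, config.duration_days, blocked)
        overlap = (fire_dob > 0) & (fid > 0)
        if overlap.any():
            raise ValueError(
                "synthetic fires overlap; enlarge the grid or shorten duration_days"
            )
        fid[fire_dob > 0] = i + 1
        dob = np.where(fire_dob > 0, fire_dob, dob)
    scene = BurnScene(
        day_of_burn=burn_grid_proto.like(dob),
        fire_id=burn_grid_proto.like(fid),
        year=0,
    )
    last_day = int(dob.max()) if (dob > 0).any() else config.burn_start_doy
    cessation_doy = config.burn_start_doy + config.duration_days - 1

    # --- landscape stack ---------------------------------------------------
    noise = config.noise
    tree = _fine_grid(config, 30.0, rng, config.tree_cover_mean, noise.tree_cover)
    agb = _fine_grid(config, 100.0, rng, config.agb_mean, noise.agb)
    land = _fine_grid(config, 345.0, rng, config.base_land_cover, 0.0, dtype=int)
    hist = _fine_grid(config, 300.0, rng, config.no_fire_years, 0.0)
    elev = _fine_grid(config, 30.0, rng, config.elevation_mean, noise.elevation)
    road = _fine_grid(config, 30.0, rng, 0.0, 0.0, dtype=int)
    water = _fine_grid(config, 30.0, rng, 0.0, 0.0, dtype=int)

    cause_rows = []
    for cause in barrier_causes:
        targets = range(config.n_fires) if cause.fire_index is None else [cause.fire_index]
        for i in targets:
            ixy = ignition_xy[i]
            line = _feature_line(config, cause)
            if cause.kind == "water_edge":
                _paint_beyond(water, ixy, cause.flank, line, 1, band_m=3 * ps)
            elif cause.kind == "road_edge":
                _paint_beyond(road, ixy, cause.flank, line, 1, band_m=ps)
            elif cause.kind == "burn_history_edge":
                years = cause.magnitude
                if noise.burn_history_years > 0:
                    # noisy recent-burn band: redraw cells inside the band
                    nr_h, nc_h = hist.shape
                    rows, cols = np.meshgrid(np.arange(nr_h), np.arange(nc_h), indexing="ij")
                    cx, cy = hist.cell_center(rows, cols)
                    s = _along_flank(cx, cy, ixy, cause.flank)
                    sel = (s >= line) & (s < line + 3 * ps)
                    hist.data[sel] = np.maximum(
                        years + rng.normal(0.0, noise.burn_history_years, size=int(sel.sum())),
                        0.0,
                    )
                else:
                    _paint_beyond(hist, ixy, cause.flank, line, years, band_m=3 * ps)
            elif cause.kind == "fuel_load_edge":
                drop_tree = 19.0 * cause.magnitude
                drop_agb = 25.0 * cause.magnitude
                # subtract rather than overwrite so the noise field is kept
                for layer, drop in ((tree, drop_tree), (agb, drop_agb)):
                    nr_l, nc_l = layer.shape
                    rows, cols = np.meshgrid(np.arange(nr_l), np.arange(nc_l), indexing="ij")
                    cx, cy = layer.cell_center(rows, cols)
                    s = _along_flank(cx, cy, ixy, cause.flank)
                    layer.data[s >= line] -= drop
            elif cause.kind == "landcover_edge":
                _paint_beyond(land, ixy, cause.flank, line, int(cause.magnitude))
            elif cause.kind == "downslope_edge":
                theta = np.radians(cause.magnitude)
                ramp_start = line - 1.5 * ps  # whole sampling ellipse sits on the ramp
                nr_l, nc_l = elev.shape
                rows, cols = np.meshgrid(np.arange(nr_l), np.arange(nc_l), indexing="ij")
                cx, cy = elev.cell_center(rows, cols)
                s = _along_flank(cx, cy, ixy, cause.flank)
                drop = np.tan(theta) * np.maximum(s - ramp_start, 0.0)
                elev.data -= drop
            cause_rows.append(
                {"kind": cause.kind, "magnitude": cause.magnitude, "fire_id": i + 1,
                 "flank": cause.flank, "line_m": line, "break_doy": np.nan}
            )
    tree.data = np.clip(tree.data, 0.0, 100.0)
    agb.data = np.clip(agb.data, 0.0, None)
    stack = LandscapeStack(
        tree_cover=tree, agb=agb, land_cover=land, burn_history=hist,
        elevation=elev, road_presence=road, water_presence=water,
    )

    # --- weather cube ------------------------------------------------------
    start_doy_cube = config.burn_start_doy - 6
    end_doy_cube = max(last_day, cessation_doy) + 6
    n_hours = (end_doy_cube - start_doy_cube + 1) * 24
    hours = np.arange(n_hours)
    hod = hours % 24  # hour of day

    ncy = max(1, int(np.ceil(nr * ps / config.weather_cell_size)))
    ncx = max(1, int(np.ceil(nc * ps / config.weather_cell_size)))
    wx = _coords_1d(ncx, config.weather_cell_size)
    wy = (nr * ps) - _coords_1d(ncy, config.weather_cell_size)  # descending, top row first

    diurnal = np.sin(2 * np.pi * (hod - 9.0) / 24.0)  # peaks mid-afternoon
    t2m_base = 15.0 + 8.0 * diurnal
    vpd_base = 1.6 + 0.6 * diurnal
    sm_base = np.full(n_hours, 0.25)
    u_base = np.full(n_hours, 1.5)
    v_base = np.full(n_hours, 0.5)

    def step_hour(cause: PlantedCause) -> int:
        # the step lands at hour 0 of the day after the last spread day
        break_doy = cessation_doy + cause.offset_days
        return (break_doy + 1 - start_doy_cube) * 24

    vpd_t = np.tile(vpd_base, (ncy, ncx, 1)).transpose(2, 0, 1)
    sm_t = np.tile(sm_base, (ncy, ncx, 1)).transpose(2, 0, 1)
    u_t = np.tile(u_base, (ncy, ncx, 1)).transpose(2, 0, 1)
    v_t = np.tile(v_base, (ncy, ncx, 1)).transpose(2, 0, 1)
    for cause in weather_causes:
        h = step_hour(cause)
        break_doy = cessation_doy + cause.offset_days
        if cause.kind == "vpd_drop":
            vpd_t[h:] -= cause.magnitude
        elif cause.kind == "sm_rise":
            sm_t[h:] += cause.magnitude
        elif cause.kind == "wfsi_drop":
            fx, fy = FLANKS[cause.flank]
            u_t[:h], v_t[:h] = cause.magnitude * fx, cause.magnitude * fy
            u_t[h:], v_t[h:] = -cause.magnitude * fx, -cause.magnitude * fy
        cause_rows.append(
            {"kind": cause.kind, "magnitude": cause.magnitude, "fire_id": np.nan,
             "flank": cause.flank, "line_m": np.nan, "break_doy": break_doy}
        )

    shape3 = (n_hours, ncy, ncx)
    if noise.vpd > 0:
        vpd_t = vpd_t + rng.normal(0.0, noise.vpd, size=shape3)
    if noise.sm > 0:
        sm_t = sm_t + rng.normal(0.0, noise.sm, size=shape3)
    if noise.wind > 0:
        u_t = u_t + rng.normal(0.0, noise.wind, size=shape3)
        v_t = v_t + rng.normal(0.0, noise.wind, size=shape3)
    vpd_t = np.clip(vpd_t, 0.05, None)
    sm_t = np.clip(sm_t, 0.0, 1.0)
    t2m = np.tile(t2m_base, (ncy, ncx, 1)).transpose(2, 0, 1)
    d2m = dewpoint_for_vpd(t2m, vpd_t)
    cube = make_weather_cube(
        t2m, d2m, u_t, v_t, sm_t, x=wx, y=wy, start_doy=start_doy_cube,
        crs=burn_grid_proto.crs,
    )

    # --- ground truth ------------------------------------------------------
    stops = extract_fire_stops(scene)
    truth_cols = {f"truth_{k}": np.zeros(len(stops), dtype=bool) for k in CAUSE_KINDS if k != "none"}
    for cause in barrier_causes:
        targets = range(1, config.n_fires + 1) if cause.fire_index is None else [cause.fire_index + 1]
        for fire in targets:
            ixy = ignition_xy[fire - 1]
            line = _feature_line(config, cause)
            s = _along_flank(stops["x"].to_numpy(), stops["y"].to_numpy(), ixy, cause.flank)
            fx, fy = FLANKS[cause.flank]
            align = stops["dir_x"].to_numpy() * fx + stops["dir_y"].to_numpy() * fy
            sel = (
                (stops["fire_id"].to_numpy() == fire)
                & (s - line >= 0)
                & (s - line <= 1.5 * ps)       # within one minor axis of the feature
                & (np.nan_to_num(align) > 0.3)
            )
            truth_cols[f"truth_{cause.kind}"] |= sel
    for cause in weather_causes:
        if cause.offset_days != 0:
            continue  # deliberately mistimed: no stop should be flagged
        sel = stops["last_burn_date"].to_numpy() == cessation_doy
        if cause.kind == "wfsi_drop":
            fx, fy = FLANKS[cause.flank]
            align = stops["dir_x"].to_numpy() * fx + stops["dir_y"].to_numpy() * fy
            sel = sel & (np.nan_to_num(align) > 0.3)
        truth_cols[f"truth_{cause.kind}"] |= sel

    truth_stops = stops[["fire_id", "row", "col", "last_burn_date"]].copy()
    for k, v in truth_cols.items():
        truth_stops[k] = v
    kinds = [k.removeprefix("truth_") for k in truth_cols]
    truth_stops["truth"] = [
        ",".join(sorted(k for k in kinds if truth_cols[f"truth_{k}"][i]))
        for i in range(len(stops))
    ]
    cause_df = pd.DataFrame(
        cause_rows, columns=["kind", "magnitude", "fire_id", "flank", "line_m", "break_doy"]
    )
    truth = GroundTruth(stops=truth_stops, causes=cause_df)

    # barrier adjacency sanity: every planted barrier must be reachable
    for cause in barrier_causes:
        if not truth_stops[f"truth_{cause.kind}"].any():
            raise ValueError(
                f"planted {cause.kind} barrier is not adjacent to any fire stop; "
                "the fire never reached it (increase duration_days or move it closer)"
            )
    return scene, cube, stack, truth


def null_scenario(config: ScenarioConfig):
    """A scenario with no planted causes: fires halt by schedule alone.

    All weather series are stationary (diurnal cycle + noise) and all
    landscape layers homogeneous (+ noise), so any flag raised downstream is
    a false positive; used to measure false-flag rates.
    """
    if any(c.kind != "none" for c in config.planted_causes):
        raise ValueError("null_scenario requires a config with no planted causes")
    return generate_scenario(replace(config, planted_causes=()))
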