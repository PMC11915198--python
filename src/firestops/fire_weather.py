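"""Top-down (fire-weather) attribution at fire stops.

For each stop a 10-day hourly window of three series is examined around the
last recorded burn date: vapor pressure deficit (VPD, kPa), the wind fire
spread index (WFSI, m/s — wind projected onto the outward spread direction),
and surface soil moisture (0–7 cm volumetric). A driver is flagged by a
two-stage test:

1. a two-sample t-test between the 5 days before-and-including the burn date
   and the 5 days after, gated on the direction of change (VPD and WFSI must
   decline, soil moisture must rise), at a conservative p < 0.01;
2. a structural-break search (piecewise-constant-mean segmentation by exact
   dynamic programming, model order by BIC); the flag is raised only if some
   break, including its confidence interval, falls between 1 day before and
   2 days after the burn date.

The timing gate is what separates a genuine cessation-synchronous weather
shift from a merely different week.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "saturation_vapor_pressure",
    "compute_vpd",
    "dewpoint_for_vpd",
    "compute_wfsi",
    "make_weather_cube",
    "extract_window",
    "split_ttest",
    "dp_segment",
    "detect_breakpoints",
    "BreakpointResult",
    "attribute_weather",
    "WINDOW_DAYS_BEFORE",
    "WINDOW_DAYS_AFTER",
    "WINDOW_HOURS",
    "SPLIT_INDEX",
]

# 10-day window: 5 days before-and-including the last burn date, 5 after.
WINDOW_DAYS_BEFORE = 5  # includes the burn day itself
WINDOW_DAYS_AFTER = 5
WINDOW_HOURS = 24 * (WINDOW_DAYS_BEFORE + WINDOW_DAYS_AFTER)
#: first hour index of the "after" half (hour 0 of the day after the burn day)
SPLIT_INDEX = 24 * WINDOW_DAYS_BEFORE

#: weather drivers and the direction of change that can stop a fire
WEATHER_DIRECTIONS = {"vpd": "decline", "sm": "increase", "wfsi": "decline"}


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(t_c):
    """Saturation vapor pressure over water (kPa), Magnus form, WMO constants.

    e_s(T) = 0.6112 * exp(17.62 * T / (243.12 + T)), T in °C.
    """
    t = np.asarray(t_c, dtype=float)
    return 0.6112 * np.exp(17.62 * t / (243.12 + t))


def compute_vpd(t2m_c, d2m_c, clamp_tol: float = 0.5):
    """Vapor pressure deficit (kPa) from 2 m temperature and dewpoint (°C).

    VPD = e_s(T) − e_s(T_d). Supersaturated inputs (T_d > T) are clamped to
    saturation when within ``clamp_tol`` °C (reanalysis round-off); larger
    violations propagate as NaN. Non-finite inputs propagate as NaN.
    """
    t = np.asarray(t2m_c, dtype=float)
    d = np.asarray(d2m_c, dtype=float)
    d_eff = np.where(d > t, np.where(d - t <= clamp_tol, t, np.nan), d)
    vpd = saturation_vapor_pressure(t) - saturation_vapor_pressure(d_eff)
    return np.maximum(vpd, 0.0)


def dewpoint_for_vpd(t2m_c, vpd_kpa):
    """Dewpoint (°C) that realises a target VPD at temperature ``t2m_c``.

    Inverse Magnus on e = e_s(T) − VPD; the target is clipped so the actual
    vapor pressure stays positive. Used by the scenario generator to plant
    VPD steps while keeping temperature untouched.
    """
    t = np.asarray(t2m_c, dtype=float)
    e = saturation_vapor_pressure(t) - np.asarray(vpd_kpa, dtype=float)
    e = np.clip(e, 1e-4, None)
    ln = np.log(e / 0.6112)
    return 243.12 * ln / (17.62 - ln)


def compute_wfsi(u, v, outward_direction):
    """Wind fire spread index (m/s): wind vector projected on the spread axis.

    Positive when the wind pushes air toward the unburned side of the
    perimeter (aligned with the fire front), negative when opposing it, with
    magnitude scaled by wind speed: WFSI = u·n_x + v·n_y for the outward unit
    vector n. Range is [−speed, +speed].
    """
    nx, ny = outward_direction
    norm = float(np.hypot(nx, ny))
    if not np.isfinite(norm) or abs(norm - 1.0) > 1e-6:
        raise ValueError("outward_direction must be a finite unit vector")
    return np.asarray(u, dtype=float) * nx + np.asarray(v, dtype=float) * ny


# ---------------------------------------------------------------------------
# weather cube
# ---------------------------------------------------------------------------

def make_weather_cube(
    t2m, d2m, u10, v10, sm, *, x, y, start_doy: int, crs: str = "local-planar"
) -> xr.Dataset:
    """Assemble hourly weather fields into the pipeline's cube convention.

    Arrays are (time, y, x); the time axis is hourly starting at hour 0 of
    ``start_doy`` (day of year). Coordinates x/y are cell-center coordinates
    in the projected frame. Soil moisture is volumetric (m³/m³) and must lie
    in [0, 1].
    """
    sm = np.asarray(sm, dtype=float)
    if np.nanmin(sm) < 0 or np.nanmax(sm) > 1:
        raise ValueError("soil moisture must lie in [0, 1]")
    n_time = np.asarray(t2m).shape[0]
    hours = np.arange(n_time)
    ds = xr.Dataset(
        {
            "t2m": (("time", "y", "x"), np.asarray(t2m, dtype=float)),
            "d2m": (("time", "y", "x"), np.asarray(d2m, dtype=float)),
            "u10": (("time", "y", "x"), np.asarray(u10, dtype=float)),
            "v10": (("time", "y", "x"), np.asarray(v10, dtype=float)),
            "sm": (("time", "y", "x"), sm),
        },
        coords={"time": hours, "x": np.asarray(x, float), "y": np.asarray(y, float)},
        attrs={"crs": crs, "start_doy": int(start_doy), "time_units": "hours since start_doy 00:00"},
    )
    ds["t2m"].attrs["units"] = "degC"
    ds["d2m"].attrs["units"] = "degC"
    ds["u10"].attrs["units"] = "m s-1"
    ds["v10"].attrs["units"] = "m s-1"
    ds["sm"].attrs["units"] = "m3 m-3"
    return ds


def _nearest_cell_1d(coords: np.ndarray, value: float) -> int:
    """Index of the nearest coordinate; exact midpoints go to the lower index."""
    d = np.abs(coords - value)
    best = d.min()
    return int(np.nonzero(d <= best + 1e-9)[0][0])


def extract_window(cube: xr.Dataset, stop: pd.Series) -> pd.DataFrame | None:
    """The 240-hour VPD/WFSI/soil-moisture window at one stop.

    The series come from the single coarse weather cell containing the stop
    (nearest-cell lookup, lower index on ties — no interpolation, matching
    per-cell reanalysis semantics). Returns a DataFrame with columns
    ``hour, vpd, wfsi, sm`` (hour 0 = first hour of day −4 relative to the
    burn date), or None when the window would run off the cube's time axis;
    such stops are excluded from weather attribution. WFSI is NaN for
    direction-undefined stops.
    """
    start_doy = int(cube.attrs["start_doy"])
    doy = int(stop["last_burn_date"])
    # hours covered: day doy-4 .. day doy+5 inclusive
    h0 = (doy - start_doy - (WINDOW_DAYS_BEFORE - 1)) * 24
    h1 = h0 + WINDOW_HOURS
    if h0 < 0 or h1 > cube.sizes["time"]:
        return None
    ix = _nearest_cell_1d(cube["x"].values, float(stop["x"]))
    iy = _nearest_cell_1d(cube["y"].values, float(stop["y"]))
    sl = cube.isel(time=slice(h0, h1), y=iy, x=ix)
    vpd = compute_vpd(sl["t2m"].values, sl["d2m"].values)
    if bool(stop.get("direction_defined", True)):
        wfsi = compute_wfsi(sl["u10"].values, sl["v10"].values, (stop["dir_x"], stop["dir_y"]))
    else:
        wfsi = np.full(WINDOW_HOURS, np.nan)
    return pd.DataFrame(
        {
            "hour": np.arange(WINDOW_HOURS),
            "vpd": vpd,
            "wfsi": wfsi,
            "sm": sl["sm"].values,
        }
    )


# ---------------------------------------------------------------------------
# two-stage statistics
# ---------------------------------------------------------------------------

def split_ttest(
    values,
    split_index: int = SPLIT_INDEX,
    direction: str = "decline",
    alpha: float = 0.01,
    equal_var: bool = False,
):
    """Two-sample t-test between the halves of a stop window.

    Welch's unequal-variance form by default (configurable to the pooled
    Student form). Passing requires both p < alpha and the mean moving in the
    stated direction ("decline": after < before; "increase": after > before).

    Degenerate inputs: zero variance in both halves with equal means gives
    (t=0, p=1); zero variance with unequal means is an unambiguous change and
    passes with p = 0 (below any machine floor).
    """
    if direction not in ("decline", "increase"):
        raise ValueError(f"unknown direction {direction!r}")
    v = np.asarray(values, dtype=float)
    before, after = v[:split_index], v[split_index:]
    if before.size == 0 or after.size == 0:
        raise ValueError("both halves of the window must be non-empty")
    mb, ma = float(np.mean(before)), float(np.mean(after))
    if np.var(before) == 0.0 and np.var(after) == 0.0:
        if mb == ma:
            return 0.0, 1.0, False
        t = np.inf if mb > ma else -np.inf
        direction_ok = (ma < mb) if direction == "decline" else (ma > mb)
        return float(t), 0.0, bool(direction_ok)
    t, p = stats.ttest_ind(before, after, equal_var=equal_var)
    direction_ok = (ma < mb) if direction == "decline" else (ma > mb)
    return float(t), float(p), bool(p < alpha and direction_ok)


@dataclass
class BreakpointResult:
    """Outcome of the piecewise-constant-mean segmentation of one series."""

    breaks: np.ndarray          # indices where a new segment starts, sorted
    ci_low: np.ndarray          # per break, inclusive
    ci_high: np.ndarray         # per break, inclusive
    segment_means: np.ndarray
    rss: float
    n: int
    rss_by_m: dict[int, float] = field(default_factory=dict)

    @property
    def n_breaks(self) -> int:
        return int(len(self.breaks))


def _segment_cost_matrix(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment sum of squares of x[i:j+1] (else inf)."""
    n = x.size
    s1 = np.concatenate(([0.0], np.cumsum(x)))
    s2 = np.concatenate(([0.0], np.cumsum(x * x)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = s1[j + 1] - s1[i]
        cost = (s2[j + 1] - s2[i]) - tot * tot / length
    cost = np.where(length >= 1, np.maximum(cost, 0.0), np.inf)
    return cost


def dp_segment(x: np.ndarray, min_segment: int, max_breaks: int):
    """Exact optimal partitions for every admissible number of breaks.

    Returns ``(rss_by_m, breaks_by_m)``: for each m from 0 up to
    ``max_breaks`` (bounded by feasibility n // min_segment − 1), the minimal
    total within-segment RSS over all partitions into m+1 segments of length
    ≥ ``min_segment``, and the break indices achieving it.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    h = int(min_segment)
    if h < 1 or n < h:
        raise ValueError("need min_segment >= 1 and a series at least that long")
    cost = _segment_cost_matrix(x)
    m_max = max(0, min(max_breaks, n // h - 1))

    dp = np.full((m_max + 1, n), np.inf)
    arg = np.zeros((m_max + 1, n), dtype=int)
    dp[0, :] = cost[0, :]
    for k in range(1, m_max + 1):
        for j in range((k + 1) * h - 1, n):
            bs = np.arange(k * h, j - h + 2)
            cand = dp[k - 1, bs - 1] + cost[bs, j]
            best = int(np.argmin(cand))
            dp[k, j] = cand[best]
            arg[k, j] = bs[best]

    rss_by_m: dict[int, float] = {}
    breaks_by_m: dict[int, np.ndarray] = {}
    for m in range(m_max + 1):
        if not np.isfinite(dp[m, n - 1]):
            continue
        rss_by_m[m] = float(dp[m, n - 1])
        breaks: list[int] = []
        j = n - 1
        for k in range(m, 0, -1):
            b = int(arg[k, j])
            breaks.append(b)
            j = b - 1
        breaks_by_m[m] = np.array(sorted(breaks), dtype=int)
    return rss_by_m, breaks_by_m


def detect_breakpoints(
    series,
    min_segment_frac: float = 0.15,
    max_breaks: int = 5,
    penalty: str = "bic",
) -> BreakpointResult:
    """Multiple structural breaks in the mean of a series.

    Fits a piecewise-constant-mean model by *exact* dynamic programming: for
    each candidate number of breaks m ≤ ``max_breaks``, the partition
    minimising the total within-segment residual sum of squares subject to a
    minimum segment length of ceil(min_segment_frac · n) is found, and m is
    chosen by BIC,  n·log(RSS/n) + (2m+1)·log(n)  (each extra segment costs a
    mean and a break date). The global search is what distinguishes this from
    greedy binary segmentation: an m-break optimum need not contain the
    (m−1)-break optimum.

    Missing values (≤ 10% of the series) are linearly interpolated first.
    Series shorter than two minimum segments return zero breaks.

    Break convention: a break at index b means the new segment starts at b.
    The reported confidence interval is the documented conservative interval
    b ± ceil(min_segment/2), clipped to [0, n−1].
    """
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    bad = ~np.isfinite(x)
    if bad.any():
        if bad.mean() > 0.10:
            raise ValueError("more than 10% of the series is missing")
        good = np.nonzero(~bad)[0]
        x[bad] = np.interp(np.nonzero(bad)[0], good, x[good])

    h = int(np.ceil(min_segment_frac * n))
    h = max(h, 1)
    if n < 2 * h:
        rss0 = float(np.sum((x - x.mean()) ** 2)) if n else 0.0
        return BreakpointResult(
            breaks=np.array([], dtype=int),
            ci_low=np.array([], dtype=int),
            ci_high=np.array([], dtype=int),
            segment_means=np.array([x.mean()]) if n else np.array([]),
            rss=rss0,
            n=n,
            rss_by_m={0: rss0},
        )

    rss_by_m, breaks_by_m = dp_segment(x, h, max_breaks)
    if penalty != "bic":
        raise ValueError(f"unknown penalty {penalty!r}")
    eps = 1e-12
    bic = {
        m: n * np.log(max(r, eps) / n) + (2 * m + 1) * np.log(n)
        for m, r in rss_by_m.items()
    }
    m_best = min(bic, key=lambda m: (bic[m], m))
    breaks = breaks_by_m[m_best]

    bounds = np.concatenate(([0], breaks, [n]))
    means = np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    half = int(np.ceil(h / 2))
    ci_low = np.clip(breaks - half, 0, n - 1)
    ci_high = np.clip(breaks + half, 0, n - 1)
    return BreakpointResult(
        breaks=breaks,
        ci_low=ci_low,
        ci_high=ci_high,
        segment_means=means,
        rss=rss_by_m[m_best],
        n=n,
        rss_by_m=rss_by_m,
    )


def attribute_weather(
    window: pd.DataFrame,
    alpha: float = 0.01,
    timing_window_days: tuple[int, int] = (-1, 2),
    min_segment_frac: float = 0.15,
    max_breaks: int = 5,
    equal_var: bool = False,
) -> dict:
    """Run the two-stage attribution on one stop window.

    Returns a flat dict with, per driver d ∈ {vpd, sm, wfsi}: ``{d}_t``,
    ``{d}_p``, ``{d}_t_pass``, ``{d}_break_hour`` (NaN if none qualified) and
    the final flags ``vpd_decline``, ``sm_increase``, ``wfsi_decline`` and the
    composite ``fuel_moisture`` (VPD decline and/or soil-moisture rise — a
    fuel rewetting event).

    The timing gate accepts a break only when its whole confidence interval
    lies between the start of day ``timing_window_days[0]`` and the end of day
    ``timing_window_days[1]`` relative to the last burn date (day 0).
    """
    lo_day, hi_day = timing_window_days
    # day 0 occupies hours [96, 120) of the window; window starts at day -4
    lo_hour = (lo_day + WINDOW_DAYS_BEFORE - 1) * 24
    hi_hour = (hi_day + WINDOW_DAYS_BEFORE - 1) * 24 + 23
    out: dict = {}
    for var, direction in WEATHER_DIRECTIONS.items():
        flag_name = f"{var}_{'decline' if direction == 'decline' else 'increase'}"
        vals = window[var].to_numpy()
        if not np.all(np.isfinite(vals)):
            out.update({f"{var}_t": np.nan, f"{var}_p": np.nan, f"{var}_t_pass": False,
                        f"{var}_break_hour": np.nan, flag_name: False})
            continue
        t, p, t_pass = split_ttest(
            vals, SPLIT_INDEX, direction=direction, alpha=alpha, equal_var=equal_var
        )
        break_hour = np.nan
        flagged = False
        if t_pass:
            bp = detect_breakpoints(vals, min_segment_frac, max_breaks)
            for b, lo, hi in zip(bp.breaks, bp.ci_low, bp.ci_high):
                if lo >= lo_hour and hi <= hi_hour:
                    break_hour = int(b)
                    flagged = True
                    break
        out.update({f"{var}_t": t, f"{var}_p": p, f"{var}_t_pass": t_pass,
                    f"{var}_break_hour": break_hour, flag_name: flagged})
    out["fuel_moisture"] = bool(out["vpd_decline"] or out["sm_increase"])
    return out
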