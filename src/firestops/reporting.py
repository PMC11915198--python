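"""Spatial and temporal aggregation of per-stop attribution records.

Two accountings are always distinguished, as both are scientifically useful:

* *flag percentages* — the share of stops at which a driver was flagged;
  drivers can co-occur, so these may sum past 100%;
* *relative shares* — built from the 1/|flags| normalized contributions, so
  shares (including "unknown") sum to exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .attribution import ALL_DRIVERS

__all__ = [
    "GridSummary",
    "TrendResult",
    "grid_aggregate",
    "annual_series",
    "ols_trend",
    "size_class_summary",
    "run_report",
]

CONTRIB_COLS = [f"contrib_{d}" for d in ALL_DRIVERS] + ["contrib_unknown"]
FLAG_COLS = [f"final_{d}" for d in ALL_DRIVERS]


@dataclass
class GridSummary:
    """Per-cell statistics on an equal-area grid."""

    table: pd.DataFrame      # index (cell_row, cell_col); per-driver columns
    cell_size: float
    statistic: str


@dataclass
class TrendResult:
    """OLS trend of an annual driver-share series."""

    slope: float             # percent points per year
    intercept: float
    p_value: float
    r_squared: float
    n_years: int


def _cells(records: pd.DataFrame, cell_size: float) -> pd.DataFrame:
    out = records.copy()
    out["cell_col"] = np.floor(out["x"] / cell_size).astype(int)
    out["cell_row"] = np.floor(-out["y"] / cell_size).astype(int)
    return out


def grid_aggregate(
    records: pd.DataFrame, cell_size: float = 20_000.0, statistic: str = "flag_pct"
) -> GridSummary:
    """Aggregate stop records onto an equal-area grid.

    statistics:

    * ``flag_pct`` — per driver, percent of the cell's stops flagged with it
      (raw flags; may sum past 100 across drivers);
    * ``relative_share`` — per driver (+ unknown), percent of the cell's
      summed normalized contributions; sums to 100 per cell;
    * ``dominant_landscape`` — the landscape driver (water, road, burn
      history, fuel load, land cover, downslope) with the largest summed
      contribution in the cell, NaN where none is flagged.

    Cells with no stops simply do not appear in the table.
    """
    recs = _cells(records, cell_size)
    groups = recs.groupby(["cell_row", "cell_col"])
    if statistic == "flag_pct":
        table = groups[FLAG_COLS].mean() * 100.0
        table.columns = [c.removeprefix("final_") for c in table.columns]
        table["n_stops"] = groups.size()
    elif statistic == "relative_share":
        sums = groups[CONTRIB_COLS].sum()
        table = sums.div(sums.sum(axis=1), axis=0) * 100.0
        table.columns = [c.removeprefix("contrib_") for c in table.columns]
        table["n_stops"] = groups.size()
    elif statistic == "dominant_landscape":
        landscape = ["downslope", "water", "road", "burn_history", "fuel_load", "land_cover"]
        sums = groups[[f"contrib_{d}" for d in landscape]].sum()
        sums.columns = landscape
        dom = sums.idxmax(axis=1).where(sums.max(axis=1) > 0)
        table = dom.to_frame("dominant_landscape")
        table["n_stops"] = groups.size()
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return GridSummary(table=table, cell_size=cell_size, statistic=statistic)


def annual_series(
    records: pd.DataFrame, region_mask: pd.Series | None = None, kind: str = "relative_share"
) -> pd.DataFrame:
    """Per-year per-driver percentages (rows = years, columns = drivers).

    ``kind`` is ``relative_share`` (normalized contributions, rows sum to
    100) or ``flag_pct`` (raw flag rates). ``region_mask`` restricts to a
    boolean subset of records (e.g. a sub-region of interest).
    """
    recs = records if region_mask is None else records[np.asarray(region_mask, bool)]
    groups = recs.groupby("year")
    if kind == "relative_share":
        sums = groups[CONTRIB_COLS].sum()
        out = sums.div(sums.sum(axis=1), axis=0) * 100.0
        out.columns = [c.removeprefix("contrib_") for c in out.columns]
    elif kind == "flag_pct":
        out = groups[FLAG_COLS].mean() * 100.0
        out.columns = [c.removeprefix("final_") for c in out.columns]
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return out


def ols_trend(series: pd.Series) -> TrendResult:
    """Ordinary-least-squares trend of an annual percentage series.

    The index is the year. A constant series has slope 0 and R² reported as
    0. Requires at least 3 years.
    """
    y = np.asarray(series.values, dtype=float)
    t = np.asarray(series.index.values, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 years for a trend")
    model = sm.OLS(y, sm.add_constant(t)).fit()
    if np.allclose(y, y[0]):
        return TrendResult(0.0, float(y[0]), 1.0, 0.0, y.size)
    return TrendResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n_years=int(y.size),
    )


def size_class_summary(
    records: pd.DataFrame,
    fire_sizes: pd.Series,
    class_edges_km2: np.ndarray,
    pixel_area_km2: float = 0.09,
) -> pd.DataFrame:
    """Driver relative shares per (logarithmic) fire-size class.

    ``fire_sizes`` maps fire_id → pixel count; ``class_edges_km2`` are the
    bin edges in km². Returns one row per non-empty class with the per-driver
    share (%) and the number of stops.
    """
    area = fire_sizes.reindex(records["fire_id"]).to_numpy() * pixel_area_km2
    labels = pd.cut(area, class_edges_km2)
    recs = records.copy()
    recs["size_class"] = labels
    groups = recs.groupby("size_class", observed=True)
    sums = groups[CONTRIB_COLS].sum()
    out = sums.div(sums.sum(axis=1), axis=0) * 100.0
    out.columns = [c.removeprefix("contrib_") for c in out.columns]
    out["n_stops"] = groups.size()
    return out


def run_report(records: pd.DataFrame) -> str:
    """Plain-text summary of one attribution run."""
    n = len(records)
    lines = [f"fire stops analysed: {n}"]
    if n == 0:
        return "\n".join(lines) + "\n"
    explained = records["explained"].mean() * 100.0
    lines.append(f"explained: {explained:.1f}% (p < 0.01, any driver)")
    testable = records.get("landscape_testable")
    if testable is not None:
        lines.append(f"landscape-testable stops: {int(testable.sum())}")
    excl = records.get("weather_excluded")
    if excl is not None:
        lines.append(f"weather-excluded stops: {int((excl != '').sum())}")
    lines.append("driver flag percentages (can sum past 100):")
    for d in ALL_DRIVERS:
        lines.append(f"  {d:14s} {records[f'final_{d}'].mean() * 100.0:6.1f}%")
    sums = records[CONTRIB_COLS].sum()
    shares = sums / sums.sum() * 100.0
    lines.append("relative shares (sum to 100, incl. unknown):")
    for c in CONTRIB_COLS:
        lines.append(f"  {c.removeprefix('contrib_'):14s} {shares[c]:6.1f}%")
    return "\n".join(lines) + "\n"
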