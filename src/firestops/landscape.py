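"""Bottom-up (landscape) attribution at fire stops.

At each stop an ellipse is oriented with its major axis perpendicular to the
fire perimeter (along the outward direction) and centred halfway between the
stop pixel and its nearest burned pixel, so roughly half the ellipse covers
burned and half unburned ground. Landscape layers are sampled inside the
ellipse on a 100 m grid at each layer's native resolution, and the burned and
unburned groups are compared: t-tests for continuous layers (tree cover,
aboveground biomass, burn history), chi-squared contingency tests for
categorical ones (land cover, road presence, water presence), and a slope
rule for terrain. Every test is gated on the direction a fire stop requires
(e.g. less fuel, more water *outside* the perimeter) at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import RasterGrid
from .perimeter import BurnScene

__all__ = [
    "LandscapeStack",
    "OrientedEllipse",
    "build_ellipse",
    "sample_ellipse",
    "test_continuous",
    "test_categorical",
    "test_downslope",
    "combine_fuel_load",
    "attribute_landscape",
    "CONTINUOUS_DIRECTIONS",
]

#: direction of change, inside → outside, required to call a layer a stop cause
CONTINUOUS_DIRECTIONS = {
    "tree_cover": "decline",      # less canopy fuel outside
    "agb": "decline",             # less biomass outside
    "burn_history": "increase",   # stronger fuel reduction (more recent fire) outside
}


@dataclass
class LandscapeStack:
    """The landscape layers, each at its own native resolution.

    ``burn_history`` holds years since the last fire (a large sentinel such
    as 9999 meaning no recorded fire); it is converted to a fuel-reduction
    fraction via a linear recovery over ``recovery_years`` when sampled:
    reduction = clip(1 − years/recovery_years, 0, 1).
    """

    tree_cover: RasterGrid        # percent, 30 m
    agb: RasterGrid               # Mg/ha, 100 m
    land_cover: RasterGrid        # class codes, ~345 m
    burn_history: RasterGrid      # years since last fire, 300 m
    elevation: RasterGrid         # m, 30 m
    road_presence: RasterGrid     # binary, 30 m
    water_presence: RasterGrid    # binary, 30 m
    recovery_years: float = 25.0

    CONTINUOUS = ("tree_cover", "agb", "burn_history")
    CATEGORICAL = ("land_cover", "road", "water")

    def layers(self) -> dict[str, RasterGrid]:
        return {
            "tree_cover": self.tree_cover,
            "agb": self.agb,
            "land_cover": self.land_cover,
            "burn_history": self.burn_history,
            "elevation": self.elevation,
            "road": self.road_presence,
            "water": self.water_presence,
        }

    def validate_frame(self, scene: BurnScene) -> None:
        for name, layer in self.layers().items():
            if not layer.covers(scene.day_of_burn):
                raise ValueError(
                    f"layer {name!r} does not cover the burn scene frame "
                    f"(crs/extent mismatch)"
                )

    def fuel_reduction(self, years_since):
        """Fuel-reduction fraction left by a past fire after ``years_since`` years."""
        y = np.asarray(years_since, dtype=float)
        return np.clip(1.0 - y / self.recovery_years, 0.0, 1.0)


@dataclass(frozen=True)
class OrientedEllipse:
    """The perimeter-perpendicular sampling ellipse of one stop."""

    center: tuple[float, float]
    semi_major: float             # along the outward direction, meters
    semi_minor: float
    orientation: tuple[float, float]  # outward unit vector

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("require semi_major >= semi_minor > 0")
        nx, ny = self.orientation
        if abs(np.hypot(nx, ny) - 1.0) > 1e-6:
            raise ValueError("orientation must be a unit vector")

    @property
    def minor_direction(self) -> tuple[float, float]:
        nx, ny = self.orientation
        return (-ny, nx)

    def contains(self, x, y) -> np.ndarray:
        """Strict point-in-ellipse test in the rotated frame."""
        cx, cy = self.center
        nx, ny = self.orientation
        dx, dy = np.asarray(x) - cx, np.asarray(y) - cy
        a = dx * nx + dy * ny          # along-major coordinate
        b = -dx * ny + dy * nx         # along-minor coordinate
        return (a / self.semi_major) ** 2 + (b / self.semi_minor) ** 2 < 1.0

    @property
    def area(self) -> float:
        return float(np.pi * self.semi_major * self.semi_minor)


def build_ellipse(
    stop: pd.Series,
    scene: BurnScene,
    spacing: float | None = None,
    major_mult: float = 3.0,
    minor_mult: float = 1.5,
) -> OrientedEllipse | None:
    """The sampling ellipse of one stop, or None for degenerate stops.

    Axis lengths default to 3× (major) and 1.5× (minor) the stop spacing —
    900 m × 450 m at the 300 m spacing of the burn grid. The center is the
    midpoint of the stop pixel center and the nearest burned pixel center, so
    the ellipse straddles the perimeter.
    """
    if not bool(stop.get("direction_defined", True)):
        return None
    if spacing is None:
        spacing = scene.pixel_size
    sx, sy = scene.day_of_burn.cell_center(stop["row"], stop["col"])
    bx, by = scene.day_of_burn.cell_center(stop["nb_row"], stop["nb_col"])
    center = ((float(sx) + float(bx)) / 2.0, (float(sy) + float(by)) / 2.0)
    return OrientedEllipse(
        center=center,
        semi_major=major_mult * spacing / 2.0,
        semi_minor=minor_mult * spacing / 2.0,
        orientation=(float(stop["dir_x"]), float(stop["dir_y"])),
    )


def sample_ellipse(
    ellipse: OrientedEllipse,
    scene: BurnScene,
    stack: LandscapeStack,
    grid_step: float = 100.0,
) -> pd.DataFrame:
    """Landscape values on a regular grid clipped to the ellipse.

    The grid is aligned with the ellipse axes and anchored deterministically:
    integer-step offsets along the major axis, half-step offsets along the
    minor axis (the half shift keeps grid rows off the ellipse center line so
    the point count honours the sampled-area budget). Points strictly inside
    the ellipse are kept; points falling outside the raster frame are dropped.

    Columns: x, y, along (signed major-axis coordinate), burned, plus one
    column per landscape layer (burn_history already converted to the
    fuel-reduction fraction).
    """
    a, b = ellipse.semi_major, ellipse.semi_minor
    ni = int(np.floor(a / grid_step))
    nj = int(np.ceil(b / grid_step - 0.5))
    ii = np.arange(-ni, ni + 1) * grid_step
    jj = (np.arange(-nj, nj) + 0.5) * grid_step
    ai, bj = np.meshgrid(ii, jj, indexing="ij")
    inside = (ai / a) ** 2 + (bj / b) ** 2 < 1.0
    ai, bj = ai[inside], bj[inside]

    ux, uy = ellipse.orientation
    vx, vy = ellipse.minor_direction
    cx, cy = ellipse.center
    x = cx + ai * ux + bj * vx
    y = cy + ai * uy + bj * vy

    dob = scene.day_of_burn.sample(x, y)
    ok = np.isfinite(dob)
    x, y, ai, dob = x[ok], y[ok], ai[ok], dob[ok]

    df = pd.DataFrame({"x": x, "y": y, "along": ai, "burned": dob > 0})
    for name, layer in stack.layers().items():
        vals = layer.sample(x, y)
        if name == "burn_history":
            vals = stack.fuel_reduction(vals)
        df[name] = vals
    return df


def _welch(burned_vals: np.ndarray, unburned_vals: np.ndarray):
    """Welch t-test returning (t, p) with the degenerate zero-variance cases."""
    mb, mu = float(np.mean(burned_vals)), float(np.mean(unburned_vals))
    if np.var(burned_vals) == 0.0 and np.var(unburned_vals) == 0.0:
        if mb == mu:
            return 0.0, 1.0
        return (np.inf if mb > mu else -np.inf), 0.0
    t, p = stats.ttest_ind(burned_vals, unburned_vals, equal_var=False)
    return float(t), float(p)


def test_continuous(
    sample: pd.DataFrame,
    layer: str,
    direction: str | None = None,
    alpha: float = 0.01,
    min_group: int = 3,
):
    """Burned-vs-unburned t-test on a continuous layer, with a direction gate.

    Returns (t, p, pass). ``direction`` is the required change from inside to
    outside ("decline": unburned mean lower; "increase": higher); defaults to
    the layer's standard stop direction. Groups smaller than ``min_group``
    make the stop untestable (t=NaN, p=NaN, no pass).
    """
    if direction is None:
        direction = CONTINUOUS_DIRECTIONS[layer]
    vals = sample[layer].to_numpy(dtype=float)
    burned = sample["burned"].to_numpy(dtype=bool)
    finite = np.isfinite(vals)
    bv, uv = vals[burned & finite], vals[~burned & finite]
    if bv.size < min_group or uv.size < min_group:
        return np.nan, np.nan, False
    t, p = _welch(bv, uv)
    if direction == "decline":
        direction_ok = uv.mean() < bv.mean()
    elif direction == "increase":
        direction_ok = uv.mean() > bv.mean()
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return t, p, bool(p < alpha and direction_ok)


def test_categorical(
    sample: pd.DataFrame,
    layer: str,
    alpha: float = 0.01,
    correction_2x2: bool = True,
):
    """Burned-vs-unburned chi-squared test on a categorical layer.

    Builds the group × class contingency table (classes absent from both
    groups are dropped). For road/water presence the direction gate demands a
    higher presence fraction outside the perimeter; for land cover it demands
    that the class gaining the most cover share outside differs from the
    modal class inside. 2×2 tables use the Yates continuity correction
    (configurable); a 2×2 table with any expected count below 1 is skipped.

    Returns (chi2, p, pass, direction_ok).
    """
    vals = sample[layer].to_numpy()
    burned = sample["burned"].to_numpy(dtype=bool)
    finite = np.isfinite(vals.astype(float))
    vals, burned = vals[finite], burned[finite]
    if burned.all() or (~burned).all() or vals.size == 0:
        return np.nan, np.nan, False, False

    classes = np.unique(vals)
    table = np.array(
        [
            [np.sum((vals == c) & burned) for c in classes],
            [np.sum((vals == c) & ~burned) for c in classes],
        ],
        dtype=float,
    )
    keep = table.sum(axis=0) > 0
    table, classes = table[:, keep], classes[keep]
    if table.shape[1] < 2:
        return 0.0, 1.0, False, False

    expected = stats.contingency.expected_freq(table)
    if table.shape[1] == 2 and (expected < 1).any():
        return np.nan, np.nan, False, False
    correction = correction_2x2 and table.shape[1] == 2
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)

    share_in = table[0] / table[0].sum()
    share_out = table[1] / table[1].sum()
    if layer in ("road", "water"):
        # presence = class code 1
        present = classes.astype(float) == 1.0
        direction_ok = bool(share_out[present].sum() > share_in[present].sum())
    elif layer == "land_cover":
        gain_class = classes[int(np.argmax(share_out - share_in))]
        modal_in = classes[int(np.argmax(table[0]))]
        direction_ok = bool(gain_class != modal_in)
    else:
        raise ValueError(f"unknown categorical layer {layer!r}")
    return float(chi2), float(p), bool(p < alpha and direction_ok), direction_ok


def test_downslope(
    sample: pd.DataFrame,
    alpha: float = 0.01,
    slope_threshold_deg: float = -5.0,
    min_group: int = 3,
):
    """Terrain-drop test: significant elevation decline outward at ≤ −5°.

    The slope is arctan(Δmean elevation / Δmean along-axis position) in
    degrees, signed along the outward direction (negative = downhill going
    out of the fire). Flagging requires a significant decline (t-test,
    p < alpha) *and* a slope at or below the threshold — gentle declines do
    not meaningfully limit spread. Returns (slope_deg, p, pass).
    """
    vals = sample["elevation"].to_numpy(dtype=float)
    burned = sample["burned"].to_numpy(dtype=bool)
    along = sample["along"].to_numpy(dtype=float)
    finite = np.isfinite(vals)
    bv, uv = vals[burned & finite], vals[~burned & finite]
    if bv.size < min_group or uv.size < min_group:
        return np.nan, np.nan, False
    d_elev = uv.mean() - bv.mean()
    d_along = along[~burned & finite].mean() - along[burned & finite].mean()
    if d_along <= 0:
        return np.nan, np.nan, False
    slope_deg = float(np.degrees(np.arctan2(d_elev, d_along)))
    _, p = _welch(bv, uv)
    ok = bool(p < alpha and d_elev < 0 and slope_deg <= slope_threshold_deg)
    return slope_deg, p, ok


def combine_fuel_load(tree_cover_pass: bool, agb_pass: bool) -> bool:
    """Fuel-load flag: a decline in tree cover and/or aboveground biomass."""
    return bool(tree_cover_pass or agb_pass)


def attribute_landscape(
    stop: pd.Series,
    scene: BurnScene,
    stack: LandscapeStack,
    alpha: float = 0.01,
    grid_step: float = 100.0,
    major_mult: float = 3.0,
    minor_mult: float = 1.5,
    slope_threshold_deg: float = -5.0,
) -> dict:
    """All landscape tests for one stop, as a flat record.

    Raised flags: ``water``, ``road``, ``burn_history``, ``fuel_load``
    (tree-cover and/or biomass decline), ``land_cover``, ``downslope``; each
    with its statistic and p-value. Stops without a defined outward direction
    or with an empty burned/unburned group are untestable: all flags False
    and ``landscape_testable`` False.
    """
    out: dict = {"landscape_testable": False}
    for name in ("water", "road", "burn_history", "fuel_load", "land_cover", "downslope"):
        out[name] = False
    ellipse = build_ellipse(stop, scene, major_mult=major_mult, minor_mult=minor_mult)
    if ellipse is None:
        out["landscape_excluded"] = "direction-undefined"
        return out
    sample = sample_ellipse(ellipse, scene, stack, grid_step=grid_step)
    n_b = int(sample["burned"].sum())
    n_u = int((~sample["burned"]).sum())
    out["n_burned_samples"], out["n_unburned_samples"] = n_b, n_u
    if n_b == 0 or n_u == 0:
        out["landscape_excluded"] = "one-sided-ellipse"
        return out
    out["landscape_testable"] = True

    for layer in ("tree_cover", "agb", "burn_history"):
        t, p, ok = test_continuous(sample, layer, alpha=alpha)
        out[f"{layer}_t"], out[f"{layer}_p"], out[f"{layer}_pass"] = t, p, ok
    out["burn_history"] = out["burn_history_pass"]
    out["fuel_load"] = combine_fuel_load(out["tree_cover_pass"], out["agb_pass"])

    for layer in ("water", "road", "land_cover"):
        chi2, p, ok, direction_ok = test_categorical(sample, layer, alpha=alpha)
        out[f"{layer}_chi2"], out[f"{layer}_p"] = chi2, p
        out[f"{layer}_direction_ok"] = direction_ok
        out[layer] = ok

    slope, p, ok = test_downslope(sample, alpha=alpha, slope_threshold_deg=slope_threshold_deg)
    out["slope_deg"], out["slope_p"], out["downslope"] = slope, p, ok
    return out
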