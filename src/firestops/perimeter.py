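"""Fire-stop extraction from day-of-burn rasters.

A *fire stop* is an unburned 300 m pixel touching (8-neighbour, "Queen's"
adjacency) the burned pixels of one fire: the atomic unit at which cessation
causes are attributed. Each stop carries the burn date of the nearest burned
pixel — the moment spread last halted there — and an outward unit vector
pointing from the fire into unburned land, which later orients the wind
projection and the sampling ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import RasterGrid

__all__ = [
    "BurnScene",
    "label_fire_events",
    "filter_small_fires",
    "extract_fire_stops",
    "compute_outward_direction",
]

# Queen's (first-order, 8-neighbour) structuring element.
QUEEN = np.ones((3, 3), dtype=bool)

#: offsets of the 8 Queen neighbours with their center distances (pixel units)
_NEIGHBOUR_OFFSETS = [
    (dr, dc, float(np.hypot(dr, dc)))
    for dr in (-1, 0, 1)
    for dc in (-1, 0, 1)
    if not (dr == 0 and dc == 0)
]


@dataclass
class BurnScene:
    """Day-of-burn + fire-event labels for one fire year on a 300 m grid.

    ``day_of_burn`` is 0 for unburned cells, else an integer day of year.
    ``fire_id`` is 0 for no fire, else a dense positive event label. The two
    grids share one georeference; ``fire_id > 0`` exactly where
    ``day_of_burn > 0``.
    """

    day_of_burn: RasterGrid
    fire_id: RasterGrid
    year: int = 0

    def __post_init__(self) -> None:
        if self.day_of_burn.shape != self.fire_id.shape:
            raise ValueError("day_of_burn and fire_id grids differ in shape")
        burned = self.day_of_burn.data > 0
        labelled = self.fire_id.data > 0
        if not np.array_equal(burned, labelled):
            raise ValueError("fire_id > 0 must hold exactly where day_of_burn > 0")

    @property
    def pixel_size(self) -> float:
        return self.day_of_burn.pixel_size

    def fire_sizes(self) -> pd.Series:
        """Pixel count per fire id (index = fire id)."""
        ids = self.fire_id.data[self.fire_id.data > 0]
        if ids.size == 0:
            return pd.Series(dtype=int, name="n_pixels")
        counts = np.bincount(ids)
        s = pd.Series(counts[1:], index=np.arange(1, counts.size), name="n_pixels")
        return s[s > 0]


def label_fire_events(day_of_burn: np.ndarray, max_gap_days: int = 14) -> np.ndarray:
    """Label spatiotemporal fire events on a day-of-burn grid.

    Two burned pixels belong to the same event iff they are Queen-adjacent and
    their burn dates differ by at most ``max_gap_days``; events are the
    connected components of that graph. Labels are dense from 1; unburned
    pixels get 0.

    This is a helper for rasters that do not already carry event labels (the
    synthetic scenes, or a raw burned-area product).
    """
    dob = np.asarray(day_of_burn)
    burned = dob > 0
    n = int(burned.sum())
    labels = np.zeros(dob.shape, dtype=int)
    if n == 0:
        return labels

    # union-find over burned pixels
    idx = np.full(dob.shape, -1, dtype=int)
    rows, cols = np.nonzero(burned)
    idx[rows, cols] = np.arange(n)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    nr, nc = dob.shape
    for r, c in zip(rows, cols):
        for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):  # forward half of Queen
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and burned[r2, c2]:
                if abs(int(dob[r, c]) - int(dob[r2, c2])) <= max_gap_days:
                    ra, rb = find(idx[r, c]), find(idx[r2, c2])
                    if ra != rb:
                        parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    _, dense = np.unique(roots, return_inverse=True)
    labels[rows, cols] = dense + 1
    return labels


def filter_small_fires(scene: BurnScene, min_pixels: int = 6) -> BurnScene:
    """Drop fires smaller than ``min_pixels`` contiguous pixels.

    The default of six 300 m pixels (0.54 km²) removes the small events whose
    perimeters are dominated by detection noise; removed pixels become
    unburned so they produce no stops downstream.
    """
    sizes = scene.fire_sizes()
    keep = set(sizes.index[sizes >= min_pixels])
    fid = scene.fire_id.data
    mask = np.isin(fid, list(keep)) if keep else np.zeros_like(fid, dtype=bool)
    new_fid = np.where(mask, fid, 0)
    new_dob = np.where(mask, scene.day_of_burn.data, 0)
    return BurnScene(
        day_of_burn=scene.day_of_burn.like(new_dob),
        fire_id=scene.fire_id.like(new_fid),
        year=scene.year,
    )


def _nearest_burned_neighbour(scene: BurnScene, row: int, col: int, fire: int):
    """Nearest burned pixel of ``fire`` in the 3×3 window around (row, col).

    Returns (nb_row, nb_col, date). Orthogonal neighbours (distance 1) beat
    diagonal ones (distance √2); among equidistant candidates the *latest*
    burn date wins — the stop represents where spread last halted.
    """
    dob = scene.day_of_burn.data
    fid = scene.fire_id.data
    nr, nc = dob.shape
    best = None  # (distance, -date, row, col)
    for dr, dc, dist in _NEIGHBOUR_OFFSETS:
        r2, c2 = row + dr, col + dc
        if 0 <= r2 < nr and 0 <= c2 < nc and fid[r2, c2] == fire:
            key = (dist, -int(dob[r2, c2]))
            if best is None or key < best[0]:
                best = (key, r2, c2)
    if best is None:
        raise ValueError(f"pixel ({row}, {col}) has no Queen neighbour of fire {fire}")
    _, r2, c2 = best
    return r2, c2, int(dob[r2, c2])


def compute_outward_direction(
    scene: BurnScene, row: int, col: int, fire: int, neighborhood_radius: int = 1
):
    """Unit vector from the fire toward the unburned stop pixel.

    The direction is the normalised vector from the centroid of the fire's
    burned pixels within ``neighborhood_radius`` of the stop to the stop
    center. If the surround is symmetric (centroid on the stop), fall back to
    the vector from the single nearest burned pixel; a still-degenerate stop
    is returned as (nan, nan) and excluded from wind and ellipse analyses.
    """
    fid = scene.fire_id.data
    nr, nc = fid.shape
    r0 = max(0, row - neighborhood_radius)
    r1 = min(nr, row + neighborhood_radius + 1)
    c0 = max(0, col - neighborhood_radius)
    c1 = min(nc, col + neighborhood_radius + 1)
    sub = fid[r0:r1, c0:c1] == fire
    rs, cs = np.nonzero(sub)
    if rs.size == 0:
        return float("nan"), float("nan")
    # grid vector toward the stop: +x is +col (east), +y is -row (north)
    dx = float(np.mean(col - (cs + c0)))
    dy = float(np.mean((rs + r0) - row))  # row decreases northwards
    norm = float(np.hypot(dx, dy))
    if norm < 1e-12:
        nb_r, nb_c, _ = _nearest_burned_neighbour(scene, row, col, fire)
        dx, dy = float(col - nb_c), float(nb_r - row)
        norm = float(np.hypot(dx, dy))
        if norm < 1e-12:
            return float("nan"), float("nan")
    return dx / norm, dy / norm


def extract_fire_stops(scene: BurnScene, neighborhood_radius: int = 1) -> pd.DataFrame:
    """All fire stops of a scene, one row per (fire, unburned pixel) pair.

    Stops are emitted per fire: an unburned pixel wedged between two fires
    yields one stop for each. Columns:

    ``fire_id, row, col, x, y, last_burn_date, nb_row, nb_col,
    dir_x, dir_y, direction_defined, year``

    where (nb_row, nb_col) is the nearest burned pixel used for the date and
    for centring the sampling ellipse, and (dir_x, dir_y) the outward unit
    vector (NaN when degenerate).
    """
    fid = scene.fire_id.data
    dob_grid = scene.day_of_burn
    unburned = scene.day_of_burn.data == 0
    records: list[dict] = []
    for fire in np.unique(fid[fid > 0]):
        mask = fid == fire
        ring = ndimage.binary_dilation(mask, structure=QUEEN) & unburned
        for row, col in zip(*np.nonzero(ring)):
            nb_r, nb_c, date = _nearest_burned_neighbour(scene, row, col, int(fire))
            dx, dy = compute_outward_direction(
                scene, int(row), int(col), int(fire), neighborhood_radius
            )
            x, y = dob_grid.cell_center(row, col)
            records.append(
                {
                    "fire_id": int(fire),
                    "row": int(row),
                    "col": int(col),
                    "x": float(x),
                    "y": float(y),
                    "last_burn_date": date,
                    "nb_row": nb_r,
                    "nb_col": nb_c,
                    "dir_x": dx,
                    "dir_y": dy,
                    "direction_defined": bool(np.isfinite(dx) and np.isfinite(dy)),
                    "year": scene.year,
                }
            )
    columns = [
        "fire_id", "row", "col", "x", "y", "last_burn_date",
        "nb_row", "nb_col", "dir_x", "dir_y", "direction_defined", "year",
    ]
    df = pd.DataFrame.from_records(records, columns=columns)
    return df.sort_values(["fire_id", "row", "col"], ignore_index=True)
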