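"""Reading and writing the pipeline's on-disk formats.

Rasters are stored as single-band TIFF with a JSON sidecar carrying the
georeference (pixel size, top-left origin, CRS label, nodata); weather cubes
as NetCDF (classic format via xarray's scipy backend); stops and attribution
records as CSV and GeoJSON points; configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr
import yaml

from .grids import RasterGrid
from .perimeter import BurnScene
from .landscape import LandscapeStack

__all__ = [
    "write_raster",
    "read_raster",
    "write_burn_scene",
    "read_burn_scene",
    "write_landscape_stack",
    "read_landscape_stack",
    "write_weather_cube",
    "read_weather_cube",
    "stops_to_geojson",
    "write_stops",
    "read_stops",
    "write_config",
    "read_config",
]


def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write one raster as TIFF + ``<path>.georef.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(grid.data))
    meta = {
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
        "crs": grid.crs,
        "nodata": grid.nodata,
    }
    path.with_suffix(path.suffix + ".georef.json").write_text(json.dumps(meta, indent=1))


def read_raster(path: str | Path) -> RasterGrid:
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".georef.json").read_text())
    return RasterGrid(
        data,
        pixel_size=float(meta["pixel_size"]),
        origin=tuple(meta["origin"]),
        crs=meta["crs"],
        nodata=meta["nodata"],
    )


def write_burn_scene(directory: str | Path, scene: BurnScene) -> None:
    directory = Path(directory)
    write_raster(directory / "day_of_burn.tif", scene.day_of_burn)
    write_raster(directory / "fire_id.tif", scene.fire_id)
    (directory / "scene.json").write_text(json.dumps({"year": scene.year}))


def read_burn_scene(directory: str | Path) -> BurnScene:
    directory = Path(directory)
    meta = json.loads((directory / "scene.json").read_text())
    return BurnScene(
        day_of_burn=read_raster(directory / "day_of_burn.tif"),
        fire_id=read_raster(directory / "fire_id.tif"),
        year=int(meta["year"]),
    )


_STACK_FILES = {
    "tree_cover": "tree_cover.tif",
    "agb": "agb.tif",
    "land_cover": "land_cover.tif",
    "burn_history": "burn_history.tif",
    "elevation": "elevation.tif",
    "road_presence": "road_presence.tif",
    "water_presence": "water_presence.tif",
}


def write_landscape_stack(directory: str | Path, stack: LandscapeStack) -> None:
    directory = Path(directory)
    for attr, fname in _STACK_FILES.items():
        write_raster(directory / fname, getattr(stack, attr))
    (directory / "stack.json").write_text(json.dumps({"recovery_years": stack.recovery_years}))


def read_landscape_stack(directory: str | Path) -> LandscapeStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers = {attr: read_raster(directory / fname) for attr, fname in _STACK_FILES.items()}
    return LandscapeStack(recovery_years=float(meta["recovery_years"]), **layers)


def write_weather_cube(path: str | Path, cube: xr.Dataset) -> None:
    """NetCDF (classic format, scipy backend — no HDF5 dependency)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cube.to_netcdf(path, engine="scipy")


def read_weather_cube(path: str | Path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def stops_to_geojson(stops: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection of stop points (projected coordinates)."""
    feats = []
    for _, s in stops.iterrows():
        props = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in s.items()
            if k not in ("x", "y")
        }
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(s["x"]), float(s["y"])]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_stops(path: str | Path, stops: pd.DataFrame) -> None:
    """CSV plus a GeoJSON twin (same stem, .geojson suffix)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stops.to_csv(path, index=False)
    path.with_suffix(".geojson").write_text(json.dumps(stops_to_geojson(stops)))


def read_stops(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_config(path: str | Path, config) -> None:
    """Any dataclass config as YAML (nested dataclasses included)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    path.write_text(yaml.safe_dump(plain(config), sort_keys=False))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
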