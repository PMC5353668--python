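"""Reading and writing grids, layers, species tables and configs.

Layers travel as long-format CSV (cell_id, lat, lon, value) or CF-style
NetCDF (via xarray, scipy backend); species tables as CSV with
semicolon-joined cell ids; configs as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .grid import GridLayer, GridSpec, build_grid
from .species import SpeciesRecord

__all__ = [
    "layer_to_frame", "write_layer_csv", "read_layer_csv",
    "layer_to_dataarray", "write_layer_netcdf", "read_layer_netcdf",
    "write_grid_json", "read_grid_json",
    "species_to_frame", "write_species_csv", "read_species_csv",
    "load_yaml", "dump_yaml",
]


# -- grid ------------------------------------------------------------------

def write_grid_json(grid: GridSpec, path) -> None:
    payload = {
        "extent": [grid.lat_min, grid.lat_max, grid.lon_min, grid.lon_max],
        "resolution": grid.resolution,
        "land_mask": grid.land_mask.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_grid_json(path) -> GridSpec:
    payload = json.loads(Path(path).read_text())
    return build_grid(payload["extent"], payload["resolution"],
                      np.asarray(payload["land_mask"], dtype=bool))


# -- layers ----------------------------------------------------------------

def layer_to_frame(layer: GridLayer) -> pd.DataFrame:
    grid = layer.grid
    ids = grid.land_ids
    return pd.DataFrame({
        "cell_id": ids,
        "lat": grid.centroid_lat[ids],
        "lon": grid.centroid_lon[ids],
        "value": layer.values[ids],
    })


def write_layer_csv(layer: GridLayer, path) -> None:
    layer_to_frame(layer).to_csv(path, index=False)


def read_layer_csv(path, grid: GridSpec) -> GridLayer:
    df = pd.read_csv(path)
    values = np.full(grid.n_cells, np.nan)
    values[df["cell_id"].to_numpy(dtype=int)] = df["value"].to_numpy(dtype=float)
    return grid.layer(values)


def layer_to_dataarray(layer: GridLayer, name: str = "value") -> xr.DataArray:
    grid = layer.grid
    lat = grid.centroid_lat[:: grid.ncols]
    lon = grid.centroid_lon[: grid.ncols]
    return xr.DataArray(
        layer.as_2d(), coords={"lat": lat, "lon": lon}, dims=("lat", "lon"),
        name=name,
        attrs={"resolution_deg": grid.resolution},
    )


def write_layer_netcdf(layer: GridLayer, path, name: str = "value") -> None:
    layer_to_dataarray(layer, name).to_dataset().to_netcdf(path, engine="scipy")


def read_layer_netcdf(path, grid: GridSpec, name: str = "value") -> GridLayer:
    with xr.open_dataset(path, engine="scipy") as ds:
        values = ds[name].values.ravel()
    return grid.layer(values)


# -- species ---------------------------------------------------------------

def species_to_frame(records: list[SpeciesRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "species_id": [r.species_id for r in records],
        "taxon": [r.taxon for r in records],
        "habitat": ["|".join(sorted(r.habitats)) for r in records],
        "iucn_category": [r.iucn_category for r in records],
        "cell_ids": [";".join(map(str, r.cells.tolist())) for r in records],
    })


def write_species_csv(records: list[SpeciesRecord], path) -> None:
    species_to_frame(records).to_csv(path, index=False)


def read_species_csv(path) -> list[SpeciesRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        cells = np.array([int(c) for c in row.cell_ids.split(";") if c != ""],
                         dtype=np.int64)
        records.append(SpeciesRecord(
            species_id=row.species_id,
            taxon=row.taxon,
            habitats=frozenset(t for t in row.habitat.split("|") if t),
            iucn_category=row.iucn_category,
            cells=cells,
        ))
    return records


# -- configs ---------------------------------------------------------------

def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(obj, path) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
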