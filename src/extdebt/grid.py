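"""Geographic grid geometry: cells, spherical areas, distances, adjacency.

Everything downstream (forest metrics, richness maps, debt maps) lives on a
regular latitude/longitude grid. Cells are indexed row-major starting at the
north-west corner; a boolean land mask marks which cells carry data. Areas
and distances are computed on a sphere of radius 6371.0088 km (IUGG mean
Earth radius).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "GridSpec",
    "GridLayer",
    "DistanceMatrix",
    "build_grid",
    "cell_area",
    "great_circle_distance",
    "distance_matrix",
]


def cell_area(lat_bottom: float, lat_top: float, lon_width: float) -> float:
    """Area in km² of a lat/lon cell (spherical zone segment).

    A = R² · Δλ · (sin φ_top − sin φ_bottom), with Δλ in radians.
    """
    lat_bottom = np.asarray(lat_bottom, dtype=float)
    lat_top = np.asarray(lat_top, dtype=float)
    if np.any(lat_bottom >= lat_top):
        raise ValueError("lat_bottom must be strictly below lat_top")
    if np.any(lat_bottom < -90.0) or np.any(lat_top > 90.0):
        raise ValueError("latitudes must lie in [-90, 90]")
    dlon = np.deg2rad(lon_width)
    area = EARTH_RADIUS_KM**2 * dlon * (
        np.sin(np.deg2rad(lat_top)) - np.sin(np.deg2rad(lat_bottom))
    )
    return float(area) if area.ndim == 0 else area


def great_circle_distance(p1, p2) -> float:
    """Haversine great-circle distance in km between (lat, lon) points.

    Accepts scalars or broadcastable arrays of degrees.
    """
    lat1, lon1 = (np.deg2rad(np.asarray(c, dtype=float)) for c in p1)
    lat2, lon2 = (np.deg2rad(np.asarray(c, dtype=float)) for c in p2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if d.ndim == 0 else d


@dataclass(frozen=True, eq=False)
class GridSpec:
    """A regular lat/lon grid with a land mask.

    Cell ids run row-major from the north-west corner: id = row * ncols + col,
    row 0 being the northernmost band. Longitude wraps when the grid spans a
    full 360°; latitude never wraps across the poles.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float
    land_mask: np.ndarray  # (nrows, ncols) bool

    def __post_init__(self):
        mask = np.asarray(self.land_mask, dtype=bool)
        object.__setattr__(self, "land_mask", mask)
        if mask.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"land_mask shape {mask.shape} does not match grid "
                f"({self.nrows}, {self.ncols})"
            )
        if not mask.any():
            raise ValueError("land mask has no land cells")

    def __eq__(self, other):
        if not isinstance(other, GridSpec):
            return NotImplemented
        scalars = ("lat_min", "lat_max", "lon_min", "lon_max", "resolution")
        return (all(getattr(self, f) == getattr(other, f) for f in scalars)
                and np.array_equal(self.land_mask, other.land_mask))

    def __hash__(self):
        return hash((self.lat_min, self.lat_max, self.lon_min, self.lon_max,
                     self.resolution, self.land_mask.tobytes()))

    # -- shape ---------------------------------------------------------------

    @property
    def nrows(self) -> int:
        return _n_steps(self.lat_max - self.lat_min, self.resolution)

    @property
    def ncols(self) -> int:
        return _n_steps(self.lon_max - self.lon_min, self.resolution)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def wraps_lon(self) -> bool:
        return abs((self.lon_max - self.lon_min) - 360.0) < 1e-9

    # -- per-cell geometry ---------------------------------------------------

    @property
    def centroid_lat(self) -> np.ndarray:
        """Centroid latitude per cell id (degrees)."""
        rows = np.arange(self.nrows)
        lat = self.lat_max - (rows + 0.5) * self.resolution
        return np.repeat(lat, self.ncols)

    @property
    def centroid_lon(self) -> np.ndarray:
        cols = np.arange(self.ncols)
        lon = self.lon_min + (cols + 0.5) * self.resolution
        return np.tile(lon, self.nrows)

    @property
    def cell_areas(self) -> np.ndarray:
        """Spherical area per cell id (km²)."""
        rows = np.arange(self.nrows)
        top = self.lat_max - rows * self.resolution
        bottom = top - self.resolution
        per_row = cell_area(bottom, top, self.resolution)
        return np.repeat(per_row, self.ncols)

    @property
    def land_ids(self) -> np.ndarray:
        return np.flatnonzero(self.land_mask.ravel())

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def rowcol(self, cell_id) -> tuple:
        return np.divmod(np.asarray(cell_id), self.ncols)

    # -- adjacency -----------------------------------------------------------

    def neighbors(self, cell_id: int) -> np.ndarray:
        """Von Neumann neighbor ids: longitude wraps (on full-width grids),
        latitude clamps (no neighbor across a pole or the grid edge).

        Masked (non-land) neighbors are included; callers that need land-only
        adjacency should intersect with the mask.
        """
        row, col = divmod(int(cell_id), self.ncols)
        out = []
        if row > 0:
            out.append((row - 1) * self.ncols + col)
        if row < self.nrows - 1:
            out.append((row + 1) * self.ncols + col)
        for dc in (-1, 1):
            c = col + dc
            if 0 <= c < self.ncols:
                out.append(row * self.ncols + c)
            elif self.wraps_lon:
                out.append(row * self.ncols + c % self.ncols)
        return np.array(sorted(out), dtype=np.int64)

    def neighbor_matrix(self) -> np.ndarray:
        """(n_cells, 4) neighbor ids with -1 where a neighbor does not exist."""
        n = self.n_cells
        ids = np.arange(n)
        row, col = np.divmod(ids, self.ncols)
        up = np.where(row > 0, ids - self.ncols, -1)
        down = np.where(row < self.nrows - 1, ids + self.ncols, -1)
        if self.wraps_lon:
            left = row * self.ncols + (col - 1) % self.ncols
            right = row * self.ncols + (col + 1) % self.ncols
        else:
            left = np.where(col > 0, ids - 1, -1)
            right = np.where(col < self.ncols - 1, ids + 1, -1)
        return np.stack([up, down, left, right], axis=1)

    # -- layers --------------------------------------------------------------

    def layer(self, values=None, fill=np.nan) -> "GridLayer":
        """Build a GridLayer on this grid; off-land cells are set missing."""
        vals = np.full(self.n_cells, fill, dtype=float)
        if values is not None:
            values = np.asarray(values, dtype=float)
            if values.size == self.n_cells:
                vals = values.astype(float).ravel().copy()
            elif values.size == self.n_land:
                vals = np.full(self.n_cells, np.nan)
                vals[self.land_ids] = values.ravel()
            else:
                raise ValueError(
                    f"values size {values.size} matches neither n_cells "
                    f"({self.n_cells}) nor n_land ({self.n_land})"
                )
        vals[~self.land_mask.ravel()] = np.nan
        return GridLayer(grid=self, values=vals)


def _n_steps(extent: float, resolution: float) -> int:
    steps = extent / resolution
    n = round(steps)
    if n < 1 or abs(steps - n) > 1e-9:
        raise ValueError(f"resolution {resolution} does not evenly divide extent {extent}")
    return int(n)


def build_grid(
    extent: Sequence[float] = (-90.0, 90.0, -180.0, 180.0),
    resolution: float = 1.0,
    land_mask: np.ndarray | None = None,
) -> GridSpec:
    """Construct a GridSpec from (lat_min, lat_max, lon_min, lon_max).

    ``land_mask=None`` means all cells are land. Antarctica-style exclusions
    are expressed purely through the mask.
    """
    lat_min, lat_max, lon_min, lon_max = map(float, extent)
    if not (-90.0 <= lat_min < lat_max <= 90.0):
        raise ValueError("invalid latitude extent")
    if not (lon_min < lon_max <= lon_min + 360.0):
        raise ValueError("invalid longitude extent")
    nrows = _n_steps(lat_max - lat_min, resolution)
    ncols = _n_steps(lon_max - lon_min, resolution)
    if land_mask is None:
        land_mask = np.ones((nrows, ncols), dtype=bool)
    return GridSpec(lat_min, lat_max, lon_min, lon_max, float(resolution), land_mask)


@dataclass
class GridLayer:
    """Per-cell real values on a grid; NaN marks masked/undefined cells."""

    grid: GridSpec
    values: np.ndarray  # (n_cells,) float, NaN off land

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_cells:
            raise ValueError("layer length does not match grid")

    @property
    def land_values(self) -> np.ndarray:
        return self.values[self.grid.land_ids]

    def with_values(self, values: np.ndarray) -> "GridLayer":
        return self.grid.layer(values)

    def as_2d(self) -> np.ndarray:
        return self.values.reshape(self.grid.nrows, self.grid.ncols)

    # arithmetic propagates missingness through NaN semantics
    def _binop(self, other, op):
        o = other.values if isinstance(other, GridLayer) else other
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return self.grid.layer(op(self.values, o))

    def __add__(self, other):
        return self._binop(other, np.add)

    def __sub__(self, other):
        return self._binop(other, np.subtract)

    def __mul__(self, other):
        return self._binop(other, np.multiply)

    def __truediv__(self, other):
        return self._binop(other, np.divide)


@dataclass
class DistanceMatrix:
    """Pairwise great-circle distances (km) among land-cell centroids.

    Entries beyond an optional cutoff are NaN ("absent"); metric kernels
    treat absent pairs as zero contribution. Row/col order follows
    ``grid.land_ids``.
    """

    grid: GridSpec
    distances: np.ndarray  # (n_land, n_land), NaN = beyond cutoff
    cutoff: float | None = None

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.distances)


def distance_matrix(grid: GridSpec, cutoff: float | None = None) -> DistanceMatrix:
    """All-pairs haversine distances between land-cell centroids."""
    if cutoff is not None and cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    ids = grid.land_ids
    lat = np.deg2rad(grid.centroid_lat[ids])
    lon = np.deg2rad(grid.centroid_lon[ids])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    np.fill_diagonal(d, 0.0)
    if cutoff is not None:
        off = ~np.eye(len(ids), dtype=bool) & (d > cutoff)
        d[off] = np.nan
    return DistanceMatrix(grid=grid, distances=d, cutoff=cutoff)
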