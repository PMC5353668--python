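"""Forest fragmentation predictors per epoch.

Four per-cell predictors are computed from a forest-fraction layer for each
epoch t (the 1500s and the 2000s):

* ``Areas_t(i)``  — forest area, fraction × spherical cell area (km²);
* ``IFM_t(i)``    — incidence-function connectivity,
  Σ_{j≠i} exp(−α·d_ij)·A_t(j), the distance-decayed colonization potential
  familiar from metapopulation theory;
* ``Prox_t(i)``   — proximity, Σ_{j≠i, d_ij≤h} A_t(j)/d_ij², inverse-square
  weighted surrounding forest (low values flag fragmentation);
* ``Conc_t(i)``   — concentration, total forest in the focal cell plus its
  von Neumann neighbors.

All four are linear in the area field; correlations downstream are therefore
insensitive to area units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import DistanceMatrix, GridLayer, GridSpec

PREDICTOR_NAMES = (
    "Areas1500", "Areas2000",
    "IFM1500", "IFM2000",
    "Prox1500", "Prox2000",
    "Conc1500", "Conc2000",
)

__all__ = [
    "PREDICTOR_NAMES",
    "MetricConfig",
    "ForestMetricSet",
    "epoch_mean",
    "forest_area",
    "connectivity_ifm",
    "proximity",
    "concentration",
    "compute_metric_set",
]


@dataclass(frozen=True)
class MetricConfig:
    """Kernel parameters for the distance-based indices.

    alpha: connectivity decay (km⁻¹); default 0.001 gives an e-folding
    distance of 1000 km (~9 one-degree cells at the equator).
    prox_radius: proximity search radius h in km; None = no radius limit.
    ifm_cutoff: distance cutoff for the connectivity sum; None = global.
    """

    alpha: float = 0.001
    prox_radius: float | None = None
    ifm_cutoff: float | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("prox_radius", "ifm_cutoff"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when set")


def epoch_mean(annual_layers: Mapping[int, GridLayer] | Sequence[GridLayer],
               window: tuple[int, int] | None = None) -> GridLayer:
    """Per-cell arithmetic mean of annual forest fractions over a year window.

    ``annual_layers`` is either a {year: layer} mapping (then ``window`` is an
    inclusive (start, end) pair) or a plain sequence of layers to average.
    """
    if isinstance(annual_layers, Mapping):
        if window is None:
            layers = list(annual_layers.values())
        else:
            y0, y1 = window
            layers = [annual_layers[y] for y in annual_layers if y0 <= y <= y1]
    else:
        layers = list(annual_layers)
    if not layers:
        raise ValueError("empty averaging window")
    grid = layers[0].grid
    if any(l.grid is not grid and l.grid != grid for l in layers):
        raise ValueError("annual layers are not on the same grid")
    stack = np.stack([l.values for l in layers])
    return grid.layer(stack.mean(axis=0))


def forest_area(layer: GridLayer, grid: GridSpec | None = None) -> GridLayer:
    """A_t(i) = fraction(i) × cell_area(i), in km²."""
    grid = grid or layer.grid
    frac = layer.values
    finite = np.isfinite(frac)
    if np.any((frac[finite] < 0) | (frac[finite] > 1)):
        raise ValueError("forest fractions must lie in [0, 1]")
    return grid.layer(frac * grid.cell_areas)


def _land_kernel_sum(areas: GridLayer, dmat: DistanceMatrix, weights: np.ndarray) -> GridLayer:
    """Σ_j w_ij A_j over land cells, NaN pairs contributing zero."""
    grid = areas.grid
    a = areas.land_values
    a = np.where(np.isfinite(a), a, 0.0)
    out = weights @ a
    return grid.layer(out)


def connectivity_ifm(
    areas: GridLayer,
    dmat: DistanceMatrix,
    alpha: float = 0.001,
    cutoff: float | None = None,
) -> GridLayer:
    """IFM_t(i) = Σ_{j≠i} exp(−α·d_ij)·A_t(j) over land cells.

    Pairs beyond ``cutoff`` km (or absent from ``dmat``) contribute zero.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    d = np.where(np.isfinite(dmat.distances), dmat.distances, np.inf)
    if cutoff is not None:
        if cutoff < 0:
            raise ValueError("cutoff must be non-negative")
        d = np.where(d > cutoff, np.inf, d)
    w = np.exp(-alpha * d)
    np.fill_diagonal(w, 0.0)
    return _land_kernel_sum(areas, dmat, w)


def proximity(areas: GridLayer, dmat: DistanceMatrix, h: float | None = None) -> GridLayer:
    """Prox_t(i) = Σ_{j≠i, d_ij ≤ h} A_t(j)/d_ij²."""
    if h is not None and h <= 0:
        raise ValueError("search radius must be positive when set")
    d = dmat.distances.copy()
    np.fill_diagonal(d, np.nan)  # self-exclusion
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 1.0 / d**2
    w[~np.isfinite(w)] = 0.0
    if h is not None:
        w[~np.isfinite(d) | (d > h)] = 0.0
    return _land_kernel_sum(areas, dmat, w)


def concentration(areas: GridLayer, grid: GridSpec | None = None) -> GridLayer:
    """Conc_t(i) = Σ_{j ∈ S(i)} A_t(j), S(i) = focal cell ∪ von Neumann
    neighbors; masked or non-existent neighbors contribute zero."""
    grid = grid or areas.grid
    a = np.where(np.isfinite(areas.values), areas.values, 0.0)
    nbrs = grid.neighbor_matrix()  # (n_cells, 4), -1 where absent
    padded = np.concatenate([a, [0.0]])
    conc = a + padded[nbrs].sum(axis=1)  # nbrs == -1 hits the trailing 0
    return grid.layer(conc)


@dataclass
class ForestMetricSet:
    """The eight predictors (4 metrics × 2 epochs) as layers."""

    grid: GridSpec
    layers: dict  # predictor name -> GridLayer

    def table(self) -> pd.DataFrame:
        """Tidy table over land cells: cell_id, lat, lon + 8 predictor columns."""
        ids = self.grid.land_ids
        df = pd.DataFrame({
            "cell_id": ids,
            "lat": self.grid.centroid_lat[ids],
            "lon": self.grid.centroid_lon[ids],
        })
        for name in PREDICTOR_NAMES:
            df[name] = self.layers[name].values[ids]
        return df


def compute_metric_set(
    fraction_1500s: GridLayer,
    fraction_2000s: GridLayer,
    dmat: DistanceMatrix,
    config: MetricConfig = MetricConfig(),
) -> ForestMetricSet:
    """All eight predictors from the two epoch forest-fraction layers."""
    grid = fraction_1500s.grid
    layers: dict[str, GridLayer] = {}
    for epoch, frac in (("1500", fraction_1500s), ("2000", fraction_2000s)):
        areas = forest_area(frac, grid)
        layers[f"Areas{epoch}"] = areas
        layers[f"IFM{epoch}"] = connectivity_ifm(
            areas, dmat, config.alpha, cutoff=config.ifm_cutoff
        )
        layers[f"Prox{epoch}"] = proximity(areas, dmat, config.prox_radius)
        layers[f"Conc{epoch}"] = concentration(areas, grid)
    return ForestMetricSet(grid=grid, layers=layers)
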