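"""Species–area relationship fitting and per-cell extinction-debt maps.

The power-law SAR S = c·A^z links richness to habitat area. Assuming the
1500s richness pattern was at equilibrium with 1500s forest area, and that
contemporary richness still approximates it (the debt not yet paid), the
equilibrium richness under present forest area is

    S_eq(i) = S_obs(i) · (A_2000(i) / A_1500(i))^z

and the extinction debt is Debt(i) = S_obs(i) − S_eq(i). Negative debts are
retained and read as species/immigration credits where forest area grew.
z is either fixed (0.25 by convention; 0.1 and 0.15 as conservative
variants) or fitted per taxon as the slope of ln S on ln A_1500.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import GridLayer

DEFAULT_Z_VALUES = (0.25, 0.1, 0.15)

__all__ = [
    "DEFAULT_Z_VALUES",
    "SARFit",
    "DebtConfig",
    "DebtMap",
    "fit_sar",
    "equilibrium_richness",
    "extinction_debt",
    "compute_debt_maps",
]


@dataclass
class SARFit:
    c: float
    z: float
    r_squared: float
    n_cells: int
    residual_sd: float  # spread of ln S residuals


@dataclass(frozen=True)
class DebtConfig:
    """Which z exponents to map debts under."""

    z_values: tuple = DEFAULT_Z_VALUES
    fit_z: bool = True

    def __post_init__(self):
        if any(z <= 0 for z in self.z_values):
            raise ValueError("fixed z values must be positive")


@dataclass
class DebtMap:
    s_eq: GridLayer
    debt: GridLayer  # S_obs - S_eq; negative = credit; NaN where undefined
    z: float
    z_label: str = ""


def _values(layer) -> np.ndarray:
    return layer.values if isinstance(layer, GridLayer) else np.asarray(layer, dtype=float)


def fit_sar(s_obs, a_1500) -> SARFit:
    """OLS of ln S on ln A over cells with S > 0 and A > 0.

    z is the slope, c = exp(intercept). Natural logs; the slope is
    base-invariant and the intercept is back-transformed consistently.
    """
    s = _values(s_obs)
    a = _values(a_1500)
    keep = np.isfinite(s) & np.isfinite(a) & (s > 0) & (a > 0)
    if keep.sum() < 3:
        raise ValueError("need at least 3 cells with positive richness and area")
    ls, la = np.log(s[keep]), np.log(a[keep])
    if np.ptp(la) == 0:
        raise ValueError("log habitat area is constant; slope undefined")
    res = stats.linregress(la, ls)
    resid = ls - (res.intercept + res.slope * la)
    return SARFit(
        c=float(np.exp(res.intercept)),
        z=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_cells=int(keep.sum()),
        residual_sd=float(resid.std(ddof=2)) if keep.sum() > 2 else 0.0,
    )


def equilibrium_richness(s_obs, a_1500, a_2000, z: float) -> GridLayer:
    """S_eq(i) = S_obs(i)·(A_2000(i)/A_1500(i))^z; cells with A_1500 = 0 are
    masked (0/0 is undefined, not zero debt)."""
    if z <= 0:
        raise ValueError("z must be positive")
    grid = s_obs.grid if isinstance(s_obs, GridLayer) else a_1500.grid
    s = _values(s_obs)
    a1 = _values(a_1500)
    a2 = _values(a_2000)
    finite = np.isfinite(a1) & np.isfinite(a2)
    if np.any(a1[finite] < 0) or np.any(a2[finite] < 0):
        raise ValueError("areas must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a1 > 0, a2 / a1, np.nan)
        s_eq = s * ratio**z
    return grid.layer(s_eq)


def extinction_debt(s_obs, s_eq) -> GridLayer:
    """Debt(i) = S_obs(i) − S_eq(i); negatives retained (credits)."""
    if isinstance(s_obs, GridLayer) and isinstance(s_eq, GridLayer):
        if s_obs.grid != s_eq.grid:
            raise ValueError("richness and equilibrium layers are on different grids")
        grid = s_obs.grid
    else:
        grid = s_obs.grid if isinstance(s_obs, GridLayer) else s_eq.grid
    return grid.layer(_values(s_obs) - _values(s_eq))


def compute_debt_maps(
    s_obs: GridLayer,
    a_1500: GridLayer,
    a_2000: GridLayer,
    config: DebtConfig = DebtConfig(),
) -> tuple[dict[str, DebtMap], SARFit | None]:
    """Debt maps for every configured z variant plus the fitted z (if any)."""
    maps: dict[str, DebtMap] = {}
    for z in config.z_values:
        s_eq = equilibrium_richness(s_obs, a_1500, a_2000, z)
        maps[f"z={z:g}"] = DebtMap(s_eq, extinction_debt(s_obs, s_eq), z, f"z={z:g}")
    fit = None
    if config.fit_z:
        fit = fit_sar(s_obs, a_1500)
        s_eq = equilibrium_richness(s_obs, a_1500, a_2000, fit.z)
        maps["z=fitted"] = DebtMap(s_eq, extinction_debt(s_obs, s_eq), fit.z, "z=fitted")
    return maps, fit
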