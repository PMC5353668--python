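"""Synthetic worlds with known ground truth.

Real inputs for a global extinction-debt analysis are species range maps,
a land-use reconstruction back to 1500 and a contemporary land-cover map.
This module generates stand-ins with the statistical structure the analysis
actually relies on, plus the generative parameters recorded as truth:

* a baseline 1500 forest-fraction field: logistic transform of a spatially
  autocorrelated Gaussian field (white noise smoothed with a Gaussian
  kernel of the configured correlation length);
* monotone deforestation concentrated in a smooth "human pressure" field:
  per-cell cumulative loss = intensity × logistic(pressure), applied along
  a linear annual ramp from 1500 to 2000, so fractions stay in [0, 1] and
  never increase in time;
* species richness planted through a power-law SAR S = c·A_1500^z with
  lognormal noise, species ranges realized as nested threshold sets
  (species k occupies every cell whose target richness ≥ k) or grown as
  connected "spreading-dye" ranges;
* IUCN categories drawn from a configurable multinomial, optionally linked
  to range size.

Everything is a pure function of (config, seed); per-stage substreams keep
one stage's draws independent of another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .grid import GridLayer, GridSpec, build_grid
from .species import SpeciesRecord

IUCN_ASSIGNABLE = ("DD", "LC", "NT", "VU", "EN", "CR")

_STAGE_KEYS = {
    "land": 11, "forest": 12, "pressure": 13, "richness": 14,
    "ranges": 15, "distractors": 16, "iucn": 17,
}

__all__ = [
    "SyntheticConfig",
    "SyntheticWorld",
    "ForestHistory",
    "generate_forest_history",
    "generate_species",
    "assign_iucn_categories",
    "generate_world",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic world; defaults define the study conditions."""

    seed: int = 0
    extent: tuple = (-64.0, 64.0, -180.0, 180.0)
    resolution: float = 4.0
    land_fraction: float = 0.7          # share of cells that are land
    land_corr_length: float = 4.0       # cells

    forest_corr_length: float = 5.0     # cells
    forest_mean: float = 0.45           # baseline mean forest fraction, 1500
    forest_logit_sd: float = 1.5        # spread on the logit scale

    deforest_intensity: float = 0.5     # max cumulative loss fraction, [0, 1]
    pressure_corr_length: float = 8.0   # cells
    pressure_steepness: float = 1.5     # logistic slope on the pressure field
    forest_floor: float = 0.0           # fraction never deforested below

    taxa: tuple = ("reptile", "mammal", "amphibian")
    sar_c: float = 10.0                 # SAR truth, S = c·A^z
    sar_z: float = 0.25
    richness_sigma: float = 0.2         # lognormal richness noise (log sd)
    range_mode: str = "direct-sar"      # or "spreading-dye"
    n_species: int = 300                # per taxon, spreading-dye mode only
    dye_pareto_shape: float = 1.2       # heavy-tailed range-size draw
    dye_size_scale: float = 8.0
    nonforest_fraction: float = 0.05    # distractor (marine/freshwater) species

    iucn_probs: tuple = (0.15, 0.55, 0.10, 0.10, 0.07, 0.03)  # DD LC NT VU EN CR
    threat_size_link: float = 0.0       # 0 = iid draw; 1 = fully size-ranked

    year_start: int = 1500
    year_end: int = 2000
    epoch_1500s: tuple = (1500, 1550)
    epoch_2000s: tuple = (1950, 2000)

    def __post_init__(self):
        probs = np.asarray(self.iucn_probs, dtype=float)
        if probs.size != 6 or np.any(probs < 0):
            raise ValueError("iucn_probs must be 6 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("iucn_probs must sum to 1 (within 1e-12)")
        for name in ("land_corr_length", "forest_corr_length", "pressure_corr_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.deforest_intensity <= 1.0:
            raise ValueError("deforest_intensity must lie in [0, 1]")
        if self.sar_c <= 0 or not 0 < self.sar_z < 1:
            raise ValueError("SAR truth requires c > 0 and z in (0, 1)")
        if self.richness_sigma < 0:
            raise ValueError("richness_sigma must be non-negative")
        if self.range_mode not in ("direct-sar", "spreading-dye"):
            raise ValueError("range_mode must be 'direct-sar' or 'spreading-dye'")

    def rng(self, stage: str) -> np.random.Generator:
        """Named per-stage substream: regenerating one stage does not perturb
        the draws of any other."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STAGE_KEYS[stage]]))


# --------------------------------------------------------------------------
# random fields and the grid

def _smooth_field(shape, corr_length, rng, wrap_lon: bool) -> np.ndarray:
    """Standardized Gaussian random field: white noise smoothed with a
    Gaussian kernel of sd = corr_length cells."""
    noise = rng.standard_normal(shape)
    mode = ("nearest", "wrap" if wrap_lon else "nearest")
    f = gaussian_filter(noise, sigma=corr_length, mode=mode)
    return (f - f.mean()) / f.std()


def build_world_grid(config: SyntheticConfig) -> GridSpec:
    """The grid with a land mask carved from a smooth random field."""
    probe = build_grid(config.extent, config.resolution)
    shape = (probe.nrows, probe.ncols)
    if config.land_fraction >= 1.0:
        mask = np.ones(shape, dtype=bool)
    else:
        f = _smooth_field(shape, config.land_corr_length, config.rng("land"), probe.wraps_lon)
        thr = np.quantile(f, 1.0 - config.land_fraction)
        mask = f >= thr
        if not mask.any():
            mask.ravel()[int(np.argmax(f))] = True
    return build_grid(config.extent, config.resolution, mask)


# --------------------------------------------------------------------------
# forest history

@dataclass
class ForestHistory:
    """Annual forest-fraction layers, year_start..year_end inclusive."""

    grid: GridSpec
    years: np.ndarray            # (n_years,)
    fractions: np.ndarray        # (n_years, n_cells), NaN off land

    def layer(self, year: int) -> GridLayer:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"no layer for year {year}")
        return self.grid.layer(self.fractions[idx])

    def as_mapping(self) -> dict[int, GridLayer]:
        return {int(y): self.grid.layer(v) for y, v in zip(self.years, self.fractions)}

    def epoch_mean(self, window: tuple[int, int]) -> GridLayer:
        y0, y1 = window
        sel = (self.years >= y0) & (self.years <= y1)
        if not sel.any():
            raise ValueError(f"no years in window {window}")
        return self.grid.layer(self.fractions[sel].mean(axis=0))


def generate_forest_history(config: SyntheticConfig, grid: GridSpec | None = None) -> ForestHistory:
    """Baseline 1500 field plus a monotone deforestation ramp to 2000."""
    grid = grid or build_world_grid(config)
    shape = (grid.nrows, grid.ncols)

    base_field = _smooth_field(shape, config.forest_corr_length,
                               config.rng("forest"), grid.wraps_lon)
    f1500 = expit(logit(config.forest_mean) + config.forest_logit_sd * base_field).ravel()

    pressure = _smooth_field(shape, config.pressure_corr_length,
                             config.rng("pressure"), grid.wraps_lon).ravel()
    loss = config.deforest_intensity * expit(config.pressure_steepness * pressure)
    floor = config.forest_floor
    f2000 = floor + (f1500 - floor).clip(min=0.0) * (1.0 - loss)

    years = np.arange(config.year_start, config.year_end + 1)
    ramp = (years - config.year_start) / max(1, config.year_end - config.year_start)
    fractions = f1500[None, :] - ramp[:, None] * (f1500 - f2000)[None, :]
    fractions = fractions.clip(0.0, 1.0)
    fractions[:, ~grid.land_mask.ravel()] = np.nan
    return ForestHistory(grid=grid, years=years, fractions=fractions)


def _snap_fractions_to_sar(fraction: GridLayer, c: float, z: float) -> GridLayer:
    """Lower fractions so that c·A^z is exactly integer per cell: in the
    noise-free regime the world then lies exactly on the SAR."""
    grid = fraction.grid
    areas = fraction.values * grid.cell_areas
    s_real = c * np.where(areas > 0, areas, np.nan) ** z
    s_int = np.floor(s_real + 1e-9)
    a_snap = np.where(s_int > 0, (s_int / c) ** (1.0 / z), 0.0)
    frac = np.where(np.isfinite(s_real), a_snap / grid.cell_areas, fraction.values)
    return grid.layer(frac)


# --------------------------------------------------------------------------
# species generation

def _richness_targets(config: SyntheticConfig, areas: np.ndarray, rng) -> np.ndarray:
    """Per-cell target richness round(c·A^z·ε) with lognormal ε."""
    eps = np.ones_like(areas)
    if config.richness_sigma > 0:
        eps = np.exp(rng.normal(0.0, config.richness_sigma, size=areas.shape))
    with np.errstate(invalid="ignore"):
        s = config.sar_c * np.where(areas > 0, areas, 0.0) ** config.sar_z * eps
        s[areas <= 0] = 0.0
    return np.rint(np.where(np.isfinite(s), s, 0.0)).astype(np.int64)


def _nested_ranges(taxon: str, targets: np.ndarray, cell_ids: np.ndarray) -> list[SpeciesRecord]:
    """Species k occupies every cell with target richness >= k. Reproduces
    the targets exactly; ranges are contiguous wherever the richness field
    is spatially smooth."""
    records = []
    for k in range(1, int(targets.max(initial=0)) + 1):
        cells = cell_ids[targets >= k]
        records.append(SpeciesRecord(
            species_id=f"{taxon}_{k:05d}", taxon=taxon,
            habitats=frozenset({"forest", "terrestrial"}), cells=cells,
        ))
    return records


def _spreading_dye_ranges(
    config: SyntheticConfig, taxon: str, areas: np.ndarray,
    grid: GridSpec, rng,
) -> list[SpeciesRecord]:
    """Connected ranges grown from a seed cell, colonization weighted by
    1500s forest area, until a heavy-tailed target size is reached."""
    land_ids = grid.land_ids
    land = np.zeros(grid.n_cells, dtype=bool)
    land[land_ids] = True
    weights = np.zeros(grid.n_cells)
    weights[land_ids] = np.where(areas > 0, areas, 1e-9)
    p_seed = weights[land_ids] / weights[land_ids].sum()
    nbr = grid.neighbor_matrix()
    records = []
    for k in range(config.n_species):
        size = int(min(land_ids.size,
                       1 + rng.pareto(config.dye_pareto_shape) * config.dye_size_scale))
        start = int(rng.choice(land_ids, p=p_seed))
        occupied = {start}
        frontier = [int(j) for j in nbr[start] if j >= 0 and land[j]]
        while len(occupied) < size and frontier:
            w = weights[frontier]
            nxt = frontier.pop(int(rng.choice(len(frontier), p=w / w.sum())))
            if nxt in occupied:
                continue
            occupied.add(nxt)
            frontier.extend(int(j) for j in nbr[nxt]
                            if j >= 0 and land[j] and j not in occupied)
        records.append(SpeciesRecord(
            species_id=f"{taxon}_{k:05d}", taxon=taxon,
            habitats=frozenset({"forest", "terrestrial"}),
            cells=np.array(sorted(occupied), dtype=np.int64),
        ))
    return records


def _distractor_species(config: SyntheticConfig, grid: GridSpec,
                        n_forest: int, rng) -> list[SpeciesRecord]:
    """Non-forest species (filtered out downstream) to exercise the habitat
    filter on realistic mixed inputs."""
    n = int(round(config.nonforest_fraction * n_forest))
    tags = [frozenset({"marine"}), frozenset({"freshwater"}),
            frozenset({"terrestrial", "other"})]
    land_ids = grid.land_ids
    records = []
    for k in range(n):
        size = int(rng.integers(1, min(50, land_ids.size) + 1))
        cells = rng.choice(land_ids, size=size, replace=False)
        taxon = config.taxa[int(rng.integers(len(config.taxa)))]
        records.append(SpeciesRecord(
            species_id=f"{taxon}_nonforest_{k:04d}", taxon=taxon,
            habitats=tags[int(rng.integers(len(tags)))],
            cells=np.sort(cells),
        ))
    return records


def generate_species(
    config: SyntheticConfig,
    forest_1500: GridLayer,
    grid: GridSpec | None = None,
) -> list[SpeciesRecord]:
    """Species list planted on the 1500s forest layer (fractions)."""
    grid = grid or forest_1500.grid
    areas_full = np.where(np.isfinite(forest_1500.values),
                          forest_1500.values * grid.cell_areas, np.nan)
    if not np.isfinite(areas_full).any():
        raise ValueError("forest layer is entirely missing")
    land_ids = grid.land_ids
    areas = areas_full[land_ids]
    rng_rich = config.rng("richness")
    rng_ranges = config.rng("ranges")
    records: list[SpeciesRecord] = []
    for taxon in config.taxa:
        if config.range_mode == "direct-sar":
            targets = _richness_targets(config, areas, rng_rich)
            records.extend(_nested_ranges(taxon, targets, land_ids))
        else:
            if config.n_species < 1:
                raise ValueError("spreading-dye mode needs n_species >= 1")
            records.extend(_spreading_dye_ranges(config, taxon, areas, grid, rng_ranges))
    if not records:
        raise ValueError("no species generated (zero richness everywhere?)")
    records.extend(_distractor_species(config, grid, len(records), config.rng("distractors")))
    return records


def assign_iucn_categories(
    records: list[SpeciesRecord],
    probs: Sequence[float] | None = None,
    seed: int = 0,
    threat_size_link: float = 0.0,
) -> list[SpeciesRecord]:
    """Assign DD/LC/NT/VU/EN/CR in place-order, returning new records.

    With ``threat_size_link = 0`` each species draws its category
    independently from ``probs``. With link > 0, category *counts* are drawn
    multinomially and then dealt out by a noisy range-size ranking so that
    smaller-ranged species tend toward the threatened end.
    """
    probs = np.asarray(
        probs if probs is not None else (0.15, 0.55, 0.10, 0.10, 0.07, 0.03),
        dtype=float,
    )
    if probs.size != 6 or np.any(probs < 0):
        raise ValueError("probs must be 6 non-negative values")
    if abs(probs.sum() - 1.0) > 1e-12:
        raise ValueError("probs must sum to 1")
    if not 0.0 <= threat_size_link <= 1.0:
        raise ValueError("threat_size_link must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(records)
    if threat_size_link == 0.0:
        cats = rng.choice(len(IUCN_ASSIGNABLE), size=n, p=probs)
        labels = [IUCN_ASSIGNABLE[c] for c in cats]
    else:
        counts = rng.multinomial(n, probs)
        sizes = np.array([r.range_size for r in records], dtype=float)
        ranks = sizes.argsort().argsort() / max(1, n - 1)
        score = (1 - threat_size_link) * rng.random(n) + threat_size_link * ranks
        order = np.argsort(score)  # smallest score = most threatened
        labels = [""] * n
        threat_order = ("CR", "EN", "VU", "NT", "LC", "DD")
        pos = 0
        for cat in threat_order:
            c = counts[IUCN_ASSIGNABLE.index(cat)]
            for i in order[pos:pos + c]:
                labels[int(i)] = cat
            pos += c
    return [replace(r, iucn_category=lab) for r, lab in zip(records, labels)]


# --------------------------------------------------------------------------
# the full world

@dataclass
class SyntheticWorld:
    config: SyntheticConfig
    grid: GridSpec
    history: ForestHistory
    fraction_1500s: GridLayer    # epoch-mean fractions (snapped when σ = 0)
    fraction_2000s: GridLayer
    species: list
    richness_targets: dict       # taxon -> GridLayer of planted richness
    truth: dict                  # c_true, z_true, planted per-taxon debt


def generate_world(config: SyntheticConfig = SyntheticConfig()) -> SyntheticWorld:
    """Build the complete synthetic world: grid, forest history, epoch
    layers, species with IUCN categories, and the planted truth record."""
    grid = build_world_grid(config)
    history = generate_forest_history(config, grid)
    f1500s = history.epoch_mean(config.epoch_1500s)
    f2000s = history.epoch_mean(config.epoch_2000s)

    snap = config.richness_sigma == 0 and config.range_mode == "direct-sar"
    if snap:
        f1500s = _snap_fractions_to_sar(f1500s, config.sar_c, config.sar_z)

    species = generate_species(config, f1500s, grid)
    species = assign_iucn_categories(
        species,
        probs=config.iucn_probs,
        seed=int(np.random.SeedSequence([int(config.seed), _STAGE_KEYS["iucn"]]).generate_state(1)[0] % (2**31)),
        threat_size_link=config.threat_size_link,
    )

    # planted richness and debt truth (forest-dwelling species only)
    land_ids = grid.land_ids
    richness = {}
    for taxon in config.taxa:
        counts = np.zeros(grid.n_cells)
        for rec in species:
            if rec.taxon == taxon and {"forest", "terrestrial"} <= rec.habitats:
                counts[rec.cells] += 1
        richness[taxon] = grid.layer(counts)

    a1500 = f1500s.values * grid.cell_areas
    a2000 = f2000s.values * grid.cell_areas
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a1500 > 0, a2000 / a1500, np.nan)
    planted_debt = {
        taxon: grid.layer(richness[taxon].values * (1.0 - ratio**config.sar_z))
        for taxon in config.taxa
    }
    truth = {"c_true": config.sar_c, "z_true": config.sar_z, "planted_debt": planted_debt}
    return SyntheticWorld(config, grid, history, f1500s, f2000s,
                          species, richness, truth)
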