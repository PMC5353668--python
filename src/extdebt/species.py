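"""Species records: habitat filtering and richness rasterization.

A species record carries a taxon label, a set of habitat tags, an IUCN Red
List category and the set of grid cells its range occupies. Analyses keep
only terrestrial forest-dwelling species, and count species per cell into
per-taxon richness maps, excluding species already extinct (EX) or extinct
in the wild (EW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import GridLayer, GridSpec

IUCN_CATEGORIES = ("DD", "LC", "NT", "VU", "EN", "CR", "EX", "EW")
HABITAT_VOCABULARY = frozenset({"forest", "terrestrial", "marine", "freshwater", "other"})

__all__ = [
    "IUCN_CATEGORIES",
    "HABITAT_VOCABULARY",
    "SpeciesRecord",
    "filter_forest_terrestrial",
    "rasterize_richness",
]


@dataclass
class SpeciesRecord:
    species_id: str
    taxon: str  # reptile | mammal | amphibian
    habitats: frozenset = field(default_factory=lambda: frozenset({"forest", "terrestrial"}))
    iucn_category: str = "LC"
    cells: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self):
        self.habitats = frozenset(self.habitats)
        self.cells = np.unique(np.asarray(self.cells, dtype=np.int64))
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {self.iucn_category!r}")

    @property
    def range_size(self) -> int:
        return int(self.cells.size)


def filter_forest_terrestrial(records: list[SpeciesRecord]) -> list[SpeciesRecord]:
    """Keep terrestrial forest-dwelling species, preserving input order.

    Records tagged only marine/freshwater/other are dropped; records with
    habitat tags outside the controlled vocabulary are dropped with a
    warning rather than silently kept.
    """
    kept = []
    for rec in records:
        unknown = rec.habitats - HABITAT_VOCABULARY
        if unknown:
            warnings.warn(
                f"species {rec.species_id}: unknown habitat tags {sorted(unknown)}; "
                "record dropped",
                stacklevel=2,
            )
            continue
        if {"forest", "terrestrial"} <= rec.habitats:
            kept.append(rec)
    return kept


def rasterize_richness(
    records: list[SpeciesRecord],
    grid: GridSpec,
    exclude: frozenset = frozenset({"EX", "EW"}),
    taxa: list[str] | None = None,
) -> dict[str, GridLayer]:
    """Per-taxon species counts per cell.

    count(i) = number of non-excluded records whose occupied set contains i.
    Cells outside the grid raise; off-land occupied cells raise too, since a
    range cannot occupy ocean under the grid's land mask. ``taxa`` forces
    all-zero maps for taxa with no records.
    """
    land = np.zeros(grid.n_cells, dtype=bool)
    land[grid.land_ids] = True
    taxa = sorted({rec.taxon for rec in records} | set(taxa or ()))
    counts = {t: np.zeros(grid.n_cells, dtype=float) for t in taxa}
    for rec in records:
        if rec.iucn_category in exclude:
            continue
        if rec.cells.size:
            if rec.cells.min() < 0 or rec.cells.max() >= grid.n_cells:
                raise ValueError(f"species {rec.species_id}: cell id outside grid")
            if not land[rec.cells].all():
                raise ValueError(f"species {rec.species_id}: occupied cell off land")
            counts[rec.taxon][rec.cells] += 1.0
    return {t: grid.layer(v) for t, v in counts.items()}
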