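"""IUCN-probability risk maps, top-decile hotspots and conservation gaps.

Each Red List category carries an extinction probability (DD 0.0001,
LC 0.001, NT 0.01, VU 0.1, EN 0.667, CR 0.999); a cell's risk is the sum of
the probabilities of the species occurring there. Hotspots of richness,
risk and debt are the cells at or above the 90th percentile of the map, and
the conservation gap is the part of the debt hotspot covered by neither the
richness nor the risk hotspot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import GridLayer, GridSpec
from .species import SpeciesRecord

#: Extinction probability per IUCN category (EX/EW are excluded upstream).
DEFAULT_EXTINCTION_PROBS = {
    "DD": 0.0001,
    "LC": 0.001,
    "NT": 0.01,
    "VU": 0.1,
    "EN": 0.667,
    "CR": 0.999,
}

__all__ = [
    "DEFAULT_EXTINCTION_PROBS",
    "HotspotSet",
    "OverlapReport",
    "extinction_risk",
    "top_decile_hotspots",
    "overlap_report",
]


def extinction_risk(
    records: list[SpeciesRecord],
    grid: GridSpec,
    probs: dict[str, float] = DEFAULT_EXTINCTION_PROBS,
) -> GridLayer:
    """risk(i) = Σ over species occupying i of prob(category)."""
    risk = np.zeros(grid.n_cells)
    for rec in records:
        if rec.iucn_category not in probs:
            raise KeyError(
                f"species {rec.species_id}: category {rec.iucn_category!r} has no "
                "extinction probability (EX/EW must be excluded upstream)"
            )
        if rec.cells.size:
            if rec.cells.min() < 0 or rec.cells.max() >= grid.n_cells:
                raise ValueError(f"species {rec.species_id}: cell id outside grid")
            risk[rec.cells] += probs[rec.iucn_category]
    return grid.layer(risk)


@dataclass
class HotspotSet:
    criterion: str  # richness | risk | debt (free label)
    threshold: float
    members: np.ndarray  # sorted cell ids
    n_valid: int
    degenerate: bool = False

    def __post_init__(self):
        self.members = np.unique(np.asarray(self.members, dtype=np.int64))

    @property
    def member_set(self) -> set:
        return set(self.members.tolist())


def top_decile_hotspots(layer: GridLayer, criterion: str, decile: float = 0.9) -> HotspotSet:
    """Cells at or above the ``decile`` quantile (linear interpolation) of
    the valid (non-missing) cells; ties at the threshold are kept.

    A constant layer has no meaningful top decile: flagged degenerate and an
    empty set returned with a warning.
    """
    if not 0 < decile < 1:
        raise ValueError("decile must lie in (0, 1)")
    values = layer.values
    valid = np.flatnonzero(np.isfinite(values))
    if valid.size < 10:
        raise ValueError("need at least 10 valid cells")
    v = values[valid]
    if np.ptp(v) == 0:
        warnings.warn(f"{criterion}: constant layer, hotspot set undefined", stacklevel=2)
        return HotspotSet(criterion, float(v[0]), np.empty(0, np.int64),
                          valid.size, degenerate=True)
    thr = float(np.quantile(v, decile))
    members = valid[v >= thr]
    return HotspotSet(criterion, thr, members, valid.size)


@dataclass
class OverlapReport:
    jaccard: dict          # frozenset({label_a, label_b}) -> Jaccard index
    coverage_fraction: float  # share of debt hotspot inside richness ∪ risk
    gap_fraction: float       # 1 − coverage
    gap_cells: np.ndarray     # debt hotspot cells covered by neither


def _jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def overlap_report(
    debt_hs: HotspotSet,
    richness_hs: HotspotSet,
    risk_hs: HotspotSet,
) -> OverlapReport:
    """Pairwise Jaccard overlap and the debt-relative conservation gap."""
    sets = {"debt": debt_hs.member_set,
            "richness": richness_hs.member_set,
            "risk": risk_hs.member_set}
    jac = {}
    labels = list(sets)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            jac[frozenset({a, b})] = _jaccard(sets[a], sets[b])
    covered = sets["debt"] & (sets["richness"] | sets["risk"])
    gap = sets["debt"] - (sets["richness"] | sets["risk"])
    n_debt = len(sets["debt"])
    coverage = len(covered) / n_debt if n_debt else 0.0
    return OverlapReport(
        jaccard=jac,
        coverage_fraction=coverage,
        gap_fraction=1.0 - coverage if n_debt else 1.0,
        gap_cells=np.array(sorted(gap), dtype=np.int64),
    )
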