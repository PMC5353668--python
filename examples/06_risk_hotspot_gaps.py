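"""IUCN-probability risk maps, top-decile hotspots and conservation gaps.

Each Red List category carries an extinction probability (CR 0.999,
EN 0.667, VU 0.1, NT 0.01, LC 0.001, DD 0.0001); cell risk is the sum over
resident species. The conservation gap is the part of the debt hotspot not
covered by the richness or risk hotspots.
"""
import extdebt as ed

world = ed.generate_world(ed.SyntheticConfig(seed=42, resolution=8.0))
grid = world.grid
kept = [r for r in ed.filter_forest_terrestrial(world.species)
        if r.taxon == "mammal"]
richness = ed.rasterize_richness(kept, grid)["mammal"]
risk = ed.extinction_risk(kept, grid)
a1500 = grid.layer(world.fraction_1500s.values * grid.cell_areas)
a2000 = grid.layer(world.fraction_2000s.values * grid.cell_areas)
debt = ed.extinction_debt(
    richness, ed.equilibrium_richness(richness, a1500, a2000, z=0.25))

hs = {
    "richness": ed.top_decile_hotspots(richness, "richness"),
    "risk": ed.top_decile_hotspots(risk, "risk"),
    "debt": ed.top_decile_hotspots(debt, "debt"),
}
for crit, h in hs.items():
    print(f"{crit:<9} hotspot: {h.members.size} cells at or above "
          f"threshold {h.threshold:.2f}")
rep = ed.overlap_report(hs["debt"], hs["richness"], hs["risk"])
for pair, j in sorted(rep.jaccard.items(), key=lambda kv: sorted(kv[0])):
    print(f"Jaccard({' vs '.join(sorted(pair))}) = {j:.3f}")
print(f"debt hotspot covered by richness/risk hotspots: "
      f"{rep.coverage_fraction:.1%}; conservation gap: {rep.gap_fraction:.1%} "
      f"({rep.gap_cells.size} cells)")
# A large gap fraction is the headline conservation message: the places
# committed to future losses are mostly not today's richness or risk
# hotspots.
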