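"""End-to-end analysis: synthetic world → evidence tables → debt maps →
conservation-gap report.

``run_analysis`` chains every stage from a single config and returns an
AnalysisReport whose tables mirror the analysis surface: a per-taxon
correlation table (8 predictors × 3 tests, Bonferroni-adjusted, plus a
permutation null), a variable-importance table (4 metrics × 8 predictors
with bootstrap intervals), SAR fits and debt maps under each z variant,
IUCN-probability risk maps, and top-decile hotspot overlap reports.
The whole pipeline is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (CorrelationResult, bonferroni, modified_ttest,
                          partial_correlation, randomization_test,
                          semipartial_correlation)
from .grid import GridLayer, distance_matrix
from .hotspots import (DEFAULT_EXTINCTION_PROBS, extinction_risk,
                       overlap_report, top_decile_hotspots)
from .importance import bootstrap_importance
from .io import write_layer_csv
from .metrics import PREDICTOR_NAMES, MetricConfig, compute_metric_set
from .sar import DebtConfig, compute_debt_maps
from .species import filter_forest_terrestrial, rasterize_richness
from .synthetic import SyntheticConfig, generate_world

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "write_report"]


@dataclass(frozen=True)
class AnalysisConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    debt: DebtConfig = field(default_factory=DebtConfig)
    nclass: int = 13               # distance classes of the spatial test
    bonferroni_m: int = 8          # family = predictors per taxon per test
    n_permutations: int = 999      # randomization null
    n_bootstrap: int = 1000        # importance bootstrap iterations
    hotspot_decile: float = 0.9
    extinction_probs: tuple = tuple(sorted(DEFAULT_EXTINCTION_PROBS.items()))
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    correlations: pd.DataFrame     # taxon, predictor, method, r, df, p, p_bonferroni
    randomization: pd.DataFrame    # taxon, predictor, r_observed, p_perm
    importance: pd.DataFrame       # taxon, predictor, metric, value, ci_low, ci_high
    sar_fits: dict                 # taxon -> SARFit
    richness: dict                 # taxon -> GridLayer
    risk: dict                     # taxon -> GridLayer
    debt_maps: dict                # taxon -> {z_label -> DebtMap}
    hotspot_sets: dict             # taxon -> {criterion -> HotspotSet}
    overlaps: dict                 # taxon -> OverlapReport
    metric_table: pd.DataFrame
    provenance: dict


def _derived_seed(master: int, *keys: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_analysis(config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    stage_log: list[dict] = []

    def stage(name):
        stage_log.append({"stage": name, "start": time.perf_counter()})
        return name

    def done():
        s = stage_log[-1]
        s["seconds"] = round(time.perf_counter() - s.pop("start"), 3)

    try:
        stage("generate")
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        world = generate_world(syn)
        grid = world.grid
        done()

        stage("rasterize")
        kept = filter_forest_terrestrial(world.species)
        richness = rasterize_richness(kept, grid)
        done()

        stage("metrics")
        dmat = distance_matrix(grid)
        mset = compute_metric_set(world.fraction_1500s, world.fraction_2000s,
                                  dmat, config.metric)
        mtable = mset.table()
        done()

        stage("correlations")
        ids = grid.land_ids
        coords = np.column_stack([grid.centroid_lat[ids], grid.centroid_lon[ids]])
        X = {name: mset.layers[name].values[ids] for name in PREDICTOR_NAMES}
        corr_rows, rand_rows = [], []
        for t_i, taxon in enumerate(sorted(richness)):
            y = richness[taxon].values[ids]
            for p_i, name in enumerate(PREDICTOR_NAMES):
                x = X[name]
                Z = np.column_stack([X[o] for o in PREDICTOR_NAMES if o != name])
                results = []
                for method, call in (
                    ("spatial", lambda: modified_ttest(x, y, coords,
                                                       nclass=config.nclass,
                                                       predictor=name)),
                    ("semipartial", lambda: semipartial_correlation(y, x, Z,
                                                                    predictor=name)),
                    ("partial", lambda: partial_correlation(y, x, Z,
                                                            predictor=name)),
                ):
                    try:
                        results.append(call())
                    except (ValueError, np.linalg.LinAlgError):
                        # aliased or degenerate predictors (e.g. a world with
                        # no forest change duplicates the two epochs): keep
                        # the table surface, flag the cell non-evaluable
                        results.append(CorrelationResult(
                            method, np.nan, np.nan, np.nan, np.nan, y.size,
                            predictor=name, evaluable=False))
                for res in results:
                    corr_rows.append({
                        "taxon": taxon, "predictor": name, "method": res.method,
                        "r": res.r, "df": res.df, "t": res.t, "p": res.p,
                        "n": res.n, "ess": res.ess, "evaluable": res.evaluable,
                    })
                rand = randomization_test(
                    y, x, config.n_permutations,
                    seed=_derived_seed(config.seed, 100 + t_i, p_i),
                )
                rand_rows.append({
                    "taxon": taxon, "predictor": name,
                    "r_observed": rand.r_observed, "p_perm": rand.p,
                    "n_permutations": rand.n_permutations,
                })
        correlations = pd.DataFrame(corr_rows)
        correlations["p_bonferroni"] = np.nan
        for (taxon, method), idx in correlations.groupby(["taxon", "method"]).groups.items():
            correlations.loc[idx, "p_bonferroni"] = bonferroni(
                correlations.loc[idx, "p"].to_numpy(), config.bonferroni_m)
        randomization = pd.DataFrame(rand_rows)
        done()

        stage("importance")
        Xmat = np.column_stack([X[name] for name in PREDICTOR_NAMES])
        imp_rows = []
        importance_r2 = {}
        for t_i, taxon in enumerate(sorted(richness)):
            y = richness[taxon].values[ids]
            try:
                res = bootstrap_importance(
                    Xmat, y, n_bootstrap=config.n_bootstrap,
                    seed=_derived_seed(config.seed, 200 + t_i),
                    names=list(PREDICTOR_NAMES),
                )
                importance_r2[taxon] = res.r_squared
                tab = res.table()
            except (ValueError, np.linalg.LinAlgError):
                importance_r2[taxon] = np.nan
                tab = pd.DataFrame([
                    {"predictor": name, "metric": m, "value": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan}
                    for m in ("lmg", "last", "first", "genizi")
                    for name in PREDICTOR_NAMES
                ])
            tab.insert(0, "taxon", taxon)
            imp_rows.append(tab)
        importance = pd.concat(imp_rows, ignore_index=True)
        done()

        stage("sar_debt")
        a1500 = mset.layers["Areas1500"]
        a2000 = mset.layers["Areas2000"]
        sar_fits, debt_maps = {}, {}
        for taxon in sorted(richness):
            maps, fit = compute_debt_maps(richness[taxon], a1500, a2000, config.debt)
            debt_maps[taxon] = maps
            sar_fits[taxon] = fit
        done()

        stage("risk_hotspots")
        probs = dict(config.extinction_probs)
        risk, hotspot_sets, overlaps = {}, {}, {}
        primary_z = f"z={config.debt.z_values[0]:g}" if config.debt.z_values else "z=fitted"
        for taxon in sorted(richness):
            recs = [r for r in kept if r.taxon == taxon]
            risk[taxon] = extinction_risk(recs, grid, probs)
            hs = {
                "richness": top_decile_hotspots(richness[taxon], "richness",
                                                config.hotspot_decile),
                "risk": top_decile_hotspots(risk[taxon], "risk", config.hotspot_decile),
                "debt": top_decile_hotspots(debt_maps[taxon][primary_z].debt, "debt",
                                            config.hotspot_decile),
            }
            hotspot_sets[taxon] = hs
            overlaps[taxon] = overlap_report(hs["debt"], hs["richness"], hs["risk"])
        done()
    except Exception as exc:
        failed = stage_log[-1]["stage"] if stage_log else "setup"
        raise RuntimeError(f"pipeline stage '{failed}' failed: {exc}") from exc

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "stages": stage_log,
        "n_land_cells": int(grid.n_land),
        "n_species": len(world.species),
        "importance_r_squared": importance_r2,
    }
    return AnalysisReport(config, correlations, randomization, importance,
                          sar_fits, richness, risk, debt_maps, hotspot_sets,
                          overlaps, mtable, provenance)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(report: AnalysisReport, outdir) -> dict:
    """Write all report artifacts under ``outdir``; returns the manifest
    (file → sha256), also saved as manifest.json."""
    if report.correlations is None or report.correlations.empty:
        raise ValueError("report is empty")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    save_df(report.correlations, "correlations.csv")
    save_df(report.randomization, "randomization.csv")
    save_df(report.importance, "importance.csv")
    save_df(report.metric_table, "metrics.csv")

    fits = {
        taxon: (dataclasses.asdict(fit) if fit is not None else None)
        for taxon, fit in report.sar_fits.items()
    }
    (out / "sar_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    written.append(out / "sar_fits.json")

    layers = out / "layers"
    layers.mkdir(exist_ok=True)
    for taxon in sorted(report.richness):
        for label, layer in (("richness", report.richness[taxon]),
                             ("risk", report.risk[taxon])):
            path = layers / f"{label}_{taxon}.csv"
            write_layer_csv(layer, path)
            written.append(path)
        for z_label, dmap in report.debt_maps[taxon].items():
            path = layers / f"debt_{taxon}_{z_label.replace('=', '')}.csv"
            write_layer_csv(dmap.debt, path)
            written.append(path)

    overlap_payload = {}
    for taxon, rep in report.overlaps.items():
        overlap_payload[taxon] = {
            "jaccard": {"-".join(sorted(k)): v for k, v in rep.jaccard.items()},
            "coverage_fraction": rep.coverage_fraction,
            "gap_fraction": rep.gap_fraction,
            "gap_cells": rep.gap_cells.tolist(),
            "hotspots": {
                crit: {
                    "threshold": hs.threshold,
                    "n_members": int(hs.members.size),
                    "members": hs.members.tolist(),
                    "degenerate": hs.degenerate,
                }
                for crit, hs in report.hotspot_sets[taxon].items()
            },
        }
    (out / "hotspots.json").write_text(json.dumps(overlap_payload, indent=2, sort_keys=True))
    written.append(out / "hotspots.json")

    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True, default=str))
    written.append(out / "provenance.json")

    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(written)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
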