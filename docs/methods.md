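# Methods

This note documents the models implemented in `extdebt`, the assumptions
they carry, the defaults and why, and what the synthetic worlds do and do
not establish about real data.

## Grid geometry

All layers live on a regular latitude/longitude grid, cells indexed
row-major from the north-west corner. Cell areas use the spherical-zone
formula A = R²·Δλ·(sin φ_top − sin φ_bottom) with R = 6371.0088 km (the
IUGG mean radius; area totals close to 4πR² to ~1e-16 relative).
Distances are centroid-to-centroid haversine great circles. Von Neumann
adjacency wraps in longitude on full-width grids and clamps in latitude, so
polar-row cells have three neighbors; ocean is expressed purely through the
land mask, and any computation touching a masked cell yields missing (NaN),
never zero — "no land" and "no forest" are different facts.

## Fragmentation predictors

For each epoch t ∈ {1500s, 2000s} and cell i:

* `Areas_t(i)` = forest fraction × spherical cell area (km²);
* `IFM_t(i)` = Σ_{j≠i} exp(−α·d_ij)·A_t(j) — the incidence-function
  connectivity of metapopulation theory, indexing colonization potential;
* `Prox_t(i)` = Σ_{j≠i, d_ij≤h} A_t(j)/d²_ij — inverse-square proximity;
  low values flag fragmentation;
* `Conc_t(i)` = Σ over the focal cell and its von Neumann neighbors of
  A_t(j); absent or masked neighbors contribute zero.

Defaults: α = 0.001 km⁻¹ (e-folding 1000 km, about nine 1° cells at the
equator — a scale at which between-cell colonization is plausible for
vertebrates), proximity radius h unlimited, no distance cutoff. Both α and
h are free parameters of the index family rather than quantities with a
canonical value; correlations downstream are invariant to the km² unit
choice because every index is linear in the area field. IFM and Prox
exclude the focal cell (they describe the *surrounding* landscape);
concentration includes it (it describes total locally available habitat).

## The debt signal and its statistics

The operational definition of extinction-debt evidence: contemporary
richness correlates more strongly with past than with present forest
structure. Three tests are run per predictor and taxon:

* **Spatially adjusted correlation.** Both richness and forest layers are
  smooth fields, so the naive Pearson test wildly overstates the
  information content of n cells. The effective sample size follows the
  Clifford–Richardson–Hémon product-of-autocorrelations estimator:
  pairwise distances are binned into `nclass = 13` equal-width classes, the
  distance-class autocorrelations ρ̂_x(k), ρ̂_y(k) are computed with the
  global mean and the biased (1/n) variance, and

      M̂ = 1 + n² / ( n + 2·Σ_k N_k·ρ̂_x(k)·ρ̂_y(k) ),

  with N_k the upper-triangle pair count of class k. The t statistic uses
  df = M̂ − 2. On iid fields M̂ ≈ n (simulation: mean within 1% at
  n = 500) and the test is calibrated (type-I ≈ 0.05); under shared smooth
  structure M̂ collapses (measured M̂ ≈ 11 for n = 1000 strongly
  autocorrelated cells) and spurious significance disappears. If the
  denominator estimate is non-positive or M̂ ≤ 2 the result is flagged
  non-evaluable rather than reported.
* **Semi-partial correlation**: Pearson correlation of richness with the
  residual of the focal predictor on the other seven (with intercept);
  **partial correlation** residualizes both sides. Classical t reference
  on df = n − |Z| − 2; no spatial adjustment is applied to these two, so
  their p-values are anticonservative under autocorrelation and are read
  comparatively, not absolutely.
* **Bonferroni** with family size m = 8 (the predictors tested per taxon
  per method) and a **permutation null** (richness permuted across cells,
  predictors fixed, two-sided p = (1 + #{|r*| ≥ |r|})/(B + 1), default
  B = 999). The permutation destroys the spatial structure of richness, so
  like the naive tests it is generous to the alternative; it is reported
  alongside, not combined with, the parametric p.

Aliased predictors (e.g. a world with zero forest change, where the two
epochs coincide) make the control matrix rank deficient; the pipeline
records those table cells as non-evaluable instead of aborting, keeping the
8 × 3 table surface intact.

## R² decomposition

With up to 15 predictors the engine enumerates all 2^p subset R² values
from moment (correlation) matrices — one covariance per (re)sample plus
2^p small solves — which makes the 10,000-iteration default bootstrap
affordable. Metrics: `first_k` = R²({k}); `last_k` = R²(full) −
R²(full∖{k}); `lmg_k` = Shapley value of predictor k over orderings,
computed with the combinatorial weights |S|!(p−|S|−1)!/p! and verified
against explicit enumeration of all p! orderings for p ≤ 5 (≤ 1e-12);
`genizi_k` = ((R_xx^{1/2}·β)_k)² with standardized coefficients β and the
symmetric positive-definite square root. lmg and genizi sum exactly to the
full-model R²; in centered-orthogonal designs all four coincide. Predictors
enter untransformed: every metric is invariant to affine rescaling of any
column. Bootstrap intervals are percentile 95% over case resamples;
rank-deficient resamples are skipped and counted. The library default is
10,000 iterations; the bundled pipeline config and test suite use smaller
B (the intervals at the problem sizes involved stabilize well below 1,000).

## SAR-based debt

Assuming the historical richness pattern was at equilibrium with the
1500s forest area, and that present richness still approximates it (the
debt not yet paid), the power SAR S = c·A^z gives

    S_eq(i) = S_obs(i)·(A₂₀₀₀(i)/A₁₅₀₀(i))^z,
    Debt(i) = S_obs(i) − S_eq(i).

Negative debts (forest gain) are retained as species/immigration credits.
z is either fixed — 0.25 by convention, 0.1 and 0.15 because SAR
extrapolation tends to overestimate extinctions — or fitted per taxon as
the slope of ln S on ln A₁₅₀₀ (natural logs; the slope is base-invariant
and c = exp(intercept)). One global fit per taxon is used. Cells with
S_obs = 0 or A₁₅₀₀ ≤ 0 are excluded from fitting; cells with A₁₅₀₀ = 0 are
masked in debt maps (0/0 is undefined, not zero debt).

Under loss (ratio < 1) debt is cellwise increasing in z, so the
z = 0.1/0.15/0.25 maps are ordered within every cell. Note that this does
*not* make the between-cell ranking identical across z: the debt ratio of
two cells, (1−ρ_B^z)/(1−ρ_A^z), depends on z, so isolated rank swaps occur
wherever a richness contrast nearly offsets a retention-ratio contrast.
Measured across synthetic worlds the between-map Spearman correlation is
≈ 0.9999 — "z changes magnitude, not arrangement" is an excellent
approximation, not an identity.

## Risk maps, hotspots, gaps

Cell risk is the sum of per-species extinction probabilities by Red List
category (DD 0.0001, LC 0.001, NT 0.01, VU 0.1, EN 0.667, CR 0.999);
species marked EX/EW are excluded upstream (they are no longer "at risk"
and already absent from richness). Hotspots are the cells at or above the
90th percentile (linear-interpolation quantile) of the valid cells of a
map, ties included; constant maps are flagged degenerate. The overlap
report gives pairwise Jaccard indices and the debt-relative gap: the
fraction of the debt hotspot covered by neither the richness nor the risk
hotspot — the direction that matters for spotting overlooked areas.

## Synthetic worlds

The generator emulates the statistical structure the analysis relies on,
with known truth, not real biogeography:

* **Forest baseline**: logit-normal transform of a Gaussian random field
  (white noise smoothed with a Gaussian kernel; correlation length 5 cells,
  mean fraction 0.45, logit sd 1.5). The smoothing construction is the
  simplest field with controllable autocorrelation.
* **Deforestation**: cumulative loss = intensity × logistic(pressure),
  pressure being an independent smooth field (correlation length 8 cells);
  default intensity 0.5 — a strong but not total 500-year loss — applied
  along a linear annual ramp 1500 → 2000, so fractions stay in [0, 1] and
  are per-cell non-increasing. The real reconstruction of historical land
  use is a recursive reallocation procedure whose specifics are not
  reproduced; only autocorrelation and epoch-to-epoch loss matter to the
  statistics tested here.
* **Richness truth**: S(i) = round(c·A₁₅₀₀(i)^z·ε), c = 10, z = 0.25,
  ε lognormal with log-sd σ = 0.2. When σ = 0 the 1500s epoch fractions
  are snapped *down* so that c·A^z is exactly integer: "noise-free" then
  means the integer richness sits exactly on the SAR, which is what makes
  exact (1e-8) end-to-end recovery of z a meaningful test.
* **Ranges**: default allocation is nested threshold sets — species k
  occupies every cell whose target richness ≥ k — which reproduces the
  per-cell targets exactly, deterministically, and yields contiguous
  ranges wherever the richness field is smooth; the downstream mathematics
  depends only on the per-cell counts, not range shapes. A spreading-dye
  mode grows genuinely random connected ranges (seed cell ∝ forest area,
  colonization weighted by forest area, heavy-tailed Pareto size draw) for
  tests that need range geometry.
* **Categories**: one multinomial draw per species (defaults DD 0.15,
  LC 0.55, NT 0.10, VU 0.10, EN 0.07, CR 0.03 — a Red-List-like mix); an
  optional knob links threat to small range size. Distractor species with
  marine/freshwater/other habitat tags (5%) exercise the habitat filter.
* **Reproducibility**: everything derives from one seed through named
  per-stage substreams, so regenerating one stage leaves the others'
  draws untouched.

Default world: a 4°-resolution band from 64°S to 64°N with a smooth random
land mask covering 70% of cells (~2000 land cells) — large enough for the
spatial statistics, small enough that a full pipeline run takes seconds.

What passing tests on these worlds show: the estimators recover planted
parameters, the spatial adjustment is calibrated, the decompositions are
exact, and the pipeline is deterministic. What they do not show: anything
about the quality of real range maps or land-use reconstructions, the
validity of the equilibrium-SAR assumptions on real landscapes, relaxation
times (not modeled), or realistic biogeographic structure (climate,
range shifts, land-use classes beyond forest fraction).

## Numerical choices and degenerate inputs

Pairwise deletion of missing cells in all correlation tests; variables
constant after deletion raise. Residualization uses least squares with an
intercept; a focal variable inside the span of its controls raises (its
semi-partial correlation is undefined). The importance engine refuses more
than 15 predictors (2^p enumeration) and rank-deficient full models.
Quantile thresholds use linear interpolation; hotspot ties at the threshold
are kept, so a hotspot can exceed 10% of cells but never undershoots it on
continuous maps. Integer overflow is avoided by carrying all per-cell
counts as floats. Test-suite and example problem sizes (coarser grids,
smaller bootstrap/permutation counts) are chosen so the whole suite runs in
a few minutes on one core; every scale-sensitive claim is tested at the
sizes stated in the test docstrings.
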