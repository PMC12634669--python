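# Methods

This note records the models, parameter choices and numerical conventions
behind `agbstack`, and what the synthetic benchmark does and does not
demonstrate about real inventory data.

## Diameter back-casting

**Model.** Growth is treated as linear in time with a constant annual
increment per (plot, species, DBH class) group; classes partition (5, ∞) cm
as (5,10], (10,15], (15,20], (20,∞). The "growth rate" is an *absolute*
increment (cm·yr⁻¹): group rates are subtracted from later-cycle diameters,
which is only dimensionally coherent for an increment. A relative
(multiplicative) mode is exposed via `rate_mode="relative"` for sensitivity
analysis but is not the default.

**Annualisation.** Elapsed time is the calendar-year difference of the two
surveys (4–6 years depending on the revisit year of each plot). A fixed
5-year span would bias plots revisited after 4 or 6 years.

**Grouping of entered trees.** An entered tree's first-cycle class
(< 5 cm) does not exist in the grouping, so its later-cycle class —
normally (5,10] — indexes the rate table. Hold-out preserved trees use the
class of their measured first-cycle DBH, which is known for them.

**Fallbacks.** Group resolution proceeds (plot, species, class) →
(plot, class) → (species, class) → (class), most local information first,
with a final global mean for classes never observed in training. The depth
used is recorded per tree.

**Splitting.** The 80/20 train/hold-out split of preserved trees is random
by tree and stratified by (species, class) where the stratum holds at least
two trees; singleton strata train. Negative individual rates (shrinkage or
measurement error) are flagged but retained in group means — trimming would
bias the means downward.

**Clamping.** Back-cast estimates below 0.1 cm are floored at 0.1 cm and
flagged (the allometric power law requires D > 0); estimates ≥ 5 cm are kept
and flagged `over_threshold` so analysts can exclude suspected boundary or
recording errors.

## Allometry

Per stem, `AGB = 0.3·ρ·D^(7/3)` with ρ in g·cm⁻³ and D in cm, yielding
kilograms per tree; plot totals are divided by 1000 and by the plot area
(default 0.0667 ha, the 25.82 m square) to give Mg·ha⁻¹. The kg-per-tree
unit convention is fixed by checking that realistic stand tables produce
plot AGB in the tens-to-hundreds Mg·ha⁻¹ range. The bundled wood-density
table is shipped verbatim, including one conspicuously low value
(*Robinia pseudoacacia*, 0.0674 g·cm⁻³, likely a misprint of 0.674); a
constructor override lets users correct it without editing the shipped
file. Species lookup is case-insensitive exact matching on a normalised
code — fuzzy matching invites silent errors — with group fallbacks
(other pines 0.45, other hardwood broadleaves 0.625, other softwood
broadleaves 0.443).

## Raster features

Vegetation indices are computed exactly as their published band formulas,
including two red-edge chlorophyll indices whose band roles are swapped
relative to common literature usage (Chlrededge = B9/B5 − 1,
CIrededge = B5/B7); fidelity to the printed formula wins over convention.
Division by zero yields nodata at that pixel, and nodata propagates through
every derived layer.

Terrain derivatives use the standard defaults of major GIS tools: Horn's
3×3 method for slope and aspect (degrees clockwise from north; flat cells
report 0, and an optional cos/sin encoding exists for modelling),
Zevenbergen–Thorne curvature, roughness as the 3×3 max−min including the
centre, TPI as centre minus the mean of its 8 neighbours. TWI is
`ln(Ac/tan(slope))` with Ac from D8 flow accumulation (steepest-descent
routing, each cell contributing its own area) times cell area, and slope
floored at 0.001 rad so flats stay finite. Border cells use shrunken
windows and can be flagged via `border_mask`.

Plot aggregation takes the mean of pixels whose *centres* fall inside the
footprint — deterministic and resolution-robust for ~26-m plots on a 10-m
grid; plots covering no pixel centre or touching nodata are dropped and
reported. Raster I/O is float32 TIFF (nodata −9999) with a JSON sidecar
carrying the geotransform and CRS; all layers of a stack must share one
grid geometry, and resampling is bilinear for continuous layers, nearest
for masks.

## Ensemble

Base learners and tuned defaults: random forest (300 trees, 6 candidate
features per split), XGBoost (500 rounds, depth 3, learning rate 0.01), a
LightGBM gradient-boosting machine (600 rounds, depth 6, learning rate
0.01) and an RBF SVM (C = 10, γ = 0.01, standardised inputs). Grid search
is exhaustive, scored by mean 5-fold CV RMSE, ties broken toward smaller
parameter values (fewer trees, shallower depth, smaller cost).

RFECV removes the least-important feature per step — model-native
importance for the tree learners, permutation importance for the SVM,
which has no native measure — and keeps the feature set with the best CV
R², ties toward fewer features. The consensus list is the intersection of
the four per-model selections, padded or trimmed to the 20-feature target
by mean normalised elimination rank; every adjustment is logged.

Stacking trains the four base models per fold of a shuffled 5-fold split
and assembles their strictly out-of-fold predictions into an n×4 matrix on
which a ridge regression with intercept is fitted. The ridge penalty is
chosen by internal cross-validation over 10⁻³…10³ (the tree-based base
predictions are strongly collinear, which is exactly what L2 shrinkage
stabilises). Per-fold base models are retained for uncertainty, full-data
base models for deployment; negative stacked predictions are floored at 0
and flagged.

Protocols: plots are split once (seeded, default 80/20) into a modelling
and an external-verification set. CV metrics come from repeated 5-fold
cross-validation on the modelling set (means and interquartile ranges over
repetitions; the stacked CV prediction for a fold uses a ridge fitted on
the other folds' out-of-fold predictions, so it is never self-referential).
EV metrics come from the final models on the withheld plots and do not
depend on the repetition count. Permutation importances, signed by the
Pearson correlation with AGB, can be aggregated over the repetitions.

## Mapping and uncertainty

Per pixel, the map value is the full-data stacked prediction and the
uncertainty is the *population* standard deviation (divide by n = 5) of the
five fold-wise stacked predictions, each fold's base ensemble passed
through the same meta-model — the fold spread propagates through the
meta-model rather than being computed per base learner. Maps are processed
in row tiles and are exactly tile-size invariant; an optional forest mask
is accepted as a boolean raster. Summaries report the mean density over
valid pixels and `total = Σ(pixel AGB)·pixel area`.

## Synthetic benchmark

The generator emulates a two-cycle inventory over 600 square 0.0667-ha
plots (first survey 2017, revisit in 2021–2023) with a 5-cm measurement
threshold and co-registered 10-m rasters, and is built "environment first":

- Per plot, predictor values are sampled uniformly from vegetation-realistic
  ranges and the true plot AGB is *defined* as a linear signal of a few of
  them (default: strong negative weight on the short-wave-infrared band,
  smaller weights on near-infrared, red, and elevation) plus
  N(0, 19 Mg·ha⁻¹) noise. Because the noise is orthogonal to the sampled
  features, ordinary least squares on the feature table recovers the signal
  coefficients — the oracle used in testing.
- The tree list (lognormal baseline DBH, shape σ = 0.44; 60–140 stems per
  plot from a six-species pool) is scaled by a common power-law factor so
  its summed allometric biomass equals the plot's AGB exactly. 15% of plots
  are regeneration "hotspots" carrying an extra, exponentially-dispersed
  cohort (mean 180) of small stems near 4.4 cm. These choices were
  calibrated once so that (a) about 23% of first-cycle stems fall below the
  threshold — the regime reported for the inventory data this emulates —
  and (b) the attainable model R² is ≈ 0.7; the hotspot mechanism makes the
  under-threshold biomass increment vary between plots, which is what lets
  the include-scenario model verify better externally than the
  exclude-scenario model.
- Each (plot, species, class) group draws one true annual increment from
  N(0.3, 0.1) cm·yr⁻¹, truncated to [0.05, 0.8]; measurement noise
  (default 1 cm) is added independently per survey, with recorded
  first-cycle diameters floored at the 5-cm protocol threshold. Mortality
  is off by default (`dropout_rate`).
- Rasters paint each plot's plan values as constants inside its footprint
  over smoothed-noise backgrounds; the first signal feature is solved per
  plot so the configured signal reproduces the supplied AGB up to the noise
  level. The tabular "plan" path and the raster-extraction path agree
  exactly for band and elevation features; the remaining terrain
  derivatives are exogenous in the plan table but DEM-derived on the raster
  path.

**What passing tests do and do not show.** The benchmark demonstrates
correctness of the mechanics (exact recovery under zero noise, calibrated
behaviour under noise, protocol hygiene, map/tabular consistency). It does
not emulate spectral saturation at high biomass, mixed pixels, cloud
contamination, species-specific growth curves, mortality/harvest, or
spatial autocorrelation between plot biomass and terrain — so benchmark
accuracies say nothing quantitative about any particular sensor or region.

## Problem sizes

Default analyses run at 600 plots (~75 000 stems); the mapping demonstration
uses 150 plots on a 120×120 10-m grid, and the bundled demo 120 plots —
sizes chosen so a full run completes in minutes on one core while leaving
group sizes large enough for the back-casting statistics to be meaningful.

## Known limitations

- D8 flow accumulation does not resolve pits or flats (no fill/breach), so
  TWI is simplistic in closed depressions.
- The wood-density table is a point lookup; no diameter- or age-dependent
  density, and the shipped *Robinia* value is reproduced as printed.
- Stage resumption reloads tabular artifacts from disk, but trained models
  live only in memory: the `map` stage must run in the same invocation as
  `train`.
- EV plots are withheld at random; with spatially autocorrelated real data
  a spatial hold-out would be the stricter test.
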