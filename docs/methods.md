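# Methods

This note documents the modelling choices behind `emusdm`: what each stage
assumes, which knobs matter, what the synthetic testbed does and does not
emulate, and where the design was genuinely open.

## Pipeline overview

clean → thin → bias layer → environmental kernel → pseudo-absences →
extract → VIF screening → scale/centre → fit (9 algorithms × 6 repeats) →
skill gates → TSS-weighted ensemble → max-TSS binarization → scenario
projection → range change → MESS / correlation-shift diagnostics.

Everything derives from a single global seed: each stage's seed is
`SeedSequence([global_seed, crc32(stage_name)])` reduced modulo 2³¹, so a
stage can be re-run in isolation and reproduce the pipeline's behaviour
exactly.

## Occurrence hygiene

Cleaning drops records with reported coordinate uncertainty above 5 km
(records with *missing* uncertainty are kept by default, since an absent
value usually means an observer-estimated short distance; a strict flag
reverses this), recorded absences, fossils, records without a year or from
before 1970 (the start of the predictor baseline), exact duplicates after
rounding coordinates to 6 decimals, records within 10 km of supplied city
points or inside exclusion polygons, and spatial outliers more than 30 km
from every other record. A record violating several rules is counted under
each but removed once. Outlier removal is a single pass: an outlier by
definition has no neighbour within the radius, so removing outliers cannot
orphan a kept record, and the operation is idempotent.

Thinning uses a seeded random ordering with greedy accept-if-≥-30-km. No
claim of maximising the retained count is made; the greedy subset is
reproducible and standard. Distances are Euclidean on planar-km grids and
haversine (R = 6371.0088 km) on geographic ones.

At desk scale these rules bite hard: on the 200×200 study landscape, 500
raw presences reduce to ≈ 240 after cleaning (the 30-km isolation rule is
the main filter at this point density) and ≈ 100–130 after thinning. This
mirrors, proportionally, the full-data situation where tens of thousands of
sightings reduce to a few thousand fitting points.

## Pseudo-absences

Two ingredients: a **bias layer** (Gaussian point density of cleaned
analogue-species sightings, bandwidth 100 km by default, rescaled to max 1)
and a **presence environmental kernel** — predictors standardised over the
whole grid, projected onto principal components (smallest count explaining
≥ 95% variance by default), and a product-Gaussian KDE with per-component
Scott bandwidths fitted to the presence scores. Cell weight is
`(1 − F(d)) × bias`, where `F` is the grid-wide empirical CDF of the
presence-kernel density `d`: the most presence-like cells get weight near
0, the least presence-like near 1. A rank-based complement is used rather
than the superficially simpler max-normalised form `1 − d/d_max`, because
a KDE over several components spans orders of magnitude; relative to its
grid maximum the density is ≈ 0 almost everywhere, making the linear
complement non-discriminating and letting pseudo-absences leak into
clearly suitable habitat (in synthetic experiments up to ~38% of
pseudo-absences landed on true-suitability > 0.5 cells under the linear
complement, versus ~10% under the rank complement, and the
presence/pseudo-absence contrast collapsed on a fifth of landscape
realizations). The multiplicative combination with bias keeps zero weight
wherever either factor vanishes. Sampling is sequential, weighted,
without cell replacement, rejecting candidates within 30 km of any presence
or accepted pseudo-absence; after 50·n rejections the spacing problem is
reported infeasible together with the achieved count. Thinning is thus
enforced *during* sampling; thinning afterwards would discard information
about which cells were preferred.

Open points resolved here: the kernel is fitted on presences only (not
presence + background), and spacing is enforced during sampling; both
choices are recorded because the protocol we follow does not fix them.

## Predictor screening and standardisation

VIF_j = 1/(1 − R²_j) from regressing predictor j on the others (intercept
included, labels ignored), computed on the combined presence +
pseudo-absence table. Stepwise screening removes the single largest VIF
while it exceeds 10, ties broken by column order. Standardisation
parameters (mean, sd per column) come from the fitting table and are
re-applied verbatim to every scenario stack: projections must live in the
fitted model's coordinate system, never be re-centred on their own climate.

## The model roster

Nine registered learners: BIOCLIM (in-house percentile envelope: per
variable p = fraction of presence values ≤ x, score 2·min(p, 1−p), zero
outside the presence min–max, overall score the minimum over variables),
logistic GLM with linear + quadratic terms, a smooth additive logistic
model (cubic spline basis, 5 knots), a single classification tree, random
forest (200 trees), gradient-boosted trees, a one-hidden-layer neural
network (8 units), shrinkage linear discriminant analysis, and an adaptive
regression-splines learner (greedy forward selection of hinge pairs at
per-variable quantile knots, least-squares fit on the 0/1 labels, clipped
to [0, 1]). A tenth slot accepts user-registered learners; a deliberately
skill-less "noise" learner is registered for gate testing. MAXENT is not in
the default roster: its feature-class and regularisation machinery is a
project in itself, and the nine members above already span envelope,
parametric, additive, tree, ensemble, network and discriminant families.

Each of the 6 repeats draws its own stratified 70/30 calibration/holdout
split; learner seeds also vary per repeat so repeats differ in both split
and stochastic fit. Every model is scored on its own holdout: AUC
(Mann–Whitney pair-ranking, ties ½), the max-TSS threshold, and TSS, Kappa,
sensitivity and specificity at that threshold.

Hyperparameters are modest fixed defaults chosen for stability at the few
hundred fitting points the synthetic studies produce; an optional
per-learner grid search on the calibration split exists conceptually as
"tuning" but is off by default, since none of the verification studies need
it.

## Evaluation conventions

A score equal to the threshold predicts presence. Threshold candidates are
the observed unique score values; the max-TSS search uses an exact integer
numerator (n₀·TP-part + n₁·TN-part) so algebraic ties break
deterministically to the smallest optimal threshold — floating-point TSS
values can differ at 10⁻¹⁶ between equal candidates and would otherwise
break the tie rule. The continuous Boyce index uses 101 overlapping windows
of width one tenth of the observed suitability range; the Spearman
correlation of P/E against window midpoint. Note that with such heavy
window overlap the P/E noise is autocorrelated, so under the null
(presences drawn uniformly from the background) single-run indices scatter
widely even at large n; only their centring on zero is a meaningful null
property. The pipeline computes Boyce on the full current-climate surface
as background with presence predictions from the fitting table, and labels
it as such.

## Ensemble, projection, range change

Gates are inclusive (≥) at TSS 0.7 / AUC 0.9 / Kappa 0.7; survivors are
weighted by TSS normalised to sum 1. The binarization threshold is chosen
by max-TSS on the ensemble's own fitting-table predictions (the data slice
is recorded in the run report). Range change counts cells — synthetic grids
are planar equal-area by construction, so cell counts are areas — under
unlimited dispersal (whole projected range) and no dispersal (overlap
only); the latter can never exceed the former. A coefficient-of-variation
map (cell-wise sample sd / mean across members) expresses ensemble
disagreement.

## Novelty diagnostics

MESS similarity per variable follows the standard percentile formulation
with a strict less-than convention for the reference fraction; the
aggregate map is the cell-wise minimum, negative where a scenario leaves
the environmental range of the fitting points (the reference is the raw
predictor values at presences + pseudo-absences). Correlation shift is the
difference of Pearson correlation matrices of the predictor layers between
two stacks. Under purely additive scenario shifts the correlation shift is
identically zero — a useful internal control; multiplicative or
heterogeneous shifts produce nonzero entries.

## The synthetic testbed

Predictor layers are white noise convolved with a Gaussian kernel (sigma =
the autocorrelation length, periodic boundaries for stationarity) and
standardised; 10-km cells on a 200×200 grid give a 2000×2000-km domain in
which 30-km spacing rules leave a feasible point packing. The true niche is
logistic with a quadratic optimum on the strongest variable
(β = 4.0 bio13 − 1.5 bio13², −3.0 bio15, +2.0 bio18, intercept −1.0); the
coefficients are sized so the presence/pseudo-absence contrast is strongly
separable (median holdout TSS ≈ 0.7 across the roster), the regime in
which skill-gated ensembling is meant to operate. Observation bias is a
hotspot mixture (Gaussian bumps over a 5% floor); presences are drawn per
cell ∝ suitability × bias and jittered uniformly within the cell; 10% of
records deliberately violate one cleaning rule each (coarse uncertainty,
missing year, fossil flag, absence flag, relocated far outlier). Scenario
climates are cell-wise affine shifts; the range-change study shifts
precipitation seasonality by +0.6 sd, contracting the true range
(0.5-level set of the true niche) by roughly 30–45% depending on the
landscape seed. The shift magnitude is deliberately moderate: it keeps the
scenario almost entirely inside the environmental envelope of the fitting
data (MESS novel-climate fraction ≈ 5–10%), so the study measures whether
the pipeline *tracks* a range change, separately from its behaviour under
extrapolation — which is the MESS diagnostic's job, and where tree-based
ensemble members are known to respond too flatly.

What the testbed does **not** emulate: real geography (coastlines,
topography, monsoon structure), temporally varying observation effort,
spatially correlated label noise, GCM physics, or non-climate predictors
(vegetation, land use, human footprint) beyond generically named extra
layers. Passing the recovery studies therefore demonstrates that the
pipeline's statistical machinery recovers a known signal through a known
observation process — not that any particular real-world inference is
correct.

## Verification studies and problem sizes

The niche-recovery study runs the full pipeline on five seeded 200×200
landscapes with 500 raw presences and 1,500 analogue sightings
(≈ 5 s/seed) and measures Spearman ρ between ensemble and true
suitability on 10,000 cells containing no fitting point. The range-change
study uses the same landscapes with 1,200 raw presences (≈ 300 fitting
points per class after thinning, so the fitted response is steep enough
that the estimate measures tracking rather than small-sample attenuation)
and compares the unlimited-dispersal estimate with the true change. The
gate study injects the noise learner into the roster on 80×80 landscapes.
Metric implementations are cross-checked against independent brute-force
oracles (pair counting, exhaustive threshold sweep with exact rationals,
branch-by-branch MESS, normal-equation VIF) on 200 random instances. At
the frozen study conditions, measured across ten landscape seeds, ρ
ranges ≈ 0.86–0.97, the range-change error is within 10 pp in 9 of 10
seeds, and every noise model is rejected by the gates.

## Known limitations

* Greedy thinning and sequential pseudo-absence placement are O(n²); fine
  at 10³–10⁴ points, not at 10⁶.
* Fitted model states live in memory for the duration of a run; there is
  no binary model serialisation, so "project later" means re-running the
  (deterministic) fit.
* The max-TSS threshold from balanced fitting data is a biased estimator
  of the true 0.5-suitability level set; range-change ratios are fairly
  robust to this shared bias but individual range areas are not.
* Geographic-CRS support covers point distances (haversine) and cleaning;
  grid cells are never treated as equal-area on geographic grids, so
  range change there counts cells, not km².
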