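# Methods

## Response and sampling unit

The modelling unit is one histologically examined mature female. Her binary
response is 1 when the gonad shows oocyte maturation (nucleus migration
through hydration) and/or post-ovulatory follicles — i.e. the fish was within
roughly 48 hours of a spawning event — and 0 for a mature, non-spawning
female. All set-level covariates (location, date, gear, depth, temperature,
terrain statistics) are shared by the fish of one gear set, so records are
clustered by set and by year. Juveniles, males and zero-catch sets are out of
scope by design: mixing them in would confound spawning probability with
occurrence and ontogeny. `DesignBuilder` also accepts a set-level response by
collapsing records per set before building, but the fish-level Bernoulli
model is the default and the one all tests exercise.

Species with more than 90 spawning-condition females are considered
modelable (`filter_modelable`); "valid sets" (>= 3 examined fish of the
species in one deployment) are reported as a diagnostic only.

## Terrain covariates

Depth rasters (metres, positive down; regular grids projected in metres) are
differentiated on the elevation surface:

* **BPI** — elevation minus the mean elevation in an annulus whose
  membership rule is `inner < d/cell <= outer` on centre-to-centre Euclidean
  distance. Defaults: inner 1, outer 18 cells (broad) and 9 cells (fine),
  matching a ~90 m national-relief grid. BPI is kept floating point; an
  integer-rounding switch exists only for parity with desktop GIS tools that
  quantize.
* **Slope and aspect** — Horn's 3x3 weighted finite differences; aspect is
  degrees clockwise from north and is nodata on perfectly flat cells.
* **Curvature** — the general curvature of the 3x3 quadratic surface fit
  (Zevenbergen–Thorne), reported as -200·(D+E) in 1/100 m, positive =
  convex. Whether profile, plan or general curvature is most informative for
  spawning habitat is an open choice; general curvature is the default here
  and the estimator is isolated in one function if a variant is wanted.

Buffer summaries take the mean and max of each layer over cells whose
centres fall within a radius of each sampling point: 381.8 m for the coarse
grid (the hypotenuse of a 3x3 block of 90 m cells) and 127 m for fine grids.
Mean aspect is a circular (vector) mean — arithmetic means of compass angles
are meaningless — and flat-cell nodata aspects are excluded. A point whose
buffer covers no valid cell is flagged missing rather than raising.

## Lunar covariate

The signed lunar luminosity at date *t* is computed from the phase angle
θ = 2π·(days since previous new moon)/29.53059: illuminated fraction
f = (1 − cos θ)/2, signed positive while waxing (θ ≤ π) and negative while
waning, with an optional snap to the nearest quarter. "Rounded to the
nearest quarter moon" admits two readings — value-rounding (implemented as
the `quarter_round` switch) or snapping dates to quarter-phase events; the
former is the default and neither is asserted as uniquely correct. Reference
new moons come from the mean synodic lunation anchored at the 2000-01-06
epoch; a mean-lunation ephemeris is accurate to well under a day across the
survey decades, which is ample for a luminosity covariate, and avoids
shipping an external ephemeris table. Eight phase categories are assigned by
octant of θ.

## Design matrices

Month, gear, habitat and the phase category are factors; temperature and
lunar luminosity may enter continuously; latitude, depth and all terrain
statistics are binned — by quantiles (k = 4 by default, type-7/linear
quantiles; duplicate edges from ties collapse with a warning) or by the
fixed schemes (1° latitude bins over 30.5–34.5°, 20 m depth bins over
10–70 m). Bins are left-closed/right-open with the last bin closed. Factors
are dummy-coded against the first sorted level; interactions are factor
crosses; empty levels are removed. Records with missing or non-positive
temperature are dropped only for temperature-containing models — except that
`restrict_temp=True` applies the restriction up front so that every
candidate model in a stepwise comparison is fit to identical rows (an AIC
prerequisite). Bin edges, factor levels and observed continuous ranges are
stored with the design so new data (e.g. prediction grids) encode
identically; unseen levels and out-of-range binned values map to the
reference level / nearest bin with a warning (strict mode raises), which is
what lets a latitude-limited fit predict over a wider mapping domain.

## The mixed model

The marginal likelihood of the logit-linked Bernoulli model with one
Gaussian year intercept is maximised directly over (β, σ). Each group's
integral is evaluated by adaptive Gauss–Hermite quadrature: the conditional
mode of u_j is found by (concave, undamped) Newton iteration, the 21 nodes
are recentred and rescaled by the mode and curvature, and the group
likelihood is a log-sum-exp over nodes. One node reproduces the Laplace
approximation exactly and is used automatically above 40 year levels. The
gradient is computed under the same quadrature with the recentring held
fixed — the quadrature value is invariant to the recentring parameters up to
the quadrature error itself, so this gradient is exact for practical
purposes (verified against central differences at ~1e-7). Optimisation is
L-BFGS-B with σ bounded below by 0; a boundary estimate collapses the fit to
ordinary logistic regression (IRLS), as does a single-year grouping.

Conventions: deviance is −2·log marginal likelihood (the Bernoulli saturated
term is zero); the null deviance comes from an intercept-only refit with the
same random structure; AIC counts the fixed coefficients plus one variance
parameter whenever σ was estimated. Whether deviance partitions should be
conditional or marginal is a genuine fork; the marginal scale is used
throughout because model comparison and AIC already live there. Percent
deviance explained by term *i* in a nested sequence is
100·(D_{i−1} − D_i)/D_null, which telescopes to the total.

Predictions are population-level (u = 0) — multi-year maps imply year-free
predictions — with delta-method standard errors p(1−p)·se(η) from the
observed-information covariance (central-difference Hessian, computed
lazily). Wald intervals for σ are formed on the log scale and
back-transformed, which keeps them positive and markedly improves coverage
at ten-ish year levels. Complete separation is detected heuristically
(|coef| > 25 or IRLS non-convergence) and flagged; the optional penalty
applies Firth's adjusted-score correction (the Jeffreys-prior penalty) in
the plain-logistic path and a weak ridge (1e-3) in the mixed path, both off
by default and recorded on the fit when used.

## Selection, validation, spuriousness

* **Correlation screen**: pairs with |association| strictly above 0.60 may
  not co-occur in a model. Numeric pairs use Pearson r on the underlying
  continuous values, factor pairs Cramér's V, mixed pairs the correlation
  ratio; the 0.60 rule itself does not specify an estimator, so these are
  declared choices.
* **Forward stepwise (stage 1)**: starting from the intercept, add the
  candidate with the largest AIC decrease, skipping screened pairs and
  interactions whose margins are absent; stop when nothing lowers AIC. Ties
  break by candidate order. The visited models, ranked by AIC, are returned.
* **Stage 2**: terrain candidates are offered to the fixed stage-1 winner; a
  term is retained only if AIC decreases and the candidate model's pooled
  cross-validated AUC is not more than 0.5 points below the stage-1 model's.
  The "does not degrade predictive utility" rule has no published numeric
  form; 0.5 AUC points is this package's operationalisation.
* **Cross-validation**: 10 folds, stratified by class (avoids single-class
  training folds), seeded and recorded. Per fold the threshold maximising
  TPR + TNR is chosen on the *training* ROC (lowest observed score attaining
  the maximum, under a `score >= t` rule) and applied to the held-out rows.
  FPR/FNR come from pooled confusion counts. AUC is computed by the
  Mann–Whitney midrank formulation on the pooled held-out predictions;
  whether to pool or average per fold is unstated in common practice, so the
  per-fold mean is reported alongside. Grades: excellent >= 90, good 80–89,
  fair 70–79, poor < 70 (boundaries belong to the higher grade).
* **Randomization test**: keeping the non-terrain terms at their observed
  values, every terrain candidate column is independently permuted
  (preserving its marginal distribution exactly), the base model plus each
  permuted candidate is refit singly, and the best one (largest AIC
  reduction) contributes its percent deviance; over 500 replicates (the
  default; tests and the acceptance script use 100 for runtime) the spurious
  probability is the fraction of replicates whose best random candidate
  explains more deviance than the true term.

## Prediction maps and external validation

The prediction grid aggregates the source rasters by 3x3 block means
(~90 m → ~270 m), attaches per-cell moving-buffer terrain statistics, drops
land and cells deeper than 200 m, and encodes each cell with the stored bin
edges and levels. Peak settings for month/temperature/lunar terms default to
the argmax of the fitted linear predictor over observed levels (continuous
terms: the end of the observed range favoured by the coefficient sign) and
can be overridden. Probabilities — not linear predictors — are standardised
to Z-scores over the full non-nodata domain with the population SD; Z is
affine-invariant in the probability surface, and a zero-variance surface
yields Z ≡ 0 with a warning. A validation point supports the model when the
Z under it is strictly positive; support fractions are reported per source
and overall, excluding off-grid points.

## Spawning areas

A multispecies spawning event is one gear set with spawning females of two
or more species. Multi-year areas per species are single-linkage clusters of
spawning sets at a 1.1 km link distance — the underlying survey does not
define cluster edges, so single linkage at a configurable radius is a
declared convention, not an assertion about the original procedure — kept
when they span two or more sampling years and sized by the convex hull
(minimum convex polygon) of member sets, in a local Lambert azimuthal
equal-area projection centred on the cluster (hulls are never taken on raw
longitude/latitude). Fewer than three non-collinear points give area 0.
"Percent years with spawning" divides the cluster's spawning years by the
years in which any location within the link distance of a member was
histologically sampled for the species; that denominator is one reasonable
reading of an ambiguous definition and is documented as such.

## Synthetic study conditions

The generator's defaults define the study conditions: a 96×96 grid of 90 m
cells; depth rising from ~10 m at the western edge to ~200 m offshore with
one Gaussian shelf-edge ridge (amplitude 25 m, width 3 cells at 62% of the
cross-shelf span) and smooth correlated noise (SD 1.5 m, correlation length
3 cells); ten sampling years of 100 gear sets placed uniformly over
depth-eligible (10–200 m) cells; 1–12 examined females per set (uniform — the
real per-set count distribution is undocumented, so this is a declared
guess); months drawn with mass concentrated May–September; bottom
temperature = 26 + 3·cos(2π(month−8)/12) − 0.06·depth + N(0,1) °C; and a true
logit of −1.2 + 0.3·(temp−22) + 1.2·exp(−(month−6.5)²/4.5) − 0.5·lunar3 +
0.2·(mean broad BPI) with year intercepts of SD 0.5. Truth columns (true
probability, year effects) are kept in a sidecar table so the analysis path
consumes exactly the public CSV schema.

What passing tests on this generator do and do not show: the generator
reproduces the statistical structure the analysis assumes (set-level
covariate sharing, year heterogeneity, seasonal peak, terrain dependence,
effort seasonality) but not gear selectivity, preferential hardbottom
targeting, spatially autocorrelated catchability, or real regional
geography. Parameter recovery and calibration results therefore validate
the estimators and the selection machinery, not the field realism of any
particular covariate effect. One visible consequence: uniform dense
sampling in a small domain makes single-linkage clusters at 1.1 km merge
into few large multi-year areas, so the area statistics the acceptance
script reports describe that sampling regime, not a sparse field survey.

## Problem sizes and numerics

The test suite's heavier checks use 100 replicate surveys of ~4,000 fish
across 10 years for parameter-recovery coverage, 100 simulations at
n = 2,000 for stepwise calibration, and 10/20 meta-replicates of the
randomization test at 100 permutation replicates each; the acceptance
script runs the full pipeline on one ~6,500-fish survey and uses the
Laplace (one-node) integrator inside the randomization refits. Numerical
details worth knowing: quadrature uses 21 Hermite nodes by default; the
inner Newton solve runs to 1e-10; IRLS stops at a 1e-10 relative step; AIC
ties in stepwise break by candidate order; quantile-bin edge collapses and
empty-level removals are recorded on the design as warnings.

## Known limitations

Single random intercept only (no crossed/nested effects, no smoothers — the
linear-in-factors GLMM is deliberate); the correlation screen's factor
encodings are heuristic; the Esri ASCII raster reader handles the plain
uncompressed format only; geographic/projected conversions use local
spherical approximations appropriate for survey-scale extents, not a full
geodesy stack; and the desktop-GIS annulus mask that inspired the BPI
neighbourhood is undocumented, so exact parity with any particular GIS tool
is not guaranteed (the half-open Euclidean rule here is stated and tested
against its own brute-force oracle).
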