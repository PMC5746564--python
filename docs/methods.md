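# Methods

## Per-country population model

The response is the natural log of admin-unit population density,
`ln(count / unit_area + ε)` with `ε = 10⁻⁸ people/km²`.  The floor
keeps zero-count units finite and in the training set; it maps them to
a log density of about −18.4, a deliberate, strongly separated "empty"
level.  The log transform reflects the positive, heavy-tailed nature
of population density and makes the pixel-level prediction a positive
multiplicative weight after exponentiation.  A consequence worth
knowing: a single empty unit is a large-leverage point that can
depress the out-of-bag pseudo-R² noticeably (see the worked example),
exactly as genuinely empty census units would in a real model run.

Predictors are unit-level summaries of the covariate grids: the mean
over the unit's valid pixels, which for 0/1 extents equals the covered
proportion.  The model is a bagged ensemble of unpruned regression
trees (scikit-learn `DecisionTreeRegressor`s, bagging implemented
here so each tree's bootstrap membership is explicit).  Defaults
follow regression-forest convention: `k = 500` trees (250 in the demo
study), `mtry = max(1, ⌊p/3⌋)` variables per split, minimum leaf size
5.  The ensemble's out-of-bag error is the MSE of OOB-aggregated
predictions (each unit predicted only by trees not trained on it) and
`variance explained = 100·(1 − oob_mse / Var(y))` with population
variance — the convention of the standard R implementation whose
outputs this pipeline mirrors; per-tree OOB errors are kept separately
for the importance statistic.  A constant response is flagged
(`zero_variance_response`) rather than reported as NaN.

Permutation importance follows the per-tree percent-increase
definition: for each tree that used covariate *j* as a split variable,
one permutation of *j* within that tree's OOB set, percent increase in
the tree's OOB MSE, averaged over those trees and scaled by 100.
Covariates used by no tree score exactly 0; trees with a sub-2-row OOB
set or a zero baseline OOB MSE are skipped.  Averaging only over trees
that used the covariate, one permutation pass per tree, and no
standard-error scaling are deliberate; an `se_scaled` switch provides
the scaled variant, but all downstream analysis is rank-based and
insensitive to that choice.

Covariate selection drops *all* covariates with negative importance
each round and refits, stopping when none are negative or one
covariate remains (retained regardless of sign).  Retained-covariate
count is non-increasing, so termination is guaranteed.  Each iteration
derives a fresh seed from the master seed via `SeedSequence` spawn
keys — the scheme used everywhere in the package, making full runs
bit-reproducible from one integer.

The weighting layer applies the unit-level model to pixel-level
covariate values — a scale mismatch inherent to the method (training
summaries are means over units; prediction inputs are raw pixels),
documented rather than corrected.  Dasymetric redistribution allocates
each unit's count proportionally to pixel weights; units whose weights
sum to zero are allocated uniformly over their valid pixels so mass
conservation holds for every input (per-zone relative error bounded by
float rounding, in practice ~1e−15).

## Covariate classes and WIR

Name → class mapping is an ordered substring match on normalized names
(lower-case, collapsed whitespace/underscores); the first matching
pattern wins, and unmatched names soft-fail to `unclassified`, which
is carried in tables but excluded from tests together with the
`no data` class.  The shipped table (`data/covariate_classes.csv`,
user-editable) covers the 18-class vocabulary plus synonyms for the
synthetic covariates.  `classified populated place` and
`populated place` are kept as distinct classes (hierarchical
settlement typologies vs gazetteer points); users who want them merged
edit the map.

Within a country, rank 1 is the largest Per.Inc.m.s.e., ties receive
average ranks, and `WIR = (rank − 1)/(n − 1)` — the unique linear map
sending the best covariate to 0 and the worst to 1; a single-covariate
model scores 0.  Average-rank ties keep the WIR consistent with the
rank-based tests downstream.

## Comparison designs

The tie-corrected Kruskal–Wallis H (reported as "chi-squared", its
reference distribution) uses joint mid-ranks and correction
`C = 1 − Σ(t³−t)/(N³−N)`; all-tied samples give H = 0, p = 1.  Dunn
Z-scores use the tie-corrected joint-rank variance and two-sided
normal p-values; Holm's step-down correction is applied within each
Dunn family (the pairwise set of one KW test), not across designs.
Dunn tests run only when the KW gate is significant at α (default
0.05).  Scopes with fewer than two groups are reported as untestable
rather than raised.  Class-level designs pool all covariate rows per
country by default; a `per_country_median` switch collapses each
country's class rows to their median first, for users who prefer one
observation per country.

Correctness is pinned two ways: exact agreement (1e−12) with an
independent brute-force implementation on an exhaustive family of
1 809 small tied integer samples, and cross-checks against
`scipy.stats.kruskal` and statsmodels' Holm adjustment.

## Synthetic countries

The generator plants `log density = β₀ + Σ βₖ z(covₖ) + ε` with
`z(·)` standardizing each covariate over valid pixels and
`ε ~ N(0, σ²)` i.i.d. per pixel (log-scale noise keeps densities
positive and heavy-tailed).  Census counts are banker's-rounded zonal
integrals of `exp(log density) · pixel_area`; zero-count zones are
legal and exercised.  Admin zones are a nearest-seed partition of the
grid — irregular, size-heterogeneous, contiguous by construction —
and ASR = √(mean zone area) summarizes granularity.  Covariate kinds:
thresholded smooth Gaussian fields (binary extents, default 15%
coverage), Euclidean distance transforms from random lattice polylines
(roads/rivers), smoothed white noise (σ = 3 pixels; a free smoothness
knob, not calibrated to any country), gradient magnitudes of a named
smooth field (slope), and nearest-seed categorical patches.  Pixel
area defaults to 0.01 km², the 100 m-pixel analogue.

What the generator does *not* emulate: vector admin boundaries,
census-year/covariate temporal mismatch, country-specific covariate
engineering, spatially correlated noise, and realistic absolute
population magnitudes (the demo baseline e⁶ ≈ 400 people/km² gives
unit populations in the tens to thousands on a 36 km² toy country).
Passing tests therefore demonstrate the *machinery* — recovery of
planted structure, conservation, calibrated inference — not fidelity
to any real country's drivers.

## Study conditions used by the acceptance runs

* **Demo study**: 4 regions × 3 countries, 60×60 grid, 150 zones,
  8 covariates spanning six variable classes, 250 trees.
* **Recovery**: 80×80 grid, 300 zones, 3 planted smooth fields
  (β = 1.0, −0.8, 0.6) among 7 noise fields, σ = 0.25, 500 trees,
  50 seeds; success = all planted covariates survive selection and
  hold the top three importance ranks.
* **Null calibration**: 4 regions × 5 countries sharing one β vector
  (the exchangeable null), 30×30 grid, 36 zones, 6 covariates each in
  a distinct class (one WIR value per country per class, so group
  sizes are 5 with no within-country clustering), 50 trees, 500
  replicate studies; the elimination loop is skipped here — a single
  fit per country preserves exchangeability across regions while
  keeping 500 replicates tractable — and the rejection fraction pools
  the per-class inter-regional tests.

These sizes are the package's reference conditions, chosen to be the
smallest landscapes that still behave like their larger counterparts
(well-populated zones, several pixels per zone, non-degenerate OOB
sets).

## Known limitations

* Importance is conditional on the covariate set: correlated smooth
  fields share credit, and a weakly weighted but spatially coherent
  covariate (e.g. a distance field) can out-rank a stronger but
  patchier one — visible in the worked example, and a real property
  of permutation importance rather than a defect.
* The chi-squared approximation for KW is slightly conservative at
  the small group sizes typical of intra-regional scopes; observed
  null rejection ≈ 0.043 at α = 0.05 under the calibration
  conditions.
* ESRI ASCII is the only grid format; it is text-based and large for
  big rasters.
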