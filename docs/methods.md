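# Methods

## The partition

For a pair of incidence rows let `a` be the number of shared species and
`b`, `c` the counts exclusive to each site.  The Jaccard dissimilarity
β_cc = (b+c)/(a+b+c) is split into a richness-difference term
β_rich = |b−c|/(a+b+c) and a replacement term β_-3 = 2·min(b,c)/(a+b+c).
min(b,c) is the number of one-for-one species substitutions between the
two sites; each substitution involves two species, hence the factor 2.
The identity β_cc = β_rich + β_-3 holds algebraically; `BetaPartition`
enforces it at 1e−12 so any numerical drift surfaces immediately.  A pair
of two empty communities has a+b+c = 0 and no defined dissimilarity; it
raises rather than silently returning 0, because 0 would assert perfect
similarity — a biological claim empty data cannot make.  Empty sites are
removed only by an explicit `drop_empty_sites` call (or the pipeline's
logged `drop_empty_sites: true` option), never implicitly.

## Predictor matrices

Geographic distance is spherical haversine with R = 6371 km; at the scale
of regional centroids the sphere-vs-ellipsoid error is far below the
width of any distance class.  Climate predictors are absolute per-site
differences; import value and forest area are natural-log-transformed
before differencing (the base only rescales a matrix that is standardized
downstream, so one fixed convention keeps fixtures exact); forest
composition is Bray-Curtis on the site-by-forest-type area table.

## Mantel correlogram

Distance classes are equal-width over [min, max] of the off-diagonal
geographic distances, half-open [lo, hi) with the last class closed —
a deterministic binning with no data-dependent tie handling.  The default
class count is Sturges' rule on the number of pairs,
k = ceil(1 + log2(n_pairs)); an explicit `n_classes` overrides it (the
48-site study design this emulates used 5 classes).  For class *i* the
statistic is the Pearson correlation between the unfolded response
triangle and the 0/1 within-class indicator, and because the response is
a dissimilarity the reported value is negated: positive means
within-class pairs are *more similar* than expected.  A `raw` flag
restores the unflipped sign.  Permutations shuffle the site order (rows
and columns jointly) of the response matrix only — the indicator encodes
the fixed geography and is not permuted — with the add-one estimator
p = (1+#extreme)/(1+n_perm), which is valid (sub-uniform under the null)
by construction.  Tests are two-sided.  Significance is progressive
Bonferroni: class *i* in order of increasing distance is tested at α/i,
without stopping at the first non-significant class, so every class
carries its own flag as in published correlogram figures.  A class with
fewer than two member pairs is reported (r where defined) but flagged
untestable, with no p-value.

## MRM

The response triangle is regressed by OLS (with intercept) on the
triangles of the predictors, which are standardized to off-diagonal mean
0, SD 1 (ddof = 1) before fitting — `standardize_distance_matrix` is
idempotent, so already-standardized input passes through unchanged.
Quadratic terms are elementwise squares of the *standardized* linear
matrices and are deliberately not re-standardized, fixing an unambiguous
order of operations.  Coefficient p-values come from jointly permuting
the response's rows and columns; permuting the pair vector instead would
break the dependence structure of distances sharing a site, which is the
entire reason MRM inference differs from ordinary regression.  The
per-predictor summary table fits each predictor twice — linear, then
linear + quadratic — and retains the quadratic term only when its
permutation p < 0.01; `r_squared` is cumulative for the reported model.
A joint all-predictor `mrm_fit` is available; the table deliberately uses
per-predictor models because a cumulative per-predictor R² cannot come
from a single joint fit.  Rank-deficient designs raise a
`CollinearityError` naming the first offending term (checked by
incremental rank as columns are added).

## Hierarchical partitioning

The independent contribution of predictor k is the hierarchy-weighted
average of its R² gains over all subsets S not containing k,

    I_k = Σ_S |S|!(p−|S|−1)!/p! · [R²(S∪{k}) − R²(S)],

i.e. the Shapley value of R², so Σ I_k equals the full-model R² exactly
(asserted at 1e−10).  J_k = marginal R²(k) − I_k may be negative
(suppression).  Linear terms only, and the goodness-of-fit is the same
unfolded-triangle OLS R² as MRM, keeping both decompositions comparable.
Subset R² is computed by least squares, which projects onto the column
space and is therefore well-defined even for collinear subsets; two
identical predictors correctly split their shared variance (I = J = r²/2
each) instead of raising.  Enumeration is capped at 12 predictors (4096
subsets).

## NMDS

Non-metric SMACOF (scikit-learn) minimises Kruskal stress-1 with
isotonic regression of configuration distances on input dissimilarities
(primary tie treatment: tied inputs may map to equal fitted values).
The first start is Torgerson classical scaling of the input — for
metric-realizable input this start is already essentially optimal, which
is what the exact-Euclidean validation exploits — and the remaining
starts are Gaussian configurations drawn from one seeded stream, so
increasing `n_starts` under the same seed only extends the stream and
cannot worsen the best stress.  Defaults: k = 2, 4 starts, max 300
iterations, tolerance 1e−6 on the stress decrement.  The returned
configuration is centred at the origin; orientation and scale are not
identified (stress is invariant to rotation, reflection, translation and
uniform scaling).

## Synthetic data generator

The generator emulates the study design the estimators assume: 48 sites
uniform over a contiguous-USA-like window (lon −124…−67, lat 25…49).
Temperature falls 0.8 °C per degree latitude from 28 °C at the southern
edge (the negative slope is the physically sensible direction; the
latitude–temperature association is validated on magnitude), rainfall
rises 12 mm/yr per degree longitude from 500 mm at the western edge,
and both carry spatially autocorrelated Gaussian noise (exponential
covariance, 500 km range; SD 1.5 °C and 120 mm).  Imports and forest
areas are log-normal; imports can optionally be inflated toward the
east/west edges (`coast_weight`, default off).  Thirty-one forest types
have evenly spaced temperature optima (3 °C niche breadth), so the
Bray-Curtis forest matrix varies smoothly along the climate gradient.

Occupancy of species s at site i is Bernoulli with

    p = clamp( base · f_imp(i) · f_env(i,s) · f_disp(i,s), 0, 1 )

where f_env = exp(−(env_i − opt_s)²/(2σ_env²)) with optima uniform over
the (slightly widened) observed range, f_disp = exp(−d_km(i, nearest
introduction site of s)/λ), and f_imp = min(1, 2·sigmoid(γ·log imp_i)).
The import factor is scaled so that γ = 0 yields exactly 1 — the factor
then vanishes from the model, which keeps the no-import-effect limit
exact — and for γ > 0 it penalises below-median-import sites while
saturating above the median.  Species do not interact, matching the
assumption set of the downstream estimators.  Guild presets encode the
feeding-guild contrast (bark-like species filter on temperature,
ambrosia-like on rainfall); two single-mechanism presets support
recovery tests: *import-driven* (γ = 3, filtering and dispersal
limitation effectively off) and *dispersal-limited* (one introduction
site per species, λ = 400 km, γ = 0).  All randomness descends from one
`SeedSequence` split per stage, so a fixed seed gives bit-identical
datasets.

What the generator does **not** emulate: temporal invasion dynamics,
species interactions, trapping-effort heterogeneity between sites, and
phylogenetic or host-plant structure in the species pool.  Passing
recovery tests therefore shows the estimators recover the modelled
mechanisms under their own assumptions, not that real survey data meet
those assumptions.  The default two-guild preset also does not constrain
the *ratio* of mean β_rich to mean β_-3; with moderate filtering and
several introduction sites per species it typically produces more
replacement than richness difference, and the single-mechanism presets —
not the default — are the instruments for pattern-level claims.

## Problem sizes and numerical choices

Validation uses the sizes at which the checks are sharp: partition
exactness on a 150×40 table (11 175 pairs, compared pair-by-pair to a
set-operation oracle), permutation validity with 1000 replicate tests of
30-site matrices (999 permutations each; the add-one estimator makes
P(p ≤ 0.05) exactly 0.05 under the null), MRM null calibration with 1000
two-predictor fits at 199 permutations, and mechanism recovery over 100
seeds of 48-site communities at 199 permutations.  The pipeline default
is 999 permutations with a flag for 9999.  Permutation batches are
chunked (512 permuted matrices at a time) to bound memory.  Comparisons
of permuted against observed statistics use a 1e−15 slack so that exact
ties (impossible for continuous data, routine for constructed examples)
count as extreme, keeping p-values conservative.

## Known limitations

* Sturges' rule on the pair count of 48 sites gives 12 classes, not the
  5 used in the motivating study design; the rule's operand there is
  unstated, so the package defaults to the pair-count formula and exposes
  `n_classes` for an explicit override.
* Correlogram class significance is two-sided; one-tailed per-class
  testing in the direction of the observed sign is not offered.
* TEMP and RAIN are generic per-site scalars; the package is agnostic to
  which bioclimatic variable they represent.
* NMDS stress on sparse incidence data at k = 2 is routinely ~0.2–0.3;
  the ordination is a visualisation aid, and no inference is attached to
  its coordinates.
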