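# Methods

This note documents the models, numerical choices and open design decisions
behind `nutriphylo`, and what the synthetic-data tests do and do not
establish about real figures.

## Landscape extraction

A published performance landscape arrives as a raster of flat colour bands,
each band one interval of the z-axis (lifespan). Extraction proceeds in
five stages.

**Segmentation.** The background colour is the majority colour of the image
border; pixels within a tolerance of 10 RGB units of it are dropped (a
uniform single-colour image is treated as one band, since there is then no
background to strip). Remaining pixels are clustered in RGB space. When the
image holds no more distinct colours than requested, each exact colour is
its own cluster; otherwise a deterministic k-means is used (farthest-point
seeding from the most frequent colour, Lloyd iterations, index
tie-breaks), so segmentation is reproducible without a random seed.
Clusters are ordered by mean luminance and given 1-based ids. Requesting
more clusters than the image supports returns the available clusters with
a warning.

**Band values.** Assigning a performance value to each cluster is
deliberately manual for real figures (legend reading is out of scope); the
synthetic renderer emits the true map so round trips need no hand input.

**Calibration.** Two reference pixels per axis define an affine map from
pixel to nutrient coordinates; the row axis's downward-increasing index is
handled by the sign of the affine slope, not special-cased. Either nutrient
may sit on either axis.

**Jitter.** The discretised z-axis is ladder-like — many points share each
band value — which makes a thin-plate spline ill-behaved. Each point's
performance is therefore perturbed by an independent Normal(0, 0.25²) draw
(sd in absolute z-units regardless of trait scale, exposed as a
parameter). The true within-band variance of the source data is unknowable
from a figure; the constant-sd assumption is the price of interpolation
and is stated here rather than hidden.

**Noise filter.** Segmentation artefacts appear as small isolated pixel
clumps or points outside the plotting region. The filter removes
(a) points whose pixels lie in 8-connected components smaller than
`min_cluster_pixels` (default 10), and (b) points outside the convex hull
of the largest component expanded by `hull_margin` (default 5% of the axis
range; infinite margin disables the hull rule). The exact rule behind the
original filtering step is unpublished; this component-size + hull rule is
this package's documented choice. Removing every point is an error rather
than a silent empty result.

**Spline fit.** The surface minimises squared error plus a bending-energy
penalty, expanded in the r² log r kernel with an affine polynomial part,
solved as the standard augmented symmetric system. Penalty 0 interpolates
exactly; penalty → ∞ recovers the least-squares plane. "gcv" (the default)
minimises n·RSS/(n − tr(H))² over a 13-point log-spaced penalty grid; the
hat-matrix trace is computed from the same factorisation, which is why the
solver is written in-house rather than delegated to a black-box
interpolator. For more than 400 points the GCV search runs on a 400-point
subsample and the chosen penalty is rescaled proportionally to the point
count — the optimal penalty in this parameterisation grows roughly
linearly with n, and the approximation only affects smoothing strength,
not the estimand. Every band pixel is a candidate point; uniform thinning
to a cap (default 2,000) bounds the cubic solve. Coincident duplicate
coordinates are averaged with a logged note (bootstrap resampling creates
them by construction). Predictions are evaluated on a regular grid clipped
to the convex hull of the points.

## Nutrigonometry

The *peak region* is the set of grid cells with predicted performance at or
above the q-quantile of the grid (default q = 0.95); the optimum is its
unweighted centroid. A quantile region is robust to grid resolution and
plateau-shaped peaks; the single argmax cell is available as an
alternative. Angles are measured from the carbohydrate axis
(α = arctan(P/C), degrees), so a larger P:C ratio gives a larger angle and
the sign convention for theta = α_female − α_male holds by construction:
theta < 0 exactly when the female optimal ratio is lower. The hypotenuse is
the Euclidean norm of the centroid vector.

Confidence intervals are percentile bootstrap (default B = 1,000;
BCa was judged unnecessary at these B and the percentile method matches
the plain "95% confidence interval" reading). The GCV penalty is selected
once on the original data and reused across replicates, so the bootstrap
measures sampling variability of the surface, not of the smoothing search.
Degenerate replicates (collinear resamples) are skipped and counted; more
than 10% skips is an error. Validation of a reconstruction bootstraps
original and reconstructed point sets in parallel and computes the angle
between their optima and the difference of their hypotenuses per
replicate; the verdict is "consistent" when both 95% intervals contain
zero. The alternative reading — comparing two separate CIs for overlap —
was rejected as less direct; the CI-of-difference is the sharper test.

## Phylogenetic signal

**Covariance.** C[i,j] is the root-to-MRCA path length, C[i,i] the
root-to-tip distance, computed by a single postorder traversal. Before
model fitting C is scaled to unit maximum diagonal so variance priors are
comparable across trees; K is scale-invariant and unaffected.

**Blomberg's K** uses the phylogenetic GLS mean â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹y,
MSE0 = (y−â)ᵀ(y−â)/(n−1), MSE = (y−â)ᵀC⁻¹(y−â)/(n−1), and the Brownian
expectation [tr(C) − n/(1ᵀC⁻¹1)]/(n−1). On a star tree both ratio and
expectation reduce to the common branch length, so K = 1 identically.
Significance is by tip-label permutation — 1,000 permutations by default,
with the observed statistic included in the null set, so p ≥ 1/1001. The
permutation loop is vectorised as batched quadratic forms (statistically
identical to a loop).

**Pagel's lambda** comes from a Gaussian mixed model with a fixed
intercept, a species effect with covariance s2_phylo·C, an i.i.d. study
effect, and an i.i.d. residual. All full conditionals are conjugate:
normal draws for location terms, inverse-gamma draws for variances with
the univariate inverse-Wishart prior (V, nu) read as
inverse-gamma(nu/2, nu·V/2). Defaults follow the reference settings:
20,000 iterations, burn-in 2,000, thinning 20 (900 retained samples per
chain), species/study priors V = 1, nu = 0.02, and a N(0, 1) prior on the
intercept — a printed nu for a fixed effect has no meaning in this
parameterisation and is ignored. The residual and observation-level priors
default to V = 1, nu = 0.002, the conventional weakly-informative setting
for units-level variances. Lambda is computed per retained sample as
s2_phylo/(s2_phylo + s2_resid); the study variance is design-induced and
excluded from the denominator by default (`lambda_includes_study=True`
switches the convention, since the original denominator choice is
unstated).

Two caveats documented on purpose. First, with replicated observations per
species the species term absorbs *any* repeatable species-level variance,
phylogenetically structured or not, so lambda is best interpreted at one
observation per species (as in the signal analyses here), where the
residual is exactly the non-phylogenetic species-level noise. Second, with
few species the posterior is prior-sensitive; the nu sweep
(10⁻⁶, 0.002, 0.02, 0.2, applied to the G-side priors with the residual
prior held fixed) quantifies this rather than hiding it. A zero-variance
trait vector is flagged degenerate instead of crashing.

**Diagnostics.** HPD intervals are the shortest sorted-sample window.
R-hat uses the pooled-variance estimator var⁺ = (n−1)/n·W + B/n and is
reported as max(1, sqrt(var⁺/W)): values below 1 arise only from
finite-sample noise, and flooring makes identical chains report exactly 1.
Chains with any component at R-hat ≥ 1.1 are flagged, never silently
accepted. Lag-1 autocorrelation of the retained samples is reported per
component.

**Regression.** The optimal-vs-self-regulated P:C regression pairs the two
traits by (species, study, sex, within-group occurrence) and adds the
predictor as a fixed slope plus a row-level "observation" random effect
(prior V = 1, nu = 0.002). The observation term and the residual are
weakly identified from each other and are both prior-regularised; the
slope posterior, which is the quantity of interest, is insensitive to how
that variance splits. A constant predictor is an error.

## Synthetic data: what it emulates, and what it does not

The generator produces single-peaked Gaussian performance surfaces sampled
along diet rails — rays of fixed P:C ratio through the origin, sampled at
several total-intake levels, with the point at total intake d on rail r at
P = d·r/(1+r), C = d/(1+r) (so P + C = d; "dilution" is total intake,
which is also how rail designs are usually described). Defaults place the
peak at P:C = 1:2 with lifespan-scaled heights (baseline 20 d, peak +30 d)
over a 7-rail × 8-dilution design spanning 1:8 to 8:1 — the shape of
typical published designs; extents are parameters because source-figure
units vary. Rendering fits an exact spline, discretises into equal-width
value bands between the predicted min and max (band label = bin midpoint,
mimicking published legends), paints flat palette colours on pure white,
and keeps per-band masks as ground truth. Trees are unit-rate pure-birth;
traits evolve as MVN(0, sigma2·C) or its lambda-scaled version
(off-diagonals × lambda).

Real figures differ in ways the generator deliberately does not emulate:
anti-aliased band borders, axis ticks and text overlapping the plot,
JPEG-style compression noise, non-Gaussian and multi-peaked surfaces, and
legends whose band spacing is uneven. Passing round-trip tests therefore
establishes that the pipeline is internally consistent and recovers known
optima from clean banded rasters — not that segmentation is robust to
arbitrary published artwork, which still needs the per-figure visual check
the manual band-assignment step forces anyway.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale chosen to exercise the
estimators meaningfully: 50-tip trees with 500 trait replicates for the K
calibration; 10 replicate fits per lambda endpoint at the full reference
chain length; 100 seeded render-extract-validate replicates (160×160 px,
250 fitted points, B = 100) for the round-trip rate; 100 random 6-tip
trees for the K oracle; 10⁴ retained samples for the conjugacy check. All
generators and samplers are bit-reproducible under a fixed seed (single
chain); multi-chain runs derive chain seeds as seed + chain index.

## Known limitations

- Strictly two nutrients; the trigonometry does not generalise here to
  n-nutrient mixtures.
- No OCR of axis labels or legends; calibration and band values are user
  input by design.
- The mixed model is univariate-response Gaussian; no multivariate or
  non-Gaussian families.
- Maximum-likelihood lambda is not implemented; the Bayesian posterior is
  the estimator, checked against simulation truth rather than an ML
  optimiser.
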