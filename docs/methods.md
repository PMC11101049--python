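# Methods

This note documents the models implemented in `metanema`, the choices
made where the procedure admitted more than one reasonable reading, and
what the synthetic-data tests do and do not establish.

## Coordinates and distances

Lake positions (WGS84 lat/lon) are projected with an equirectangular
ellipsoidal approximation about the domain's mean latitude:
x = N(lat̄)·cos(lat̄)·Δlon, y = M(lat̄)·Δlat, with M and N the WGS84
meridional and prime-vertical curvature radii (km). Over the ≲300 km
extents this package targets, planar distances agree with true WGS84
geodesics (a Vincenty inverse solver is included for reporting
ellipsoid maxima) to well under 0.5%; the test suite checks this
against geodesics frozen from an independent implementation of
Karney's algorithm. The default projection origin is (min lat,
min lon) of the input, which makes all planar coordinates nonnegative;
inter-lake distances are invariant to this choice.

## PCNM basis

The truncation constant for distances beyond the MST threshold *t* is
4*t*, the canonical convention for principal coordinates of neighbour
matrices (the data source for the analysis did not need to state it).
Eigenvectors are returned unit-norm with a deterministic sign (largest
component positive); GLM fits, deviance statistics and BIC ranking are
invariant to per-predictor scaling, so this convention does not affect
selection. Eigenvalues are reported on the scale of the Gower-centered
matrix (km² units), because the large/medium/small cutoffs
(25 000 / 1 000 by default, configurable) are meaningful only on that
scale. The medium band is closed, [1 000, 25 000]. Axes with
eigenvalue ≤ 1e−8·λ_max are discarded as numerical zeros; negative
axes (negative spatial autocorrelation) are out of scope. On a
75-site geometry this leaves at most 74 axes, of which typically
roughly 40–45 are positive.

## Binomial GLMs and forward selection

Fits use iteratively reweighted least squares (statsmodels) to a
relative deviance change of 1e−8 or 100 iterations. For 0/1 responses
the saturated log-likelihood is zero, so BIC is computed as residual
deviance + p·log n. `boundary_fit` flags any fitted probability within
ε = 1e−10 of 0 or 1 (configurable); this is the operational definition
of "numerically indistinguishable from zero or one" and, together with
non-convergence and outright fit failure, constitutes condition (iii)
of the forward procedure. The remaining candidates are re-ranked by
BIC at every step (rather than frozen at the first ranking; the audit
trail records enough to replay either). Walking the ranking stops at
the first candidate that fails the BIC drop or the significance test —
later candidates cannot have a lower BIC — whereas condition-(iii)
failures are skipped in favour of the next candidate. Ties in BIC are
broken by candidate order (spatial axes ascending, environmental
variables in input column order). Predictors are not standardized:
selection is invariant to affine predictor scaling given full rank,
and rank-deficient designs are rejected naming the collinear column.

## Deviance partitioning

The five per-species selections are merged (duplicate columns dropped
with a warning) into a full model; total = adj-D² of that model, in
percent. Each subset's unshared fraction is total minus the adj-D² of
the model refitted without that subset's variables, with the
adjustment recomputed using the reduced model's own coefficient count;
an empty subset contributes exactly 0. Shared = total − Σ unshared.
Negative shared or unshared values are legitimate (suppression);
nothing clamps them at this stage. The identity
shared + Σ unshared = total holds to 1e−10 in floating point.

## Moran's I

Weights are the raw binary MST-threshold adjacency (no row
standardization) and the variance is the classical normality-
assumption formula, with a two-sided normal test; both follow the
package contract even though other implementations row-standardize
and/or use the randomisation (kurtosis-corrected) variance — an
optional `row_standardize` flag reproduces the row-normalized observed
I for comparison. For degenerate weight structures where the
normality variance vanishes (e.g. a complete graph), the p-value is
reported missing rather than divided by zero.

## Zero-one-inflated beta regression

The likelihood factorizes over the point masses and the interior, so
the maximum-likelihood fit optimises each part separately (logistic
parts by BFGS; the interior beta regression by L-BFGS-B from a
moment-based start plus ±1 perturbations of the log-precision).
logit(p0), logit(p1) and logit(μ) share the same covariate design
(intercept, +x, or +x+x²; the quadratic always contains the linear
term); log φ is intercept-only. A part is dropped when its boundary
value is absent from the data. Covariates are standardized inside the
cross-species and elevation wrappers — the spanned design space, hence
the selection, is affine-invariant, while raw altitude in metres
squared would make the optimisation needlessly ill-conditioned.

Model choice among null/simple/quadratic follows the Δ ≥ 4 rule: the
lowest-criterion candidate replaces the null only if it is at least 4
units lower. The default criterion is BIC from the ML fit; a seeded
random-walk Metropolis sampler with weak normal priors (sd 10)
provides a DIC (D̄ + pD, pD = D̄ − D(θ̄)) when requested. Absolute
Bayesian-criterion magnitudes are sampler- and prior-dependent and are
not reproduced; the Δ-rule decision is the scientific content.
Unshared adj-D² fractions are divided by 100 before the fit and
negative fractions are clamped to 0 (the mixture's support is [0,1]),
with the clamped count reported; the complementary Spearman statistics
use the unclamped values.

## Smoothing-spline GAM

The smooth is a natural cubic smoothing spline (Reinsch/Green–Silverman
penalty on the unique predictor values, tied predictors handled by
knot weights), computed through the Demmler–Reinsch eigendecomposition
of the symmetrized penalty — numerically stable from the interpolation
limit to the least-squares-line limit. The penalty is tuned by
bisection so the hat-matrix trace equals the target df + 1 (default
target 4, i.e. trace 5 counting the unpenalized constant and linear
components); the trace-based convention matches the reference R
smoothing spline, against which the fitted values were verified to
~1e−5 on the bundled survey data. Reported statistics: a parametric
p-value (t-test on the OLS slope), a nonparametric p-value (F-test of
the smooth against the line with 3 numerator df), a Gaussian-profile
BIC n·log(RSS/n) + trace·log n, and adj-D² with the trace as the
effective parameter count. Implementations differ in how they count
spline df and parameters, so absolute BIC/adj-D² values shift by a few
points across conventions; the bundled-survey GAM here reproduces the
qualitative pattern (female proportion explains > 50% of adjusted
deviance in Moran's I even after removing the most extreme species;
body size explains < 20% and is not significant).

## Trait and filter conventions

AFP (mean of per-lake female proportions, over lakes with ≥ 1 adult of
the species) and OFP (pooled females/adults) are species-level
statistics; the ≥ 6-adult rule applies per species overall for
species-level eligibility, and *per species per lake* only in the
per-lake community summaries, where the abundance-weighted female
proportion additionally requires ≥ 6 adults in the lake overall.
Distribution models and Moran's I require occupancy of ≥ 4 lakes and
≥ 6 adults. Taxa flagged `excluded` (parasitic families not determined
to species, indeterminate individuals) are carried in the data model
but omitted from statistics. Body mass uses B = L·a²/(1.6·10⁶) μg
from length and greatest diameter in μm, unless a mass column is
supplied. Per-lake body-size summaries are relativized by the maximum
across lakes so the largest lake scores exactly 1, making the variable
admissible for the zoib mixture. "Most extreme" observation for
removal analyses: the minimum female proportion, or the maximum body
mass.

## Synthetic surveys

The generator draws a clustered point process in an elongated band
(defaults 250 × 40 km, 75 lakes, altitudes 1620–2990 m), Gaussian
environmental fields with exponential spatial covariance (range 30 km)
plus altitude-linked trends, and 31 species with female proportions
from a mixture with mass at exactly 1 (default 0.30) over a
beta-distributed interior skewed toward 1, and log-normal body masses
(median ≈ 4 μg, spanning roughly 0.8–80 μg). Occupancy follows
logit P = α_s + β_env·env + κ(1−f_s)·u_s, where u_s is a random
unit combination of the geometry's large-scale PCNM axes with random
sign: the *strength* of large-scale clustering is the deterministic
κ(1−f_s) (κ = 12 by default), its orientation random. Abundances are
1 + negative binomial per occurrence, adults binomial of abundance
(fraction 0.72), females binomial(adults, f_s). One seeded generator
threads through all draws; identical seeds give identical bundles.

What the synthetic tests show: the full stack (PCNM → selection →
partition → rank correlation) recovers a negative female-proportion →
large-scale-deviance relationship in ≥ 90% of replicates when female
proportions span (0, 1), and Moran's I is correctly calibrated (≈ 5%
false positives, mean −1/(n−1)) when both the spatial term and the
environmental effect are switched off — with an autocorrelated
environment and β_env > 0, occupancy is genuinely spatially structured
(the dispersal-sufficiency scenario), so that configuration is not a
spatial null. What they do not show: robustness to the chemistry and
lithology structure of real mountain lakes, to observation error in
sex determination, or to taxonomic lumping; the environmental fields
are exchangeable Gaussians, not limnological variables with realistic
cross-correlations.

## Problem sizes used in the checked runs

Oracle comparisons run on 10–20-site geometries and n ≤ 75 GLMs;
noise-rate simulations use 500 replicates (n = 75, 10 candidates);
zoib recovery uses 200 replicates at n = 500; trait-signal recovery
uses 10 full-pipeline replicates at the default 75-lake/31-species
size; Moran calibration uses 200 generated surveys of 8 species.

## Known limitations

* The forward procedure inherits best-of-k selection optimism: with k
  noise candidates the probability that at least one enters is
  ≈ 1 − (1 − p)^k, p ≈ 0.038 at n = 75 — the per-candidate admission
  rate is what the α = 0.05 + BIC guard controls.
* adj-D² can exceed small negative bounds or behave erratically when
  p approaches n; the pipeline refits rather than reusing adjustments
  across models, but very sparse species (near the 4-lake filter) give
  noisy partitions.
* The Metropolis DIC is a convenience approximation (single chain,
  fixed step); posterior summaries other than DIC are not exposed.
* Boundary-probability detection uses a fixed ε; genuinely separable
  configurations are excluded by substitution, not penalized
  regression.
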