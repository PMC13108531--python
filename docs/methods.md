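# Methods

This note documents the models implemented in `foreststab`, the synthetic
data the test suite exercises them on, and the numerical and design choices
made where the procedure admitted more than one reasonable reading.

## Study design emulated

Two observation layers are represented. The adult layer is a single large
plot divided into non-overlapping 20 m × 20 m quadrats, censused every
5 years: every woody stem with DBH ≥ 1 cm is mapped and measured. The
seedling layer is a set of 1-ha plots, each divided into a 10 × 10 grid of
10 m subplots; half the subplots are selected in a checkerboard and each
selected subplot holds four 1 m × 1 m seedling quadrats (6 plots × 50
subplots × 4 = 1200 quadrats), censused annually for height. A stem is an
adult from the first census at which its DBH reaches 1 cm; stems that
graduate are excluded from seedling analyses entirely rather than censored.

Soil sampling combines regular points at the centres of alternate quadrats
with clustered points: per 100 m block, two parents each spawn seven samples
at 0.16, 0.33, 0.61, 1.03, 2.66, 6.22 and 7.67 m along a randomly chosen
diagonal (50 blocks × 2 × 7 = 700 cluster samples on a 500 m × 1000 m
plot). The checkerboard phase is configurable; a full checkerboard on a
25 × 50 grid has 625 cells and no exclusion rule is imposed on it.

Coordinates are plot-local, origin at the southwest corner; quadrats are
half-open intervals so every interior stem maps to exactly one quadrat.

## Diversity

Per quadrat: richness S, Shannon entropy H in nats, Hill evenness e^H / S,
effective species number e^H. Seedlings are weighted by individual counts,
adults by basal area (π/4)·DBH²; the weighting is overridable. Each census
record is one stem; ramets are not distinguished. Empty quadrats propagate
as missing values, not zeros.

## Productivity and the stability partition

Adult per-stem productivity is the between-census increment of allometric
aboveground biomass AGB = a·DBH^b. The allometry coefficients are
configurable with default (a, b) = (0.25, 2.5); every stability quantity is
a ratio that is invariant to the scale a, and the tests avoid depending on
either coefficient. Seedling productivity is the annual height increment in
cm. Recruits contribute their first recorded AGB/height in the interval of
first record (size treated as zero at the interval start); stems absent
from the later census contribute nothing. Negative increments are kept by
default (a truncate-at-zero option exists) and logged.

Species productivity sums conspecific surviving individuals; community
productivity sums species. Series are detrended per quadrat and per series
by OLS on calendar year, and all SDs are sample SDs (n − 1) of the
residuals — the denominator convention is a package choice. Then

- community stability = μ_comm / σ_comm,
- population stability = μ_comm / Σ σᵢ,
- asynchrony = 1 − σ_comm² / (Σ σᵢ)².

The asynchrony form follows the community-wide synchrony statistic of
Loreau & de Mazancourt, which is the only reading consistent with the
stated [0, 1] range; mirror-fluctuating two-species series give 1,
proportional series give 0, and single-species quadrats are defined as 0.
Quadrats with σ = 0 (a perfectly linear or constant community series, to a
1e-10 relative float tolerance) or fewer than 3 intervals are flagged
degenerate and excluded listwise downstream, with counts logged.
Interval coarsening sums productivity in non-overlapping 3/4/5-year
windows, dropping a trailing partial window.

## Geostatistics

Nutrient concentrations are log-transformed before variogram estimation and
kriging, and all downstream models and Monte-Carlo draws operate on that
scale. The empirical variogram is Matheron's estimator on distance bins;
model fitting is weighted least squares with weights ∝ √(pair count) over
the exponential, spherical and gaussian families, selecting the lowest SSE
(the family is configurable and the selection logged). Range parameters use
the classical forms (e.g. 1 − exp(−h/r) for the exponential), not
effective-range reparameterisations.

Ordinary kriging solves the standard system with the unbiasedness
constraint via one LU factorisation shared across targets; weights sum to 1
to 1e-10, the no-nugget predictor interpolates exactly with zero variance
at data points, and collocated duplicates are averaged. Monte-Carlo
propagation draws X ~ N(X̂, σ_k²) independently per quadrat — deliberately
ignoring cross-quadrat prediction covariance, matching the stated
procedure — refits the registered downstream model per draw (500 by
default) and reports medians and 95% intervals; failed draws are dropped
and counted with a warning past 5%.

## Dissimilarity

Bray–Curtis dissimilarity is decomposed after Baselga into balanced
variation min(B,C)/(A+min(B,C)) and the abundance-gradient remainder, with
A = Σ min, B and C the asymmetric surpluses; the components are additive by
construction. The Mantel statistic is Spearman's ρ of the off-diagonal
triangles by default (Pearson switchable; the choice of rank correlation
follows the ρ symbol convention) with a permutation test; computation
delegates to scikit-bio when available, with an equivalent in-package
fallback. PERMANOVA partitions the Gower-centred inner-product matrix by
the hat matrix of the predictor design, which accommodates a continuous
stability gradient (regression-style) as well as groups; p-values use the
add-one convention. Pairwise stability differences enter as |Δ ln
stability| distances (configurable transform).

## Regression layer

Predictors are centred and scaled (reversible transform records are kept);
count densities use log(x+1), continuous crowding indices log(x + smallest
positive value). Bootstrap CIs are percentile-based case resamples (10,000
by default). VIF is 1/(1 − R²) with perfect collinearity reported as ∞.

Queen contiguity joins the 8 edge- and corner-adjacent quadrats; weights
are row-standardised (islands flagged). The SAR error model y = Xβ + u,
u = λWu + ε is fitted by maximising the likelihood concentrated over λ
using the real eigenvalues of the row-standardised weights (via the similar
symmetric matrix); β SEs come from the GLS information matrix, the λ SE
from the numerical curvature of the concentrated log-likelihood, and
AIC = 2(p + 2) − 2ℓ. Fixing λ = 0 reproduces OLS exactly. Beta regression
(logit mean link) delegates to statsmodels' `BetaModel`, with boundary
responses shrunk by (y(n−1)+0.5)/n.

The crowding index is NCI = Σⱼ BAⱼ/(dᵢⱼ·BA_focal) over neighbours within
10 m — the reading under which larger, closer neighbours crowd a small
focal tree more — with Σ BAⱼ/dᵢⱼ exposed as an alternative and a 0.1 m
distance floor for coincident stems. The seedling survival design models
first-year survival of newly germinated cohorts on conspecific and
heterospecific same-quadrat counts, one nutrient at a time, its products
with both densities, and log initial height, with species, subplot and
cohort-year random intercepts; the adult growth design models ΔDBH on
crowding indices, nutrient, interactions, initial DBH and a fixed year
effect, for focal stems ≥ 10 m from the plot boundary, with individual,
species and quadrat random intercepts.

Mixed-model numerics are delegated: the binomial-logit GLMM uses
statsmodels' variational Bayes mixed GLM (posterior means reported;
marginal R² uses the logit-link residual variance π²/3), and Gaussian LMMs
use MixedLM. statsmodels has no exact fitter for fully crossed Gaussian
random intercepts, so the adult model uses the species factor as the
grouping variable with quadrat and individual as within-group variance
components — an approximation to the crossed structure; a singular fit
triggers a flagged refit without the variance components.

## Piecewise SEM

Component families per stage mirror the analysis design: seedling responses
are LMMs with subplot random intercepts, adult responses SAR error models
(their pseudo-R² is the squared correlation between the fixed-effect trend
and the response — a documented convention, since none is standard). For
each response all parent subsets are fitted and the minimum-AIC subset
kept, ties broken by fewer parameters then term order. The d-separation
basis set contains one claim per non-adjacent pair (the later variable in
topological order is the response, conditioning on the parents of both);
declared correlated-error pairs — here the nutrient forms — are excluded.
Claim p-values come from the coefficient test of the would-be edge in the
response's component family; Fisher's C = −2 Σ ln p with df = 2k and an
upper-tail χ² p, where C = 0, df = 0, p = 1 for a saturated model. Total
effects accumulate coefficient products over all directed paths, equal to
B(I − B)⁻¹ on the standardized scale. The default candidate graph allows
nutrients → {richness, evenness, population stability, asynchrony} and
{richness, evenness, population stability, asynchrony} → community
stability; it is fully configurable via the `A -> B` / `A ~~ B` text format.

## Synthetic generator

The generator provides ground truth, not estimates of any real forest.
Nutrient fields are stationary Gaussian random fields simulated by Cholesky
factorisation on quadrat centres and sample points jointly (sill, range,
nugget and family configurable; nugget noise added to observations only).
Species pools follow a log-series (default shape 0.95) or geometric
rank-abundance law, producing the many-rare / few-abundant structure.

Seedling dynamics: Poisson recruitment (default 3 germinants · m⁻² · yr⁻¹,
within the range implied by tens of thousands of seedlings across 1200
quadrats over 16 years), log-normal initial heights (median 15 cm), annual
Bernoulli survival with a logit-linear predictor over log(x+1) conspecific
and heterospecific counts, the z-scored nutrient, their interactions and
log height, plus species/subplot/year Gaussian random intercepts (SDs 0.3 /
0.2 / 0.2); survivor height growth has a linear trend and year shocks mixed
between a community-wide and a species-specific component by a synchrony
weight, which is how the asynchrony gradient is induced. Adult dynamics:
initial DBH from a truncated power law (exponent 1.8, ≥ 1 cm), 5-yearly
ΔDBH with the crowding model (indices computed by the same
`crowding_index` code the estimator uses), 5% interval mortality and
proportional recruitment. Density covariates in the generator are on the
log(x+1) scale while the estimator z-scores them afterwards; an affine
rescaling that preserves the signs the recovery tests check. The default
census spans are annual 2008–2023 for seedlings and five 5-yearly adult
censuses from 2011 — four intervals, the minimum comfortably above the
three needed for detrended SDs.

Scenario presets: `null` sets every nutrient coefficient to zero;
`paper-like` makes inorganic P facilitative for heterospecific
neighbourhoods (positive survival, positive HSD × nutrient) and organic P
competitive (negative), with weaker N-form interactions.

What the generator does **not** emulate: light competition and canopy
structure, topography, mycorrhizal dynamics, temporal soil-nutrient change,
species-specific allometry, and spatial aggregation of recruitment. Passing
tests therefore demonstrate that the estimators recover known effects under
the stated stochastic model, not that any particular field system behaves
this way.

## Problem sizes and tolerances in the test suite

Simulation-backed checks run at reduced but statistically adequate sizes
chosen as package defaults: SAR λ recovery on a 20 × 20 lattice over 20
seeds; GLMM interaction-sign recovery at ≈ 5000 designed seedlings per
seed over 20 seeds; Fisher's C type-I calibration over 200 replicates of a
correctly specified four-variable graph at n = 100; null-scenario
calibration over 200 generator runs (64 seedling quadrats with bootstrap
CIs, an 8 × 8 adult lattice with SAR z-tests). Exact-algebra assertions use
1e-8 (kriging vs dense solve), 1e-9 (stability partition identity) and
1e-10 (path-effect accumulation, kriging weight sums). Permutation p-values
are compared with exhaustive enumeration within 0.05 at n ≤ 6.

## Known limitations

- The SAR λ standard error is a curvature approximation that ignores
  β–λ cross-information; fine for the z-screens used here.
- The variational GLMM understates posterior SDs relative to full ML;
  sign and magnitude screening is unaffected at the sizes used.
- Crossed Gaussian random intercepts are approximated (above).
- PERMANOVA with a continuous predictor permutes raw distances, which is
  exact under the global null only.
- Kriging Monte-Carlo draws ignore cross-quadrat covariance and so
  understate the spatial coherence of prediction error.
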