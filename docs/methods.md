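# Methods

`trophicrange` implements a pipeline that links trophic interactions to a
focal species' geographic distribution and projects range change under
coupled climate/land-use scenarios.  This note documents the models, the
numerical choices, and what the synthetic study does and does not emulate.

## Spatial model

All rasters live on an abstract equal-area grid: 0-based (row, col) indices,
origin top-left, square 1-km cells.  Distances are Euclidean in cell units
(km).  The coarse "historical" grid aggregates the fine grid in exact
`coarse_factor` × `coarse_factor` blocks (block mean).  The canonical factor
is 50 (50-km cells over a 1-km grid) and that is the default; desk-scale
studies use factors of 10–25 so the coarse grid retains enough cells
(≥100) to fit the historical model.  Rasters are exchanged as single-band
ESRI ASCII grids (`.asc`, nodata −9999), a plain-text format every GIS
reads; tables as CSV.

## Dietary energetics

Within a study, the relative frequency of occurrence of item *i* is
rF_i = f_i / Σf and the relative volume rV_i = v_i / Σv.  Studies lacking
volumes get rV imputed from an ordinary least-squares line rV ~ rF fitted on
items pooled over complete studies, clipped at zero and renormalized per
study; the pooled Pearson r is reported with a percentile bootstrap 95% CI
(resampling items).  OLS-plus-renormalization is the minimal monotone model
of the frequency–volume relationship; the functional form is isolated in one
function so it can be swapped.

Relative estimated dietary energy content:

    rEDEC_i = CF_Ei · rEDC_i / Σ_j (CF_Ej · rEDC_j)

with rEDC_i = rV_i by default (an optional volume-correction factor CF_V can
enter before renormalization).  Correction factors are looked up
item-specifically, falling back to a category default, else an error —
mirroring a sparse supplementary table.  The representative diet of
subpopulation *Subp* weights studies by their sampling-unit count *Z*
(number of scats or stomachs):

    rEDEC_SubpS = Σ_i Z_i · rEDEC_Si / Σ_i Z_i ,

with rEDEC_Si = 0 when species *S* is absent from study *i*.  Items resolved
only above species level stay out of per-species shares (they form the
"unresolved" remainder) but are kept in category and wild/human-origin
summaries.

## Diet–environment associations

Covariates are layer means over cells whose center lies within 18 km of the
site (inclusive).  On a 1-km grid this is 1009 cells; the continuous-circle
area is π·18² ≈ 1018 km², and no lattice rule reproduces 1018 exactly —
the inclusive rule is the closest and the brute-force count is the test
oracle.  Collinear covariates are dropped by iterating "remove the highest
VIF > 10" (VIF = 1/(1−R²) of each covariate on the others, with intercept).
Every subset of the retained covariates (capped at 8 terms to bound the 2^k
enumeration) is fitted by OLS and ranked by AICc with k = terms + intercept
+ residual variance.  Candidates with ΔAICc < 3 receive renormalized Akaike
weights; coefficients are averaged conditionally (only over models
containing the term) with the unconditional-variance standard error
√(Σw(se² + (β−β̄)²)).  Significance is reported both as the averaged-model
z-test and the best model's t-test, since the two can disagree; neither is
asserted.  Diversity of category shares: Shannon H = −Σp ln p, Simpson
1 − Σp², inverse Simpson 1/Σp².

## Food-species distribution models

Occurrences collapse to 1-km presence cells (a cell with ≥1 point counts
once); species with <50 presence cells are excluded.  Pseudo-absences are
sampled uniformly without replacement, one per presence, from cells whose
nearest-presence distance lies in (3, 10] km — background under the same
spatial bias as the presences.  Variable selection: a pairwise |r| > 0.7
filter (dropping the member with the higher mean absolute correlation, ties
by name), then the best 6 by AIC of univariable binomial GLMs with linear +
quadratic terms.  The ensemble is deliberately small and documented: a
standardized quadratic logistic regression and shallow gradient-boosted
trees, weighted by their true skill statistic (TSS = sensitivity +
specificity − 1) on a held-out 20% stratified split; the classification
threshold maximizes TSS on the *training* predictions so held-out skill is
unbiased.  This is an honest simplification of large ensemble platforms,
chosen for reproducibility at desk scale.

## Biotic layers

For food category *c* in subpopulation *Subp*:

    Biotic_c(x) = Σ_{S∈c} rEDEC_SubpS · HS_S(x),

the diet-weighted sum ("combining" = summation, preserving energy-flow
semantics; Bio_All_species is the sum over categories).  The binary variant
replaces rEDEC_SubpS by 1{interaction observed in Subp} and is *not*
normalized by species count (documented choice).  Species without a usable
habitat model contribute nothing (logged).  Scenario layers always combine
scenario suitabilities with current diets: diet composition is not
re-estimated under scenarios.  The two proxies are compared per category by
the AIC of univariable binomial GLMs (logit link, linear + quadratic on the
standardized layer).

## The hierarchical focal-species model

**Historical stage.**  The coarse range grid (historical presence vs
extirpated/absent) is sampled with an environmentally stratified,
class-balanced design: quantile bins of Clim_3, Clim_4, Clim_8, Clim_9
(isothermality, temperature seasonality, mean temperature of the wettest and
driest quarters) are intersected into strata; within each stratum holding
both classes an equal number of each is drawn; strata lacking a class are
skipped.  The bin count is configurable (2–3 at desk scale) since the
stratum construction is not otherwise pinned down.  A Bayesian logistic
regression of status on the four climate variables (linear + quadratic on
standardized values, Normal(0, 2.5) priors, Normal(0, 5) intercept) yields
posterior means and SDs that become the fine-scale priors, transferred
*unmodified* — equal confidence in historical and current data.  The
standardization constants are recorded in the `PriorSet` and reused verbatim
at the fine scale, so both scales share one coordinate system; without this
the prior transfer would be meaningless.

**Occurrence preparation.**  Fine-scale presences are deduplicated 1-km
cells, water-masked, capped at 2000 per subpopulation (uniform subsample);
pseudo-absences are drawn per subpopulation, one per presence, from
non-presence cells within 5 km of any presence.  The 80/20 train/validation
split is stratified by subpopulation separately for presences and absences,
with a largest-remainder allocation so the global 80% is exact (24,908
presences split into 19,926 + 4,982).

**Fine-scale models.**  Bayesian binomial GLMMs (logit link) with a
subpopulation random intercept u_j ~ Normal(0, σ_u), σ_u ~ HalfNormal(1);
the grouping factor is a documented choice (subpopulation is the only
grouping in the data model) with a switch to disable.  Climate enters with
linear + quadratic terms; land-use and biotic variables linearly (the
bell-shaped response is expected in climate, not in the energy layers).
Land-use and biotic blocks are screened to the four best uncorrelated
candidates by univariable AIC; the screening model uses subpopulation fixed
intercepts as a stand-in for the mixed model — adequate for ranking and far
cheaper than MCMC per candidate.  Variants: abiotic + biotic, abiotic,
biotic, null; hierarchical variants put the historical priors on the climate
coefficients, everything else gets the weakly informative defaults.

**Sampling.**  Posteriors are sampled with emcee using posterior-specific
proposals.  Fixed-effects-only posteriors (historical model, null model,
no-random-intercept fits) are near-Gaussian: L-BFGS finds the MAP (analytic
gradient), the exact Hessian whitens the space, and a lightly inflated
Student-t independence proposal mixed with random-walk Metropolis samples
it at ~0.6 acceptance.  Random-intercept posteriors have the well-known
funnel in (u, log σ_u) — no single Gaussian approximation covers both the
σ_u → 0 neck and the wide regime — so the independence proposal is a
*mixture of conditional Laplace approximations*: log σ_u is gridded (28
points over σ_u ≈ 0.001–7.4), the conditional mode and Hessian of (β, u)
are computed analytically at each grid point (damped Newton, warm-started
along the grid), grid weights come from the conditional Laplace evidence, and a
proposal draws a grid cell, a jittered log σ_u and a Student-t perturbation
of the conditional mode.  A covariance-matched random-walk move guards
local exploration.  Walkers evolve independently under all moves and are
treated as parallel chains for split-Rhat, effective sample size and MCSE
(ArviZ); a fit is flagged non-converged above Rhat 1.05.  Defaults (32
walkers, 400 adaptation + 900 sampling steps) give min ESS of several
thousand and Rhat ≲ 1.01 on the desk-scale GLMM in a few seconds, in both
the degenerate-σ_u and well-identified regimes.  WAIC comes from the
pointwise posterior log-likelihood; ΔWAIC standard errors from the
pointwise differences (models must share the response vector).

**Threshold.**  The presence/absence cutoff is the 10th percentile (lower
interpolation) of predicted probability at training presences, so 90% of
training presences score at or above it — training TPR = 0.90 by
construction, up to one presence of discreteness (and exactly attained only
with continuous scores; with heavy ties the rule guarantees TPR ≥ 0.90).

## Projection and sensitivity

Nine scenario runs (3 SSPs × 3 modes) plus the current run.  Per mode the
non-changing block is pinned to current layers: abiotic-only uses current
biotic layers, biotic-only current abiotic layers.  Predictions are masked
to 200 km around the current binary distribution to avoid extrapolating
trophic information where there are no diet data; the current-conditions
threshold is applied unchanged to every run.  Descriptors per run and
subpopulation: area (presence cells × cell area), % change vs current, %
inside the protected mask, % of predicted cells holding an observed
presence.  The biotic sensitivity analysis refits the abiotic + biotic model
with the biotic predictors replaced by lower then upper uncertainty bounds
(in-pipeline source: the 2.5/97.5 percentile envelope of the food-SDM
ensemble members) and reports coefficient shifts plus the Pearson
correlation of each bound run's prediction map with the original.

## The synthetic study and what it shows

The generator emulates every input with known truth: Gaussian-smoothed white
noise gives spatially autocorrelated climate fields (plausible units) and
logistic-transformed fields give land-use fractions; "Natural Landscape" is
the 11×11-cell window mean of an urban<0.5 indicator and is recomputed for
scenarios that change Urban.  Food species follow logistic niches (linear +
quadratic on standardized layers).  Diet studies draw item counts from a
multinomial around Dirichlet-jittered true shares; rV = rF + Gaussian noise
clipped and renormalized, with a single global noise scale solved (Brent's
method) so the pooled rF–rV correlation hits the configured target (0.86 by
default) — the naive errors-in-variables scale is biased by the clipping
and the between-study share variance.  The exact count
round(missing_fraction × studies) of studies has all volumes masked.  Focal
presences are Bernoulli draws from a known abiotic + biotic logistic truth;
the historical range redraws the block-aggregated *climate-only* probability
at the coarse scale, so historical data are informative about climate
without duplicating the fine data.  Subpopulations are contiguous
rectangles.

Default study conditions: 100 × 100 km landscape, 4 subpopulations,
8 food species across the five categories, 3 diet studies per subpopulation
(30% without volumes), focal occupancy ~20–25% (~2,000 training presences),
coarse factor 10–20.  Replicate-based checks (WAIC ordering and coefficient
recovery over 20 seeds) use a reduced truth — 2 climate, 2 land-use and
2 biotic predictors, ~4,000 training cells — so the replicates complete in
minutes; the full 4 + 4 + 4 design runs once in the end-to-end study.

Two caveats on what passing tests show.  First, balanced pseudo-absence
sampling is a case-control design: it identifies relative, not absolute,
probabilities, so the *intercept* of the generating model is not recoverable
(its credible interval reflects the 1:1 sampling ratio) while the slope
coefficients are; coverage checks count all parameters and pass on the
slopes.  Second, the generator omits features of real data — sampling bias
beyond what the annulus/buffer designs encode, observation error in diets,
temporal variation, species dispersal and diet plasticity under scenarios —
so passing tests demonstrate the machinery recovers known structure, not
that the ecological model is correct for any real system.

## Known limitations

- The ensemble has two members; uncertainty envelopes from member spread are
  correspondingly coarse.
- σ_u is weakly identified with few subpopulations (4 in tests); the
  half-normal prior does the regularizing.
- No spatial random fields beyond the subpopulation intercept; residual
  spatial autocorrelation within subpopulations is unmodelled.
- Scenario projections inherit the fixed-diet assumption; prey switching
  would damp the biotic signal.
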