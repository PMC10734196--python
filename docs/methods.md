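# Methods

## Scope and data model

The package analyses a two-group disparity in a binary outcome from
person-level survey records. The canonical application is overweight/obesity
(BMI ≥ 25 kg/m²) among women of reproductive age by urban/rural residence,
with categorical covariates (wealth, age group, education, media exposure,
contraceptive use, …), a positive sampling weight per record, and two
exclusion rules applied before any estimation: respondents flagged pregnant,
and records whose BMI (hence outcome) is missing. Missing covariate labels
trigger listwise deletion with a separately logged count so all model fits
share one sample. The outcome may alternatively be supplied precomputed; a
record carrying both a BMI and a conflicting precomputed outcome is rejected
rather than silently resolved. Input is comma-delimited text with a header;
category labels are whitespace-trimmed and then matched case-sensitively.

Categorical covariates enter models as reference-coded indicators (k − 1
dummies plus an intercept), with column labels `covariate=level`. A level
absent from the data keeps its (all-zero) column, because group-specific
fits must share one column layout for cross-group counterfactual
predictions; the encoder warns instead of dropping it.

## Weighting

Sampling weights multiply the Bernoulli log-likelihood (frequency-style
weighting in both score and information), which gives survey-weighted point
estimates. Point estimates are invariant to rescaling all weights by a
constant; variances are not, so by default weights are normalised to mean 1
over the fitted subset, putting reported standard errors on the sample-size
scale. Descriptive tables use weighted counts (sums of weights) and weighted
percents. Chi-square association tests deliberately use classical Pearson
statistics on unweighted counts: that is the computation consistent with the
published tables this package's checks reproduce, and the interval/bootstrap
machinery does not depend on it. No design-based (cluster/stratum) variance
estimation is attempted; the bootstrap resamples records, not clusters.

## Logistic fitter

The weighted logit is maximised by iteratively reweighted least squares
(Newton scoring) with convergence when max|score| < 1e−8 or the maximum
coefficient change < 1e−10, capped at 100 iterations; step-halving guards
the first iterations. Two failure modes are diagnosed explicitly rather than
reported as numbers: rank deficiency (QR-based, naming the collinear
columns) and quasi-separation (a coefficient drifting beyond ±15 on the
log-odds scale while the score has not converged). Wald intervals
(exp(β ± z·se)) are used for odds ratios, matching symmetric exp-scale
intervals; the covariance is the inverse observed information at the
optimum. The test suite checks the fitter against statsmodels GLM with
frequency weights as an independent oracle.

## Threefold decomposition

Let group 1 be the urban analogue and group 2 the rural analogue, and
D = ȳ¹ − ȳ² the weighted prevalence gap. The decomposition is reported from
the group-2 (rural) viewpoint by default — E weighted by rural coefficients,
C evaluated at rural means — with the mirrored viewpoint available.

Two modes:

* **linear** — group-specific weighted least-squares linear-probability
  fits; E, C, I from the summation formulas (see README). The additive
  identity E + C + I = D holds to numerical precision because fits include
  an intercept. This mode is the basis of the per-part algebra.
* **logit_counterfactual** (default for headline numbers) — group-specific
  weighted logit fits; components are contrasts of weighted mean predicted
  probabilities under counterfactual pairings, I is residual-defined, and
  each group's mean prediction equals its weighted observed prevalence (the
  intercept score equation), which is why the reported group means match the
  descriptive prevalence table.

The intercept difference B ("unobservables") is folded into C for the
three-component display and also reported separately; in counterfactual mode
it is isolated by a fifth pairing that swaps intercepts only.

Detailed per-covariate-level contributions are computed from the linear
algebra: E-part βⱼ²(x̄ⱼ¹ − x̄ⱼ²) and C-part x̄ⱼ²(βⱼ¹ − βⱼ²) per dummy column,
plus a Constant row for B. Under the counterfactual mode the linear parts
are rescaled by one global factor per component so they sum to the
counterfactual aggregates; this preserves the relative allocation while
keeping the detail-sum identity exact. Because reference-coded contributions
depend on the omitted category, an optional deviation-contrast normalisation
re-expresses each covariate's coefficients as deviations from their level
mean; this spreads the contribution over all levels (a binary covariate's
two levels split evenly), removes reference dependence, and leaves the
component sums unchanged.

When |D| < 1e−12 percent contributions are undefined and suppressed (flag
`percents_defined`); they are otherwise sign-preserving, so negative shares
and shares above 100% are reported as such.

## Bootstrap

Confidence intervals are nonparametric percentile intervals from resampling
records with replacement, stratified within group by default so both group
fits always have data (plain resampling is available). Replicates that fail
(rank deficiency after losing a rare level, separation, non-convergence) are
skipped and counted; more than 20% failures aborts with an error rather than
returning intervals from a biased subset. A minimum of 100 replicates is
enforced; the default is 200. Intervals are deterministic given the seed.
Analytic (delta-method) standard errors are out of scope by design.

## Synthetic generator and truth oracle

The generator emulates the motivating survey's structure: group membership
Bernoulli (urban share 0.42), covariates drawn independently within group
from group-specific level mixes, outcome Bernoulli(inverse-logit(β₀ᵍ + βᵍx))
with group-specific coefficients, Gamma(4) sampling weights with mean 1
(optionally group-dependent to exercise weighted estimation), a 7% pregnancy
rate and 3% missing-BMI rate so the exclusion pipeline is exercised, and a
BMI synthesised on the correct side of the 25 kg/m² threshold so deriving
the outcome from BMI reproduces the Bernoulli draw exactly. The default
configuration's mixes make the urban group wealthier, more educated and more
media-exposed, and its coefficients were set so the implied prevalences are
approximately 35.5% (urban) and 21.1% (rural) — a gap of about 0.144
dominated by the endowment component — matching the disparity pattern the
package is designed to analyse. Covariates are independent within group (no
copula): no dependence structure is asserted by the emulated design, and
independence keeps the truth oracle simple and recovery tests interpretable.

Ground truth comes from Monte-Carlo integration over the covariate mixes:
mean inverse-logit predictions under the four (mix, β) pairings give D, E
and C on the probability scale, I is the residual, and B uses an
intercept-swap pairing; per-component Monte-Carlo standard errors are
reported and an error is raised if they exceed a requested tolerance.
Linear-index-scale components are closed-form in the mean dummy vectors.
The truth oracle deliberately ignores sampling weights: the estimand is the
generating process, and weights in synthetic data are informative noise.

What passing recovery tests does not show: real DHS data have cluster and
stratum structure, covariate dependence, and informative weighting tied to
the sample design, none of which the generator produces; recovery therefore
validates the estimators under the stated process, not design-based
inference on a real survey.

## Problem sizes and numerical choices

The test suite validates component recovery at n = 100,000 against a
10⁷-draw oracle (tolerance max(0.01, 3·bootstrap se) per component) and
bootstrap interval coverage over 50 repeated experiments at n = 20,000 with
B = 200, judged against a two-sided binomial band around the nominal 95%.
The acceptance script uses n = 50,000 with B = 200 and a 2·10⁶-draw oracle;
these sizes give Monte-Carlo error well inside the reported tolerances while
keeping a full run in seconds to minutes on one CPU. Rendering rounds
half-away-from-zero (decimal-based, so 27.15 → 27.2 regardless of binary
float representation) with percents and chi-squares at 1 decimal and odds
ratios at 2 by default; underlying values are stored at full precision and
p-values below 0.001 render as "< 0.001".

## Known limitations

* No design-based variance (two-stage cluster sampling, strata); the
  cluster bootstrap is not implemented.
* No Fairlie-style sequential-replacement decomposition for binary outcomes.
* No imputation of missing BMI; no parsing of proprietary survey exports
  (users pre-export to CSV).
* Detailed contributions under the counterfactual mode rely on a global
  rescaling of linear parts, which is one of several defensible allocation
  conventions.
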