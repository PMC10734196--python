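# healthgap

Decomposition of rural–urban disparities in a binary health outcome —
weighted descriptive tables, chi-square screening, survey-weighted logistic
regression, and a threefold Blinder–Oaxaca decomposition with bootstrap
confidence intervals.

The package targets the analysis pattern common in Demographic and Health
Survey (DHS) work: one row per respondent (e.g. a woman aged 15–49), a
continuous BMI from which an overweight/obesity indicator is derived
(BMI ≥ 25 → 1), a positive sampling weight, a two-level residence variable,
and categorical covariates such as wealth quintile, age group, education,
media exposure and contraceptive use. Because the motivating microdata are
distributed under registration only, the package ships a synthetic generator
that draws DHS-like samples from a known group-specific logit process and
computes the true decomposition of the gap by Monte-Carlo integration, so
every estimator can be validated end to end without any download.

## The model

Within each residence group g ∈ {1 = urban, 2 = rural} the outcome follows a
weighted logistic regression

ln [P(Y)/(1 − P(Y))] = β₀ᵍ + β₁ᵍX₁ + … + βₙᵍXₙ,

fitted by iteratively reweighted least squares with the sampling weights in
both score and information. The prevalence gap D = ȳ¹ − ȳ² is decomposed
threefold, from the rural viewpoint:

- **Endowment (E)** = Σⱼ βⱼ²(x̄ⱼ¹ − x̄ⱼ²) — the part explained by different
  covariate levels, valued at rural coefficients;
- **Coefficient (C)** = Σⱼ x̄ⱼ²(βⱼ¹ − βⱼ²) + (β₀¹ − β₀²) — different returns
  to the same characteristics, evaluated at rural means, including the
  intercept ("unobservables") share B;
- **Interaction (I)** = Σⱼ (x̄ⱼ¹ − x̄ⱼ²)(βⱼ¹ − βⱼ²).

These summation formulas define the `linear` mode (group-specific weighted
linear-probability fits). The default `logit_counterfactual` mode replaces
each term by contrasts of weighted mean predicted probabilities under
counterfactual (covariates, coefficients) pairings — e.g.
E = P̄(X¹, β²) − P̄(X², β²) — with I defined residually so E + C + I = D
exactly; its group mean predictions equal the weighted observed prevalences.
Detailed per-covariate-level contributions use the linear algebra (rescaled
to the logit aggregates), and percentile bootstrap intervals come from
stratified resampling within group.

## Worked example

```python
import healthgap as hg
from healthgap.decomposition import render_overall

cfg = hg.default_config(n=20_000, seed=2018)   # DHS-like two-group process
raw = hg.generate_sample(cfg)
ds = hg.apply_exclusions(raw.drop(columns=["outcome"]), cfg.schema())
res = hg.bootstrap_cis(ds, B=200, seed=1)      # threefold + bootstrap CIs
print(render_overall(res, ds.schema))
```

prints

```
            component coefficient          95% CI pct contribution
urban mean prediction       0.360
rural mean prediction       0.206
       Difference (D)       0.154  (0.141, 0.169)
        Endowment (E)       0.121  (0.106, 0.134)             78.3
      Coefficient (C)       0.031  (0.015, 0.049)             20.3
      Interaction (I)       0.002 (-0.016, 0.016)              1.4
```

Read: the estimated overweight/obesity prevalence is 36.0% among urban and
20.6% among rural women, a gap of 15.4 percentage points; about 78% of the
gap is attributable to differences in measured characteristics (endowments
— `res.detailed.table` shows wealth as the largest single contributor),
about 20% to different returns to those characteristics, and the interaction
is negligible. The same analysis runs from the command line on a JSON
configuration:

```
healthgap run-all -c config.json -o out/        # or: validate, simulate,
                                                # describe, fit, decompose
```

writing frequency/prevalence/odds-ratio/decomposition tables as CSV and
plain text plus a full-precision JSON report, a run log and a manifest, all
reproducible byte for byte from the single seed in the config.

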