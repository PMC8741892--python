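# cureaft

Mixture cure survival analysis for right-censored time-to-event cohorts in
which a biomarker is dichotomized at a data-driven cutoff — the setting of
distant-metastasis-free survival (DMFS) in early-stage ER+ breast cancer
stratified by high vs low gene expression.

Many such cohorts show a plateau in the Kaplan–Meier DMFS curve: a
substantial fraction of patients never develops distant metastasis. A
proportional-hazards comparison mixes two different questions — *who* will
ever progress, and *how fast* the susceptible patients progress. The
logistic-AFT mixture cure model separates them.

## Model

Let `T` be years from surgery to distant metastasis and `D` the latent
susceptibility indicator. For covariates `Z`:

```
Pr(T > t | Z) = Pr(D=1|Z) · Pr(T > t | D=1, Z) + Pr(D=0|Z)

logit Pr(D = 1 | Z) = β′Z                      (logistic part)
ln T = γ′Z + exp(α′Z) · ε,   ε ~ standard logistic   (AFT location-scale part)
```

so that event times of susceptible patients are log-logistic with median
`exp(γ′Z)` and the overall curve plateaus at the cure fraction
`Pr(D=0|Z) = 1/(1+exp(β′Z))`. All parameters are estimated jointly by
maximum likelihood under right censoring; Wald intervals come from the
inverse observed information and nested models are compared by likelihood
ratio tests.

The package provides:

- `cureaft.model` — log-logistic distribution, mixture likelihood,
  quasi-Newton fitting with Kaplan–Meier-based initial values, Wald/CI/LRT
  inference, and AIC model selection across placements of a covariate in
  the three regression parts;
- `cureaft.km` — overall product-limit curves and *conditional* (susceptible-
  only) curves in which censored patients enter the risk set with their
  posterior susceptibility probability `πS(c)/(πS(c)+1−π)`;
- `cureaft.cutoff` — dichotomization of a continuous biomarker at each of
  the nine empirical deciles, per-cutoff model selection, and selection of
  the best-fitting cutoff by minimum AIC with Bonferroni-adjusted LRT
  p-values;
- `cureaft.expression` — Wilcoxon / Kruskal–Wallis / Fisher-exact group
  comparisons and the four-group (high/low × metastasis/"cured") marker
  analysis;
- `cureaft.simulate` — a synthetic-cohort and expression-panel generator
  whose defaults mirror the fitted 8th-decile model (cure fraction 0.672,
  susceptible medians 9.48 vs 3.41 years, 15-year follow-up, n=359);
- a `cureaft` CLI (`simulate`, `fit`, `scan`, `km`, `markers`).

## Worked example

```python
import cureaft as ca

# simulate a cohort from the default generative preset and re-fit it
out = ca.generate_cohort(ca.paper80_config(n=2000, seed=42))
design = ca.ModelDesign(location_terms=("high",))
fit = ca.fit(out.records, design, seed=42)

for part, term in design.labels():
    lo, hi = ca.confidence_interval(fit, part, term)
    print(f"{part:9s} {term:9s} {fit.estimate(part, term):+.3f}  [{lo:+.3f}, {hi:+.3f}]")

print("cure fraction:", round(ca.cure_probability({}, fit.params.beta, design), 3))
print("median (high):", round(ca.median_event_time({'high': 1}, fit.params, design), 2), "years")
```

prints

```
logistic  intercept -0.814  [-1.064, -0.563]
location  intercept +2.179  [+1.943, +2.416]
location  high      -1.165  [-1.432, -0.899]
scale     intercept -0.550  [-0.679, -0.420]
cure fraction: 0.693
median (high): 2.76 years
```

Each generative truth (β₀ = −0.715, γ₀ = 2.249, γ_high = −1.022,
α₀ = −0.545) lies inside its 95% interval: about 70% of this cohort is
never going to progress, and among susceptible patients the high-expression
group reaches its median event time around 2.8 years versus roughly 8.8
years (`exp(2.179)`) in the low group.

The decile scan over the same kind of cohort selects the 8th decile —
the cutoff at which the effect truly switches on:

```python
res = ca.scan(out.records, out.biomarker, seed=42)
print(res.selected_decile)   # 80
```

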