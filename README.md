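# foodsec

Calorie-based household food-security analysis for consumption-
expenditure surveys: score households as food secure/insecure, model
the socioeconomic correlates of security with region-stratified
logistic regressions, and test whether regional data may be pooled
into one national model.

The package is aimed at analysts of household consumption-expenditure
microdata (the kind national statistical offices collect annually) who
need a reproducible pipeline from raw consumption records to regional
policy-relevant model output — and at method developers who need a
fully synthetic survey with known ground truth to validate such
pipelines end to end.

## The method

**Indicator.** Each household's annual food consumption is converted
local-unit → grams → edible grams → kcal with a food-composition table
(waste fractions removed), annualised to a daily figure and divided by
the household's adult-equivalent size AE = Σᵢ aᵢ (age-sex weights,
0.33–1.14). With y the daily kcal per AE and γ the minimum calorie
requirement (2,200 kcal/day per AE by default),

    y* = y − γ,     food insecure ⇔ y* ≤ 0.

The household dietary diversity score (HDDS) is the percentage of a
fixed 267-item catalog consumed.

**Model.** For FS ∈ {0, 1} (1 = secure) and covariates x (income-
quintile dummies, household/head recodes, food-expenditure share,
HDDS, agricultural income share),

    logit P(FS = 1 | x) = b₀ + b·x,

fitted by maximum likelihood (in-house IRLS), reported as odds ratios
exp(b) with Wald p-values, McFadden pseudo-R², and VIF collinearity
screening.

**Poolability.** One pooled model versus one model per region (or
region-year): the nested LR statistic

    LR = 2 (Σ_g LL_g − LL_pooled)  ~  χ²((G−1)·k)

decides, at α = 0.05, whether a single national model is admissible or
region-specific models are required.

See `docs/methods.md` for assumptions, parameter defaults and
limitations, and `docs/schema.md` for the file formats.

## Worked example

```python
import foodsec as fs

cfg = fs.ScenarioConfig(n_regions=4, years=(2017, 2018),
                        households_per_stratum=400, seed=11)
ds = fs.generate_survey(cfg)

scored = fs.score_households(ds.consumption, ds.composition,
                             ds.members, ds.ae_table)
print(f"insecure: {100*(1-scored['food_secure'].mean()):.1f}% "
      f"of {len(scored)} households")

hdds = fs.hdds_scores(ds.consumption, ds.households["household_id"])
matrix = fs.build_model_matrix(ds.households, ds.members, scored, hdds)
fit = fs.fit_matrix(matrix, fs.PREDICTORS)
print(fit.to_frame().round(3))

pool = fs.lr_poolability_test(
    matrix, "region",
    ["ig2", "ig3", "ig4", "ig5", "size_ge3", "food_share", "hdds"])
print(f"LR = {pool.lr_stat:.1f}, df = {pool.df}, "
      f"critical = {pool.critical_value:.1f}, "
      f"reject = {pool.reject_pooling}")
```

prints (abridged to a few model terms):

```
insecure: 43.7% of 3200 households
      term  coefficient  std_error  odds_ratio  p_value stars
     const       -3.362      0.488       0.035    0.000   ***
       ig5        1.243      0.152       3.468    0.000   ***
  size_ge3       -0.240      0.091       0.787    0.008    **
food_share        0.040      0.009       1.040    0.000   ***
      hdds        0.086      0.016       1.090    0.000   ***
LR = 41.2, df = 24, critical = 36.4, reject = True
```

Read: about 44% of the synthetic households fall at or below the
2,200 kcal/day-per-AE threshold; being in the top income quintile
multiplies the odds of food security by ≈3.5 relative to the bottom
quintile, an extra household member (size ≥ 3) lowers them, and each
percentage point of food share or dietary diversity raises them — all
directions the generator's true models encode. The poolability LR of
41.2 exceeds the χ² critical value 36.4, so one pooled model is
rejected: the four regions need separate models, which is exactly how
the scenario was generated.

The scripts in `examples/` walk each capability in turn (generation,
scoring, covariates + logit, poolability, descriptives); each prints
what it computes and a line on what the numbers mean.

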