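# Methods

`foodsec` implements a macro–micro food-security analysis of household
consumption-expenditure survey data: a calorie-based security
indicator per household, region-stratified logistic models of its
socioeconomic correlates, and a likelihood-ratio test of whether
regional data may be pooled into one national model. A synthetic
survey generator with known ground truth makes every stage testable
without access to restricted microdata.

## The food-security indicator

Each household's annual food consumption is recorded per catalog item
in a local unit. Scoring proceeds in five steps:

1. convert the declared local unit to grams (`grams_per_unit`);
2. remove the inedible waste fraction of each item;
3. convert edible mass to energy with a food-composition table
   (kcal per 100 g edible portion);
4. sum to annual household kcal and divide by 365;
5. divide by the household's adult-equivalent (AE) size — the sum over
   members of an age-sex weight between 0.33 (infants) and 1.14
   (16–18-year-old males), with adult men (30–60) at 1.00 — to obtain
   daily energy intake per adult equivalent.

With y the daily per-AE intake and γ the minimum calorie requirement
(MCR), the score is y\* = y − γ. A household is food **insecure** when
y\* ≤ 0; the boundary counts as insecure, and security requires
strictly positive y\*. γ defaults to 2,200 kcal/day per adult
equivalent, the national urban threshold the analysis is calibrated
to; it is a single per-AE constant, with age-sex variation in
requirements absorbed entirely by the AE weights.

The AE table is printed with shared band endpoints ("5–7", "7–10");
bands are implemented half-open [lower, upper) with the last band
open-ended, giving deterministic, gap-free coverage of [0, ∞).

The household dietary diversity score (HDDS) is the percentage of the
fixed item catalog (267 items by default) the household consumed at
positive quantity. The catalog size is a parameter: surveys that
aggregate similar ingredients for calorie purposes (e.g. 165
aggregates) but score diversity over the full item list can pass each
count where it applies; no aggregation map is applied by default, each
catalog item carrying its own composition entry.

## Covariates

One model-matrix row per household. Income quintiles are computed
within a scoping cell — nationally per survey year by default,
per region-year optionally — by comparing incomes to the cell's
20/40/60/80 empirical percentiles (linear-interpolation quantiles).
Households strictly above a boundary move up a quintile, so tied
incomes always share a label, assignment is invariant to row order,
and with distinct incomes cell sizes differ by at most one. A cell
whose incomes are all equal collapses to a single label and is
warned about. The first quintile is the reference group; `ig2..ig5`
are dummies.

Binary recodes follow the survey's definitions: household size ≥ 3,
students ≥ 2, male head, head age ≥ 40, head under education, head
employed, head married, home owned, home size ≥ 83 m². Head age and
home size are also available as continuous columns behind a config
switch, because odds ratios of 1.00–1.01 for these factors suggest
some analyses enter them per-unit; the binary coding is the default
as the normative definition. Shares are percentages: food share =
100 × food expenditure / total expenditure, agricultural share =
100 × agricultural income / annual income. Households with
non-positive total expenditure are excluded with a logged count.
Household income stands in for "income of the head"; no separate
head-income variable is modelled. No multiple-testing correction is
applied (per-coefficient 0.05 tests, as is conventional in this
literature); this is a known limitation.

## The logistic model

For outcome y ∈ {0, 1} (1 = food secure),

    logit P(y = 1 | x) = b0 + b·x.

Coefficients are maximum-likelihood estimates computed in-house by
iteratively reweighted least squares (Newton–Raphson with step
halving, so the log-likelihood never decreases). Convergence requires
max |score| < 1e-8 or a relative LL change < 1e-10 within 100
iterations. Standard errors come from the inverse observed
information; per-coefficient inference uses two-sided Wald z-tests at
α = 0.05; effects are reported as odds ratios exp(b) (OR > 1 raises
the odds of security, OR < 1 lowers them, OR = 1 no association).
Goodness of fit is McFadden's pseudo-R² = 1 − LL/LL0 (the variant is a
package choice; it is the conventional default reported alongside
logit tables). Complete separation is detected as a coefficient path
diverging beyond |b| > 30 and is flagged as a non-converged fit rather
than silently returning a penalised estimate — the estimator stays the
plain MLE. Collinearity is screened with variance inflation factors
VIF_j = 1/(1 − R²_j) from auxiliary least-squares regressions, flagged
at the conventional ≥ 5.

## The poolability (aggregation) test

The pooled model (one coefficient vector for all groups) is nested in
the collection of group-specific models (one vector per group), so the
comparison is the standard nested likelihood-ratio statistic

    LR = 2 (Σ_g LL_g − LL_pooled)  ~  χ²((G − 1) · k)

under the null of equal coefficients, with G the number of usable
groups and k the parameters per model including the intercept.
Pooling is rejected when LR exceeds the χ² critical value at α
(default 0.05). Degrees of freedom are not universally reported with
this test; (G − 1)·k corresponds to the full-interaction reading of
"separate models per group" and is used throughout.

Groups whose fit fails — a single-class outcome, separation, or too
few rows — are excluded with explicit accounting: they are listed in
the result, the pooled model is refit on the rows of the usable groups
only (keeping the models nested and the statistic non-negative), and
df is adjusted. A grouping with exactly one cell returns the
degenerate result LR = 0 / cannot reject (reported with df = k so a
critical value exists); two or more cells of which fewer than two are
usable raise an error. The suite runs one region-poolability test per
survey year plus one overall region-year test and emits a decision
table with one row per year plus an overall row.

## Descriptives

The prevalence table reports the percentage of food-insecure
households per region-year, a multi-year average per region, and an
ordinal rank (1 = most insecure on average, ties broken by region
label order). The average is sample-size weighted by default —
Σ_y n_ry p_ry / Σ_y n_ry — with an unweighted option; published tables
of this kind print averages that are not the unweighted mean of their
yearly cells, which is why the weighted form is the default and why
the packaged reference column of published provincial averages is used
only as a static fixture for rank and extrema checks, never as a
computational target. The Engel summary reports per-region mean
income and mean food-expenditure share and their Spearman rank
correlation; a negative correlation is consistent with Engel's law
(richer regions devote a smaller share of spending to food).

## The synthetic survey generator

The generator emulates the statistical structure of a national urban
survey — it is a study-condition stand-in, not a demographic model of
any real population:

* **Grid**: 30 regions × survey years 2010–2018 by default, a fixed
  number of households per region-year stratum (default 400, matching
  the ≈110k-household scale of the survey the defaults mirror; tests
  and the acceptance script pass smaller counts, stated below).
* **Rosters**: household size on {1..8} with mode 3; the head is an
  adult with age uniform on [20, 75); other members draw an age band
  uniformly from the AE table's bands (the open-ended band truncated
  at 80) and an age uniformly within it; sexes are Bernoulli(1/2).
  Student counts are the number of members aged 6–18.
* **Incomes**: log-normal with region-specific location (default
  locations spread linearly over ±0.5 log units) and σ = 0.5.
* **Engel behaviour**: food-expenditure share (percent) =
  35 + slope × (log income − centre) + N(0, 4), clipped to [2, 95],
  with slope −6 by default (negative by construction).
* **Other covariates**: home ownership 0.6, employment 0.8, head under
  education 0.05, married 0.8; home size log-normal around 85 m²;
  agricultural income present for 8% of (urban) households at up to
  25% of annual income; HDDS item count Binomial(catalog, 0.18).
* **Labels**: each region has a true coefficient vector over the full
  predictor set; the hidden label is Bernoulli(logistic(b0 + b·x))
  given the household's realised covariates (quintiles included). The
  default coefficient table perturbs baseline log odds ratios — signs
  matching the directions reported for urban Iran (income quintiles,
  employment, food share and HDDS positive; household size, students
  negative) — by N(0, 0.25) per region, and centres each intercept,
  using the analytic predictor means of the distributions above, so
  the marginal insecure share lands near 41% (0.3 SD of intercept
  spread across regions).
* **Baskets**: the household draws `items_consumed` distinct items
  (exactly its HDDS count) with Dirichlet(1) calorie weights; the
  total is placed at 2,200 × (1 + U) kcal/day per AE for secure
  households and 2,200 × (1 − U) for insecure, U ~ Uniform(0.02, 0.6),
  and converted back to local-unit quantities through the composition
  table. The 2% margin guarantees that scoring reproduces the hidden
  labels exactly despite floating-point round-off, while leaving a
  realistic intake spread.
* **Determinism**: one `numpy` Generator seeded from the config; the
  composition table uses seed + 1. Identical configs give
  byte-identical datasets.

The hidden truth (coefficients, labels, the generator's covariate
rendering) travels in a `truth.json` sidecar so the real-format
ingestion path is exercised honestly; `ground_truth` returns exactly
the generation-time values and raises on real-format data.

What the generator does **not** emulate: price levels or inflation,
the 2010 subsidy reform, rural households, within-year seasonality,
measurement error in reported quantities, or correlation between
income and dietary diversity. Passing tests therefore demonstrate the
correctness of the pipeline's accounting and inference on surveys of
this structure, not the field validity of any particular coefficient.

## Problem sizes used in tests and the acceptance script

Monte-Carlo experiments use sizes chosen to make their statistical
assertions sharp at desk scale: the poolability size study runs 500
replicates of a homogeneous 5-group design at n = 200/group with k = 4
parameters (rejection rate asserted within 3 binomial SDs of 0.05);
the power study 100 replicates with group coefficients 1.0 logit units
apart at n = 400/group (≥ 95% rejection); Wald-CI coverage uses 200
replicates of a 2-region design at n = 2,000 per region over the full
17-parameter model (coverage asserted within 0.95 ± 0.02). The
stratification bookkeeping check generates the full 30 × 9 grid at 50
households per stratum; the acceptance script uses 20 per stratum
(5,400 households) for its end-to-end run. These sizes are package
choices documented here so results are reproducible.

## Numerical choices and degenerate inputs

Log-likelihoods use `log(1+e^η)` via `logaddexp` for stability;
pseudo-R² is clipped to [0, 1) against −1e-17-style round-off;
the LR statistic is floored at 0 (tolerance −1e-6, beyond which an
error is raised since it indicates non-nested fits); rank ties break
by region label order; quintile ties share labels; empty consumption
scores 0 kcal (insecure); an empty item catalog, empty rosters,
negative ages, single-class outcomes and unknown item ids raise
explicit errors naming the offender.

## Known limitations

Calorie adequacy ignores dietary quality and over-consumption; the
pipeline classifies on energy alone by design. The survey's published
rank column and province-level LR table cannot be reproduced without
the restricted microdata and are not computational targets; only the
printed average column's extrema and ranks are checked against the
packaged fixture. Head-specific income, survey weights in the
regressions, and multinomial/ordered outcomes are out of scope.
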