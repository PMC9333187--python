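# File schemas

All survey artefacts are delimited text (CSV, comma-separated, header
row). A survey directory contains the first five files; `truth.json`
is present only for synthetic surveys.

## households.csv

One row per household.

| column | type | meaning |
|---|---|---|
| household_id | int | unique key |
| region_id | int | region (province) code, 1-based |
| year | int | survey year |
| head_index | int | member_index of the household head |
| monthly_income | float | currency units per month |
| total_expenditure | float | currency units per month |
| food_expenditure | float | currency units per month, ≤ total_expenditure |
| agricultural_income | float | annual currency units, ≤ 12 × monthly_income |
| home_owned | bool | personal home (True) vs rental (False) |
| home_size | float | m², > 0 |
| head_employed | bool | head has an occupation |
| head_under_education | bool | head currently enrolled in education |
| head_married | bool | head married |
| n_students | int | members enrolled in school |

## members.csv

One row per person.

| column | type | meaning |
|---|---|---|
| household_id | int | foreign key |
| member_index | int | 0-based position within the household |
| age | float | years, ≥ 0 |
| sex | str | `male` or `female` |

## consumption.csv

One row per (household, item); quantities are annual totals in the
item's declared local unit.

| column | type | meaning |
|---|---|---|
| household_id | int | foreign key |
| item_id | int | catalog item, 1-based |
| quantity | float | annual amount in local units, ≥ 0 |
| unit | str | unit code |

## composition.csv

One row per catalog item.

| column | type | meaning |
|---|---|---|
| item_id | int | catalog item |
| kcal_per_100g | float | energy per 100 g edible portion |
| waste_fraction | float | inedible share in [0, 1) |
| grams_per_unit | float | grams per declared local unit, > 0 |

## adult_equivalents.csv

One row per age band; bands are half-open `[age_lower, age_upper)`
with the last band open-ended.

| column | type | meaning |
|---|---|---|
| age_lower | float | inclusive lower bound in years |
| age_upper | float | exclusive upper bound (`inf` for the last band) |
| male | float | adult-equivalent factor for males |
| female | float | adult-equivalent factor for females |

## truth.json (synthetic surveys only)

Sidecar with the generator's hidden truth: `predictor_names`
(intercept first), `coefficients` (region_id → coefficient vector),
`labels` (household_id → food_secure) and `covariates` (the
generator's own model-matrix rendering, columns as below).

## model_matrix.csv

One row per scored household: `household_id`, `region_id`, `year`,
outcome `fs` (secure = 1) and the predictors `ig2..ig5` (quintile
dummies, first quintile reference), `size_ge3`, `students_ge2`,
`head_male`, `head_age`, `head_under_education`, `head_employed`,
`head_married`, `home_owned`, `home_size`, `food_share` (%), `hdds`
(%), `agri_share` (%). `head_age` / `home_size` hold the ≥ 40 / ≥ 83 m²
flags under the default binary encoding, raw values under the
continuous encoding.
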