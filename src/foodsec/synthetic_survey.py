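"""Synthetic household consumption-expenditure survey with known truth.

Emulates the statistical structure of a national urban survey: ~30
regions observed over 9 years, log-normal incomes with region-specific
location, Engel-law behaviour (food-expenditure share falling in log
income), a 267-item food catalog, and region-specific logistic models
linking the socioeconomic covariates to a hidden food-security label.

The consumption basket of each household is constructed so that

* the number of distinct items equals the household's generated HDDS
  count, and
* daily calories per adult equivalent land strictly above the 2,200
  kcal threshold when the hidden label is secure, and at or below it
  otherwise,

so downstream scoring must reproduce the hidden labels exactly.  The
truth (per-region coefficient vectors, labels, the generator's own
covariate rendering) travels in a sidecar block, never in the survey
tables themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import covariates as cov
from .nutrition_scoring import (AdultEquivalentTable, DAYS_PER_YEAR,
                                DEFAULT_CATALOG_SIZE, DEFAULT_MCR)
from .records import SurveyDataset, SurveyTruth

# Household-size distribution over 1..8 members (mode at 3).
_SIZE_PROBS = np.array([0.08, 0.18, 0.25, 0.22, 0.13, 0.08, 0.04, 0.02])

# Approximate population means of the predictors under the generator's
# distributions; used only to centre the default intercepts so that the
# marginal insecurity rate lands near the survey's ~41%.
_EXPECTED_PREDICTOR_MEANS = {
    "ig2": 0.2, "ig3": 0.2, "ig4": 0.2, "ig5": 0.2,
    "size_ge3": 0.74, "students_ge2": 0.25,
    "head_male": 0.5, "head_age": 0.64,
    "head_under_education": 0.05, "head_employed": 0.8, "head_married": 0.8,
    "home_owned": 0.6, "home_size": 0.53,
    "food_share": 35.0, "hdds": 18.0, "agri_share": 1.0,
}

# Baseline log-odds-ratio of each predictor for the food-secure outcome;
# signs follow the directions reported for urban Iran (higher income
# quintiles, employment and dietary diversity raise the odds; larger
# households and more students lower them).
_BASE_COEFFICIENTS = {
    "ig2": 0.30, "ig3": 0.45, "ig4": 0.70, "ig5": 0.95,
    "size_ge3": -0.35, "students_ge2": -0.12,
    "head_male": 0.05, "head_age": 0.08,
    "head_under_education": -0.30, "head_employed": 0.15,
    "head_married": -0.15,
    "home_owned": 0.10, "home_size": 0.02,
    "food_share": 0.04, "hdds": 0.08, "agri_share": 0.0,
}

_TARGET_SECURE_SHARE = 0.59   # ~41% insecure on average
_SHARE_PREDICTORS = ("food_share", "hdds", "agri_share")


class ConfigurationError(ValueError):
    """Invalid scenario configuration."""


def default_coefficient_table(n_regions: int, heterogeneity: float = 0.25,
                              seed: int = 20220714) -> np.ndarray:
    """Per-region true coefficient vectors (intercept first).

    Regions perturb the baseline log odds ratios by N(0, heterogeneity)
    (percentage-scale predictors get a proportionally small N(0, 0.01)
    jitter), and each intercept is centred so the region's expected
    secure share sits near the target, with N(0, 0.3) spread.
    """
    rng = np.random.default_rng(seed)
    means = np.array([_EXPECTED_PREDICTOR_MEANS[p] for p in cov.PREDICTORS])
    base = np.array([_BASE_COEFFICIENTS[p] for p in cov.PREDICTORS])
    sds = np.array([0.01 if p in _SHARE_PREDICTORS else heterogeneity
                    for p in cov.PREDICTORS])
    table = np.empty((n_regions, len(cov.PREDICTORS) + 1))
    target_logit = np.log(_TARGET_SECURE_SHARE / (1 - _TARGET_SECURE_SHARE))
    for r in range(n_regions):
        coef = base + rng.normal(0.0, sds)
        intercept = target_logit + rng.normal(0.0, 0.3) - coef @ means
        table[r] = np.concatenate([[intercept], coef])
    return table


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of a synthetic survey scenario.

    Defaults mirror a national urban consumption-expenditure survey:
    30 regions x survey years 2010-2018, a 267-item catalog, 400
    households per region-year stratum, log-normal incomes whose
    location varies by region, and a negative Engel slope (percentage
    points of food share per unit of log income).
    """

    n_regions: int = 30
    years: Sequence[int] = tuple(range(2010, 2019))
    households_per_stratum: int = 400
    n_items: int = DEFAULT_CATALOG_SIZE
    coefficient_table: np.ndarray | None = None
    income_region_means: np.ndarray | None = None
    income_sigma: float = 0.5
    engel_slope: float = -6.0
    base_food_share: float = 35.0
    food_share_sd: float = 4.0
    hdds_item_prob: float = 0.18
    mcr: float = DEFAULT_MCR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be at least 1")
        if self.households_per_stratum < 1:
            raise ConfigurationError("households_per_stratum must be at least 1")
        if self.n_items < 1:
            raise ConfigurationError("n_items must be at least 1")
        if len(self.years) < 1:
            raise ConfigurationError("at least one survey year is required")
        if self.engel_slope >= 0:
            raise ConfigurationError("engel_slope must be negative (Engel's law)")
        k = len(cov.PREDICTORS) + 1
        if self.coefficient_table is not None:
            tab = np.asarray(self.coefficient_table, dtype=float)
            if tab.shape != (self.n_regions, k):
                raise ConfigurationError(
                    f"coefficient_table must have shape ({self.n_regions}, {k}) "
                    f"(intercept + one coefficient per predictor), got {tab.shape}")
        if self.income_region_means is not None:
            if len(np.asarray(self.income_region_means)) != self.n_regions:
                raise ConfigurationError(
                    "income_region_means must have one entry per region")

    def resolved_coefficients(self) -> np.ndarray:
        if self.coefficient_table is not None:
            return np.asarray(self.coefficient_table, dtype=float)
        return default_coefficient_table(self.n_regions)

    def resolved_income_means(self) -> np.ndarray:
        if self.income_region_means is not None:
            return np.asarray(self.income_region_means, dtype=float)
        if self.n_regions == 1:
            return np.array([10.0])
        return np.linspace(9.5, 10.5, self.n_regions)


def generate_composition_table(n_items: int, seed: int) -> pd.DataFrame:
    """Synthetic food-composition table.

    Each item gets an energy density in [20, 900] kcal per 100 g edible
    portion, a waste (inedible) fraction in [0, 0.6], and a conversion
    factor from its declared local unit to grams (log-uniform between
    1 g and 1 kg).  Deterministic under the seed.
    """
    if n_items < 1:
        raise ConfigurationError("n_items must be at least 1")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "item_id": np.arange(1, n_items + 1),
        "kcal_per_100g": rng.uniform(20.0, 900.0, n_items),
        "waste_fraction": rng.uniform(0.0, 0.6, n_items),
        "grams_per_unit": 10.0 ** rng.uniform(0.0, 3.0, n_items),
    })


@dataclass
class DesignDraw:
    """Covariates and hidden labels drawn from the true models (the
    consumption-free part of a synthetic survey)."""

    households: pd.DataFrame
    members: pd.DataFrame
    hdds: pd.DataFrame
    matrix: pd.DataFrame            # model matrix with fs = hidden label
    coefficients: dict[int, np.ndarray]


def simulate_design(config: ScenarioConfig,
                    rng: np.random.Generator | None = None) -> DesignDraw:
    """Draw rosters, incomes, covariates and hidden security labels.

    This is the fast path used by Monte-Carlo experiments; it is also
    the first stage of :func:`generate_survey`, which additionally
    builds consumption baskets consistent with the labels.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    regions = np.arange(1, config.n_regions + 1)
    years = np.asarray(list(config.years))
    hps = config.households_per_stratum
    n = config.n_regions * len(years) * hps

    region_id = np.repeat(regions, len(years) * hps)
    year = np.tile(np.repeat(years, hps), config.n_regions)
    household_id = np.arange(1, n + 1)

    sizes = rng.choice(np.arange(1, 9), size=n, p=_SIZE_PROBS)

    # heads are adults; other members span all age bands of the AE table
    head_age = rng.uniform(20.0, 75.0, n)
    head_sex = np.where(rng.random(n) < 0.5, "male", "female")
    n_others = sizes - 1
    other_hh = np.repeat(household_id, n_others)
    m = int(n_others.sum())
    band_lower = np.array([0, 1, 2, 3, 5, 7, 10, 12, 14, 16, 18, 30, 60], dtype=float)
    band_upper = np.array([1, 2, 3, 5, 7, 10, 12, 14, 16, 18, 30, 60, 80], dtype=float)
    bands = rng.integers(0, len(band_lower), m)
    other_age = band_lower[bands] + rng.random(m) * (band_upper[bands] - band_lower[bands])
    other_sex = np.where(rng.random(m) < 0.5, "male", "female")

    members = pd.DataFrame({
        "household_id": np.concatenate([household_id, other_hh]),
        "member_index": np.concatenate(
            [np.zeros(n, dtype=int),
             np.concatenate([np.arange(1, c + 1) for c in n_others]) if m else
             np.array([], dtype=int)]),
        "age": np.concatenate([head_age, other_age]),
        "sex": np.concatenate([head_sex, other_sex]),
    }).sort_values(["household_id", "member_index"], ignore_index=True)

    school_age = (members["age"] >= 6) & (members["age"] < 19)
    n_students = (school_age.groupby(members["household_id"]).sum()
                  .reindex(household_id, fill_value=0).to_numpy())

    mu = config.resolved_income_means()
    log_income = rng.normal(mu[region_id - 1], config.income_sigma)
    income = np.exp(log_income)
    total_exp = income * 0.8 * np.exp(rng.normal(0.0, 0.15, n))
    center = float(np.mean(mu))
    share = np.clip(config.base_food_share
                    + config.engel_slope * (log_income - center)
                    + rng.normal(0.0, config.food_share_sd, n), 2.0, 95.0)
    food_exp = share / 100.0 * total_exp
    has_agri = rng.random(n) < 0.08
    agri_income = np.where(has_agri, rng.uniform(0.0, 0.25, n) * 12.0 * income, 0.0)

    households = pd.DataFrame({
        "household_id": household_id,
        "region_id": region_id,
        "year": year,
        "head_index": np.zeros(n, dtype=int),
        "monthly_income": income,
        "total_expenditure": total_exp,
        "food_expenditure": food_exp,
        "agricultural_income": agri_income,
        "home_owned": rng.random(n) < 0.6,
        "home_size": np.exp(rng.normal(np.log(85.0), 0.35, n)),
        "head_employed": rng.random(n) < 0.8,
        "head_under_education": rng.random(n) < 0.05,
        "head_married": rng.random(n) < 0.8,
        "n_students": n_students,
    })

    items_consumed = np.clip(rng.binomial(config.n_items, config.hdds_item_prob, n),
                             1, config.n_items)
    hdds_frame = pd.DataFrame({
        "household_id": household_id,
        "items_consumed": items_consumed,
        "catalog_size": config.n_items,
        "hdds": 100.0 * items_consumed / config.n_items,
    })

    placeholder = pd.DataFrame({"household_id": household_id,
                                "food_secure": np.zeros(n, dtype=bool)})
    matrix = cov.build_model_matrix(households, members, placeholder, hdds_frame)

    coefs = config.resolved_coefficients()
    X = np.column_stack([np.ones(n), matrix[cov.PREDICTORS].to_numpy(dtype=float)])
    lp = np.einsum("ij,ij->i", X, coefs[matrix["region_id"].to_numpy() - 1])
    p_secure = 1.0 / (1.0 + np.exp(-lp))
    labels = rng.random(n) < p_secure
    matrix[cov.OUTCOME] = labels.astype(int)

    coef_map = {int(r): coefs[r - 1].copy() for r in regions}
    return DesignDraw(households=households, members=members, hdds=hdds_frame,
                      matrix=matrix, coefficients=coef_map)


def _build_baskets(design: DesignDraw, composition: pd.DataFrame,
                   ae_table: AdultEquivalentTable, mcr: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Consumption records matching each household's HDDS count and
    placing per-AE daily calories on the correct side of the threshold."""
    factors = ae_table.factors(design.members["age"].to_numpy(),
                               design.members["sex"].to_numpy())
    ae = (pd.Series(factors, index=design.members["household_id"])
          .groupby(level=0).sum())

    hh_ids = design.households["household_id"].to_numpy()
    secure = design.matrix.set_index("household_id")[cov.OUTCOME] \
        .loc[hh_ids].to_numpy().astype(bool)
    counts = design.hdds.set_index("household_id")["items_consumed"] \
        .loc[hh_ids].to_numpy()
    ae_vec = ae.loc[hh_ids].to_numpy()

    # margin keeps secure strictly above and insecure strictly below MCR
    u = rng.uniform(0.02, 0.6, len(hh_ids))
    target_per_ae = np.where(secure, mcr * (1.0 + u), mcr * (1.0 - u))
    annual_kcal = target_per_ae * ae_vec * DAYS_PER_YEAR

    kcal100 = composition["kcal_per_100g"].to_numpy()
    gpu = composition["grams_per_unit"].to_numpy()
    waste = composition["waste_fraction"].to_numpy()
    n_items = len(composition)

    hh_col, item_col, qty_col = [], [], []
    for i, hid in enumerate(hh_ids):
        k = int(counts[i])
        chosen = rng.choice(n_items, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k))
        kcal_i = weights * annual_kcal[i]
        qty = kcal_i * 100.0 / (kcal100[chosen] * gpu[chosen] * (1.0 - waste[chosen]))
        hh_col.append(np.full(k, hid))
        item_col.append(chosen + 1)
        qty_col.append(qty)

    return pd.DataFrame({
        "household_id": np.concatenate(hh_col),
        "item_id": np.concatenate(item_col).astype(int),
        "quantity": np.concatenate(qty_col),
        "unit": "local",
    })


def generate_survey(config: ScenarioConfig) -> SurveyDataset:
    """Generate a full synthetic survey (see module docstring).

    Identical configs (including the seed) produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    design = simulate_design(config, rng)
    composition = generate_composition_table(config.n_items, config.seed + 1)
    ae_table = AdultEquivalentTable.default()
    consumption = _build_baskets(design, composition, ae_table, config.mcr, rng)

    truth = SurveyTruth(
        coefficients=design.coefficients,
        predictor_names=["const"] + list(cov.PREDICTORS),
        labels=design.matrix[["household_id", cov.OUTCOME]]
        .rename(columns={cov.OUTCOME: "food_secure"})
        .astype({"food_secure": bool}),
        covariates=design.matrix.copy(),
    )
    return SurveyDataset(households=design.households, members=design.members,
                         consumption=consumption, composition=composition,
                         ae_table=ae_table, truth=truth)


def ground_truth(dataset: SurveyDataset) -> SurveyTruth:
    """The hidden truth block of a synthetic survey, exactly as drawn
    during generation (never recomputed).

    Raises ValueError for real-format datasets that carry no truth.
    """
    if dataset.truth is None:
        raise ValueError("dataset carries no hidden-truth block; "
                         "it appears to be a non-synthetic survey")
    return dataset.truth
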