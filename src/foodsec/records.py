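"""Shared record types and the in-memory survey container.

The pipeline's working representation is a set of pandas DataFrames (one
row per household, per member, per consumption record); the dataclasses
here are the scalar views used by single-household entry points and by
the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)


@dataclass(frozen=True)
class PersonSpec:
    """One household member: age in years and sex."""

    age: float
    sex: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class ConsumptionRecord:
    """One annualised food-consumption record in a declared local unit."""

    household_id: int
    item_id: int
    quantity: float
    unit: str = "local"

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError("quantity must be non-negative")


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household (the unit of observation)."""

    household_id: int
    region_id: int
    year: int
    members: tuple[PersonSpec, ...]
    head_index: int
    monthly_income: float
    total_expenditure: float
    food_expenditure: float
    agricultural_income: float
    home_owned: bool
    home_size: float
    head_employed: bool
    head_under_education: bool
    head_married: bool
    n_students: int

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("household roster must be non-empty")
        if not (0 <= self.food_expenditure <= self.total_expenditure):
            raise ValueError("food expenditure must lie in [0, total expenditure]")
        if self.home_size <= 0:
            raise ValueError("home size must be positive")
        if not (0 <= self.agricultural_income <= 12 * self.monthly_income):
            raise ValueError("agricultural income must lie in [0, annual income]")


@dataclass
class SurveyTruth:
    """Hidden ground truth carried alongside a synthetic survey.

    ``coefficients`` maps region_id to the true logit coefficient vector
    (intercept first) used to draw the food-security labels; ``labels``
    holds one row per household (household_id, food_secure);
    ``covariates`` is the generator's own model-matrix rendering of the
    survey, against which the covariate builder can be checked.
    """

    coefficients: dict[int, np.ndarray]
    predictor_names: list[str]
    labels: pd.DataFrame
    covariates: pd.DataFrame


@dataclass
class SurveyDataset:
    """A household consumption-expenditure survey in memory.

    households : one row per household (incomes, expenditures, dwelling
        and head attributes).
    members : one row per person (household_id, member_index, age, sex).
    consumption : one row per (household, item) with annual quantity in
        the item's declared local unit.
    composition : food-composition lookup (kcal per 100 g edible,
        waste fraction, grams per declared unit).
    ae_table : adult-equivalent weights by age band and sex.
    truth : hidden generator truth; ``None`` for real-format data.
    """

    households: pd.DataFrame
    members: pd.DataFrame
    consumption: pd.DataFrame
    composition: pd.DataFrame
    ae_table: "object" = None
    truth: Optional[SurveyTruth] = field(default=None, repr=False)

    @property
    def n_households(self) -> int:
        return len(self.households)
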