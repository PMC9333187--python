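"""Model-matrix construction: income quintiles, recodes, shares, HDDS.

Builds one row per household with the outcome flag (food secure = 1)
and the socioeconomic predictors used by the regional logit models:
income-quintile dummies (first quintile is the reference), household
size >= 3, number of students >= 2, head sex / age / education /
occupation / marital status, home ownership and size, food-expenditure
share, HDDS, and the agricultural share of income.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

# Fixed predictor order of the model matrix (intercept excluded).
PREDICTORS = [
    "ig2", "ig3", "ig4", "ig5",
    "size_ge3", "students_ge2",
    "head_male", "head_age",
    "head_under_education", "head_employed", "head_married",
    "home_owned", "home_size",
    "food_share", "hdds", "agri_share",
]

OUTCOME = "fs"

AGE_THRESHOLD = 40.0     # head age recode: >= 40 -> 1
HOME_SIZE_THRESHOLD = 83.0  # home size recode: >= 83 m^2 -> 1
SIZE_THRESHOLD = 3       # household size recode: >= 3 members -> 1
STUDENTS_THRESHOLD = 2   # student count recode: >= 2 -> 1


@dataclass(frozen=True)
class CovariateConfig:
    """Switches for the encodings the survey leaves ambiguous.

    quintile_scope : cell within which income quintiles are computed —
        one national distribution per survey year (default) or one per
        region-year.
    age_encoding / homesize_encoding : 'binary' applies the threshold
        recodes (>= 40 years, >= 83 m^2); 'continuous' keeps the raw
        values in the same columns.
    """

    quintile_scope: Literal["national_by_year", "region_by_year"] = "national_by_year"
    age_encoding: Literal["binary", "continuous"] = "binary"
    homesize_encoding: Literal["binary", "continuous"] = "binary"


def assign_income_quintiles(households: pd.DataFrame,
                            scope: str = "national_by_year") -> pd.Series:
    """Quintile label 1..5 of each household's monthly income.

    Boundaries sit at the 20/40/60/80 empirical percentiles within each
    scoping cell (survey year, or region-year).  Households strictly
    above a boundary move up a quintile, so tied incomes always share a
    label and the assignment is invariant to row order.  A cell in
    which every income is equal collapses to a single label and is
    reported with a warning.
    """
    if scope == "national_by_year":
        keys = ["year"]
    elif scope == "region_by_year":
        keys = ["region_id", "year"]
    else:
        raise ValueError(f"unknown quintile scope {scope!r}")

    labels = pd.Series(np.zeros(len(households), dtype=int),
                       index=households.index, name="income_quintile")
    for cell, idx in households.groupby(keys, sort=True).groups.items():
        income = households.loc[idx, "monthly_income"].to_numpy(dtype=float)
        if len(income) < 5:
            raise ValueError(f"cell {cell} has {len(income)} households; "
                             "at least 5 are required to form quintiles")
        bounds = np.quantile(income, [0.2, 0.4, 0.6, 0.8])
        labels.loc[idx] = 1 + (income[:, None] > bounds[None, :]).sum(axis=1)
        if np.unique(labels.loc[idx]).size == 1:
            warnings.warn(f"degenerate income quintiles in cell {cell}: "
                          "all households share one label", stacklevel=2)
    return labels


def _head_attributes(households: pd.DataFrame, members: pd.DataFrame) -> pd.DataFrame:
    """Age and sex of each household's head, via head_index."""
    heads = households[["household_id", "head_index"]].merge(
        members, left_on=["household_id", "head_index"],
        right_on=["household_id", "member_index"], validate="1:1")
    return heads.set_index("household_id")[["age", "sex"]]


def build_model_matrix(households: pd.DataFrame, members: pd.DataFrame,
                       intake: pd.DataFrame, hdds_scores: pd.DataFrame,
                       config: CovariateConfig | None = None) -> pd.DataFrame:
    """One model-matrix row per scored household.

    ``intake`` must carry household_id and food_secure (from the
    scoring step); ``hdds_scores`` must carry household_id and hdds.
    Households with zero total expenditure are excluded with a warning.
    """
    if config is None:
        config = CovariateConfig()

    hh = households.copy()
    zero_exp = hh["total_expenditure"] <= 0
    if zero_exp.any():
        warnings.warn(f"excluded {int(zero_exp.sum())} household(s) with "
                      "non-positive total expenditure", stacklevel=2)
        hh = hh.loc[~zero_exp]

    quintile = assign_income_quintiles(hh, config.quintile_scope)
    heads = _head_attributes(hh, members)
    head_age = heads.loc[hh["household_id"], "age"].to_numpy(dtype=float)
    head_sex = heads.loc[hh["household_id"], "sex"].to_numpy()
    n_members = (members.groupby("household_id").size()
                 .reindex(hh["household_id"]).to_numpy())

    out = pd.DataFrame({
        "household_id": hh["household_id"].to_numpy(),
        "region_id": hh["region_id"].to_numpy(),
        "year": hh["year"].to_numpy(),
    })
    for q in (2, 3, 4, 5):
        out[f"ig{q}"] = (quintile.to_numpy() == q).astype(int)
    out["size_ge3"] = (n_members >= SIZE_THRESHOLD).astype(int)
    out["students_ge2"] = (hh["n_students"].to_numpy() >= STUDENTS_THRESHOLD).astype(int)
    out["head_male"] = (head_sex == "male").astype(int)
    if config.age_encoding == "binary":
        out["head_age"] = (head_age >= AGE_THRESHOLD).astype(int)
    else:
        out["head_age"] = head_age
    out["head_under_education"] = hh["head_under_education"].to_numpy().astype(int)
    out["head_employed"] = hh["head_employed"].to_numpy().astype(int)
    out["head_married"] = hh["head_married"].to_numpy().astype(int)
    out["home_owned"] = hh["home_owned"].to_numpy().astype(int)
    if config.homesize_encoding == "binary":
        out["home_size"] = (hh["home_size"].to_numpy() >= HOME_SIZE_THRESHOLD).astype(int)
    else:
        out["home_size"] = hh["home_size"].to_numpy(dtype=float)
    out["food_share"] = 100.0 * hh["food_expenditure"].to_numpy() / hh["total_expenditure"].to_numpy()
    annual_income = 12.0 * hh["monthly_income"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        agri = np.where(annual_income > 0,
                        100.0 * hh["agricultural_income"].to_numpy() / annual_income,
                        0.0)
    out["agri_share"] = agri

    hd = hdds_scores.set_index("household_id")["hdds"]
    out["hdds"] = hd.loc[out["household_id"]].to_numpy(dtype=float)

    fs = intake.set_index("household_id")["food_secure"]
    out[OUTCOME] = fs.loc[out["household_id"]].to_numpy().astype(int)

    return out[["household_id", "region_id", "year", OUTCOME] + PREDICTORS]
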