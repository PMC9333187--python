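"""Calorie-based food-security scoring and dietary diversity.

The indicator is built in five steps: (1) convert each item's declared
local unit to grams, (2) remove the inedible (waste) fraction, (3)
convert edible mass to energy with a food-composition table, (4) divide
the annual energy by 365 to obtain daily household intake, and (5)
divide by the household's adult-equivalent (AE) size — the sum of
age-sex weights over the roster — to obtain daily intake per adult
equivalent.

Writing the daily per-AE intake as y and the minimum calorie
requirement (MCR) as gamma, the score is y* = y − gamma and a household
is food **insecure** when y* ≤ 0 (the boundary counts as insecure).
The MCR defaults to 2,200 kcal/day per adult equivalent.

The household dietary diversity score (HDDS) is the percentage of a
fixed item catalog (267 items by default) that the household consumed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import MALE, FEMALE, PersonSpec, ConsumptionRecord

DEFAULT_MCR = 2200.0
DAYS_PER_YEAR = 365.0
DEFAULT_CATALOG_SIZE = 267

_AE_FACTOR_MIN = 0.33
_AE_FACTOR_MAX = 1.14


@dataclass(frozen=True)
class CompositionEntry:
    """Composition data for one catalog item.

    kcal_per_100g refers to the edible portion; waste_fraction is the
    inedible share removed before energy conversion; grams_per_unit
    converts the survey's declared local unit to grams.
    """

    item_id: int
    kcal_per_100g: float
    waste_fraction: float
    grams_per_unit: float

    def __post_init__(self) -> None:
        if self.kcal_per_100g < 0:
            raise ValueError("kcal_per_100g must be non-negative")
        if not (0 <= self.waste_fraction < 1):
            raise ValueError("waste_fraction must lie in [0, 1)")
        if self.grams_per_unit <= 0:
            raise ValueError("grams_per_unit must be positive")


class AdultEquivalentTable:
    """Age-sex adult-equivalent weights over half-open age bands.

    Bands are [lower, upper) with the last band open-ended, jointly
    covering [0, inf) without gaps.  Factors must lie in [0.33, 1.14].
    """

    def __init__(self, age_lower: Sequence[float], male: Sequence[float],
                 female: Sequence[float]):
        self.age_lower = np.asarray(age_lower, dtype=float)
        self.male = np.asarray(male, dtype=float)
        self.female = np.asarray(female, dtype=float)
        if self.age_lower[0] != 0:
            raise ValueError("first age band must start at 0")
        if np.any(np.diff(self.age_lower) <= 0):
            raise ValueError("age band lower bounds must be strictly increasing")
        for arr in (self.male, self.female):
            if arr.shape != self.age_lower.shape:
                raise ValueError("one factor per band and sex required")
            if np.any(arr < _AE_FACTOR_MIN) or np.any(arr > _AE_FACTOR_MAX):
                raise ValueError(
                    f"factors must lie in [{_AE_FACTOR_MIN}, {_AE_FACTOR_MAX}]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AdultEquivalentTable":
        return cls(frame["age_lower"].to_numpy(),
                   frame["male"].to_numpy(),
                   frame["female"].to_numpy())

    @classmethod
    def default(cls) -> "AdultEquivalentTable":
        """The standard 13-band table (infants 0.33 … adult men 1.00)."""
        ref = importlib.resources.files("foodsec.data") / "adult_equivalents.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        upper = np.append(self.age_lower[1:], np.inf)
        return pd.DataFrame({"age_lower": self.age_lower, "age_upper": upper,
                             "male": self.male, "female": self.female})

    def factors(self, ages, sexes) -> np.ndarray:
        """Vectorised lookup of the factor for each (age, sex) pair."""
        ages = np.asarray(ages, dtype=float)
        if np.any(ages < 0):
            raise ValueError("ages must be non-negative")
        idx = np.searchsorted(self.age_lower, ages, side="right") - 1
        is_male = np.asarray(sexes) == MALE
        return np.where(is_male, self.male[idx], self.female[idx])


def adult_equivalent(person: PersonSpec, table: AdultEquivalentTable | None = None) -> float:
    """Adult-equivalent factor of one person (e.g. male 45 -> 1.00)."""
    if table is None:
        table = AdultEquivalentTable.default()
    return float(table.factors([person.age], [person.sex])[0])


def household_adult_equivalents(members: Iterable[PersonSpec],
                                table: AdultEquivalentTable | None = None) -> float:
    """Household AE size: sum of the members' factors (strictly positive)."""
    members = list(members)
    if not members:
        raise ValueError("household roster must be non-empty")
    if table is None:
        table = AdultEquivalentTable.default()
    ages = [m.age for m in members]
    sexes = [m.sex for m in members]
    return float(table.factors(ages, sexes).sum())


def edible_grams(record: ConsumptionRecord, entry: CompositionEntry) -> float:
    """Edible mass of one record: quantity × g/unit × (1 − waste)."""
    if record.item_id != entry.item_id:
        raise KeyError(f"composition entry is for item {entry.item_id}, "
                       f"record is for item {record.item_id}")
    return record.quantity * entry.grams_per_unit * (1.0 - entry.waste_fraction)


@dataclass(frozen=True)
class IntakeResult:
    """Per-household calorie accounting and the security classification."""

    household_id: int
    annual_kcal: float
    daily_kcal: float
    adult_equivalents: float
    daily_kcal_per_ae: float
    y_star: float
    food_secure: bool


@dataclass(frozen=True)
class HddsScore:
    household_id: int
    items_consumed: int
    catalog_size: int
    hdds: float


def _validate_composition(consumption: pd.DataFrame, composition: pd.DataFrame) -> None:
    missing = set(consumption["item_id"]) - set(composition["item_id"])
    if missing:
        raise KeyError("consumption references items absent from the "
                       f"composition table: {sorted(missing)}")


def score_households(consumption: pd.DataFrame, composition: pd.DataFrame,
                     members: pd.DataFrame,
                     ae_table: AdultEquivalentTable | None = None,
                     mcr: float = DEFAULT_MCR) -> pd.DataFrame:
    """Score every household in a survey.

    Parameters
    ----------
    consumption : DataFrame with household_id, item_id, quantity.
    composition : DataFrame with item_id, kcal_per_100g, waste_fraction,
        grams_per_unit.
    members : DataFrame with household_id, age, sex (defines the set of
        households; a household with no consumption rows scores 0 kcal).
    ae_table : adult-equivalent weights; the standard table by default.
    mcr : minimum calorie requirement per AE per day.

    Returns one row per household: annual_kcal, daily_kcal,
    adult_equivalents, daily_kcal_per_ae, y_star and the food_secure
    flag (strictly positive y* only).
    """
    if ae_table is None:
        ae_table = AdultEquivalentTable.default()
    _validate_composition(consumption, composition)

    factors = ae_table.factors(members["age"].to_numpy(), members["sex"].to_numpy())
    ae = pd.Series(factors, index=members["household_id"]).groupby(level=0).sum()
    ae.name = "adult_equivalents"

    merged = consumption.merge(composition, on="item_id", how="left", validate="m:1")
    kcal = (merged["quantity"].to_numpy()
            * merged["grams_per_unit"].to_numpy()
            * (1.0 - merged["waste_fraction"].to_numpy())
            * merged["kcal_per_100g"].to_numpy() / 100.0)
    annual = (pd.Series(kcal, index=merged["household_id"])
              .groupby(level=0).sum()
              .reindex(ae.index, fill_value=0.0))

    out = pd.DataFrame({"household_id": ae.index,
                        "annual_kcal": annual.to_numpy(),
                        "adult_equivalents": ae.to_numpy()})
    out["daily_kcal"] = out["annual_kcal"] / DAYS_PER_YEAR
    out["daily_kcal_per_ae"] = out["daily_kcal"] / out["adult_equivalents"]
    out["y_star"] = out["daily_kcal_per_ae"] - mcr
    out["food_secure"] = out["y_star"] > 0
    return out.reset_index(drop=True)


def household_intake(records: Iterable[ConsumptionRecord],
                     composition: pd.DataFrame | dict[int, CompositionEntry],
                     members: Iterable[PersonSpec],
                     ae_table: AdultEquivalentTable | None = None,
                     mcr: float = DEFAULT_MCR,
                     household_id: int = 0) -> IntakeResult:
    """Score a single household from scalar records (see score_households)."""
    members = list(members)
    if not members:
        raise ValueError("household roster must be non-empty")
    if ae_table is None:
        ae_table = AdultEquivalentTable.default()
    if isinstance(composition, dict):
        composition = pd.DataFrame(
            [{"item_id": e.item_id, "kcal_per_100g": e.kcal_per_100g,
              "waste_fraction": e.waste_fraction, "grams_per_unit": e.grams_per_unit}
             for e in composition.values()])
    records = list(records)
    cons = pd.DataFrame(
        {"household_id": [household_id] * len(records),
         "item_id": [r.item_id for r in records],
         "quantity": [r.quantity for r in records]})
    if not records:
        cons = pd.DataFrame({"household_id": pd.Series([], dtype=int),
                             "item_id": pd.Series([], dtype=int),
                             "quantity": pd.Series([], dtype=float)})
    mem = pd.DataFrame({"household_id": [household_id] * len(members),
                        "age": [m.age for m in members],
                        "sex": [m.sex for m in members]})
    row = score_households(cons, composition, mem, ae_table, mcr).iloc[0]
    return IntakeResult(household_id=household_id,
                        annual_kcal=float(row["annual_kcal"]),
                        daily_kcal=float(row["daily_kcal"]),
                        adult_equivalents=float(row["adult_equivalents"]),
                        daily_kcal_per_ae=float(row["daily_kcal_per_ae"]),
                        y_star=float(row["y_star"]),
                        food_secure=bool(row["food_secure"]))


def hdds(records: Iterable[ConsumptionRecord] | pd.DataFrame,
         catalog_size: int = DEFAULT_CATALOG_SIZE,
         household_id: int = 0) -> HddsScore:
    """Dietary diversity of one household: % of the catalog consumed.

    Distinct items with strictly positive quantity are counted; the
    score is 100 × count / catalog_size.
    """
    if catalog_size < 1:
        raise ValueError("catalog_size must be at least 1")
    if isinstance(records, pd.DataFrame):
        positive = records.loc[records["quantity"] > 0, "item_id"]
    else:
        positive = pd.Series([r.item_id for r in records if r.quantity > 0],
                             dtype=int)
    count = int(positive.nunique())
    return HddsScore(household_id=household_id, items_consumed=count,
                     catalog_size=catalog_size,
                     hdds=100.0 * count / catalog_size)


def hdds_scores(consumption: pd.DataFrame, households: pd.Series | np.ndarray,
                catalog_size: int = DEFAULT_CATALOG_SIZE) -> pd.DataFrame:
    """HDDS for every household id in ``households`` (vectorised)."""
    if catalog_size < 1:
        raise ValueError("catalog_size must be at least 1")
    pos = consumption.loc[consumption["quantity"] > 0]
    counts = (pos.groupby("household_id")["item_id"].nunique()
              .reindex(pd.Index(households, name="household_id"), fill_value=0))
    return pd.DataFrame({"household_id": counts.index,
                         "items_consumed": counts.to_numpy(),
                         "catalog_size": catalog_size,
                         "hdds": 100.0 * counts.to_numpy() / catalog_size}
                        ).reset_index(drop=True)
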