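"""Descriptive surfaces: prevalence by region-year, ranks, Engel summary.

The prevalence table mirrors the survey-report layout: one row per
region, one column per year with the percentage of food-insecure
households, a multi-year average (sample-size weighted by default) and
an ordinal rank (1 = most insecure on average), plus a country row.

The Engel summary checks the survey against Engel's law — richer
regions should spend a smaller share of expenditure on food — via the
Spearman rank correlation between region mean income and region mean
food-expenditure share.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PrevalenceTable:
    """Region × year food-insecurity percentages with averages/ranks."""

    cells: pd.DataFrame     # region rows × year columns, % insecure
    counts: pd.DataFrame    # same shape, household counts
    average: pd.Series      # per-region multi-year %
    rank: pd.Series         # 1 = highest average
    country: pd.Series      # per-year country %, plus "average"
    weighting: str

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out["average"] = self.average
        out["rank"] = self.rank
        country = self.country.rename("country")
        country = country.rename(index={"average": "average"})
        out.loc["country"] = [country.get(c, np.nan) for c in out.columns]
        return out


def rank_regions(averages: pd.Series) -> pd.Series:
    """Ordinal ranks of the per-region averages, 1 = largest (most
    insecure); ties are broken by region label order."""
    order = sorted(averages.index, key=lambda r: (-averages[r], str(r)))
    return pd.Series({region: i + 1 for i, region in enumerate(order)},
                     name="rank").reindex(averages.index)


def prevalence_table(intake: pd.DataFrame, households: pd.DataFrame,
                     weighting: Literal["sample", "equal"] = "sample"
                     ) -> PrevalenceTable:
    """Percentage of food-insecure households per region-year.

    ``intake`` carries household_id and food_secure; ``households``
    supplies region_id and year.  The multi-year average is weighted by
    cell sample size (``weighting='sample'``) or unweighted
    (``'equal'``).
    """
    df = households[["household_id", "region_id", "year"]].merge(
        intake[["household_id", "food_secure"]], on="household_id",
        validate="1:1")
    df["insecure"] = ~df["food_secure"].astype(bool)

    grouped = df.groupby(["region_id", "year"])["insecure"]
    pct = (100.0 * grouped.mean()).unstack("year")
    n = grouped.size().unstack("year")
    if pct.isna().any().any():
        empties = int(pct.isna().sum().sum())
        warnings.warn(f"{empties} empty region-year cell(s) left blank",
                      stacklevel=2)

    if weighting == "sample":
        weights = n.fillna(0.0)
        avg = (pct * weights).sum(axis=1) / weights.sum(axis=1)
    elif weighting == "equal":
        avg = pct.mean(axis=1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    by_year = df.groupby("year")["insecure"]
    country = 100.0 * by_year.mean()
    if weighting == "sample":
        country.loc["average"] = 100.0 * df["insecure"].mean()
    else:
        country.loc["average"] = country.mean()

    return PrevalenceTable(cells=pct, counts=n, average=avg.rename("average"),
                           rank=rank_regions(avg), country=country,
                           weighting=weighting)


@dataclass
class EngelSummary:
    region_means: pd.DataFrame   # mean_income, mean_food_share per region
    spearman_rho: float
    engel_consistent: bool       # negative correlation


def engel_summary(households: pd.DataFrame) -> EngelSummary:
    """Region-level income vs food-share association.

    Requires at least 3 regions.  A degenerate (constant) food share
    yields rho = 0 with a warning rather than NaN.
    """
    if households["region_id"].nunique() < 3:
        raise ValueError("Engel summary requires at least 3 regions")
    share = 100.0 * households["food_expenditure"] / households["total_expenditure"]
    df = pd.DataFrame({"region_id": households["region_id"],
                       "income": households["monthly_income"],
                       "food_share": share})
    means = df.groupby("region_id").mean()
    means.columns = ["mean_income", "mean_food_share"]
    if (means["mean_food_share"].nunique() == 1
            or means["mean_income"].nunique() == 1):
        warnings.warn("degenerate variance in region means; "
                      "correlation reported as 0", stacklevel=2)
        rho = 0.0
    else:
        rho = float(stats.spearmanr(means["mean_income"],
                                    means["mean_food_share"]).statistic)
    return EngelSummary(region_means=means, spearman_rho=rho,
                        engel_consistent=rho < 0)


def plot_engel(summary: EngelSummary, path: str | None = None):
    """Scatter of region mean income vs mean food share (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    m = summary.region_means
    ax.scatter(m["mean_income"], m["mean_food_share"])
    ax.set_xlabel("region mean monthly income")
    ax.set_ylabel("region mean food-expenditure share (%)")
    ax.set_title(f"Engel summary (Spearman rho = {summary.spearman_rho:.2f})")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def load_published_iran_averages() -> pd.Series:
    """Published multi-year average food-insecurity percentages for the
    urban areas of Iran's provinces (static reference fixture used for
    rank and extrema checks)."""
    ref = (importlib.resources.files("foodsec.data")
           / "iran_urban_insecurity_average.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return df.set_index("province")["average_insecure_pct"]
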