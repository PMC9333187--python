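"""Poolability (aggregation) likelihood-ratio test.

Should one logit model be fitted for the whole country, or one per
region (or region-year)?  The pooled model is nested in the collection
of group-specific models, so the comparison is the standard LR
statistic

    LR = 2 (sum_g LL_g − LL_pooled),

referred to a chi-square distribution with (G − 1) × k degrees of
freedom, where G is the number of usable groups and k the number of
parameters per model (intercept included).  Rejection means the groups
need separate models.

Groups whose fit fails (single-class outcome, separation, too few
rows) are excluded with explicit accounting: the pooled model is refit
on the rows of the usable groups so the models stay nested, and the
excluded groups are listed in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import OUTCOME, PREDICTORS
from .logit_core import DegenerateOutcomeError, LogitFit, fit_matrix

Grouping = Literal["region", "region_year"]


def _group_cols(grouping: str) -> list[str]:
    if grouping == "region":
        return ["region_id"]
    if grouping == "region_year":
        return ["region_id", "year"]
    raise ValueError(f"unknown grouping {grouping!r}")


@dataclass
class PoolabilityResult:
    grouping: str
    pooled_ll: float
    group_lls: dict[tuple, float]
    lr_stat: float
    df: int
    critical_value: float
    p_value: float
    reject_pooling: bool
    alpha: float
    k: int
    n_obs: int
    failed_groups: list[tuple] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.group_lls)


@dataclass(frozen=True)
class StratificationPlan:
    """How the survey is split into separately fitted models."""

    grouping: Grouping
    expected_model_count: int | None = None


def model_count(plan: StratificationPlan, data: pd.DataFrame) -> int:
    """Number of nonempty group cells under the plan.

    For a region-year plan the count is checked against the full
    region × year cross product; empty cells are reported with a
    warning (e.g. 30 regions × 9 years fully populated -> 270).
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    cols = _group_cols(plan.grouping)
    nonempty = data.groupby(cols, sort=True).size()
    count = int(len(nonempty))
    if plan.grouping == "region_year":
        full = data["region_id"].nunique() * data["year"].nunique()
        if count < full:
            warnings.warn(f"{full - count} empty region-year cell(s): "
                          f"{count} of {full} models will be fitted",
                          stacklevel=2)
    if plan.expected_model_count is not None and count != plan.expected_model_count:
        warnings.warn(f"expected {plan.expected_model_count} models, "
                      f"found {count} nonempty cells", stacklevel=2)
    return count


def lr_poolability_test(matrix: pd.DataFrame, grouping: Grouping = "region",
                        predictor_set: list[str] | None = None,
                        alpha: float = 0.05) -> PoolabilityResult:
    """LR test of one pooled logit against group-specific logits.

    ``matrix`` is a model-matrix frame (see covariates); the pooled and
    every group model use the identical ``predictor_set`` (all
    predictors by default).
    """
    if predictor_set is None:
        predictor_set = PREDICTORS
    cols = _group_cols(grouping)
    k = len(predictor_set) + 1

    group_lls: dict[tuple, float] = {}
    failed: list[tuple] = []
    usable_idx = []
    for key, sub in matrix.groupby(cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        try:
            fit = fit_matrix(sub, predictor_set, OUTCOME)
        except (DegenerateOutcomeError, ValueError):
            failed.append(key)
            continue
        if fit.separation or not fit.converged:
            failed.append(key)
            continue
        group_lls[key] = fit.log_likelihood
        usable_idx.append(sub.index)
    if failed:
        warnings.warn(f"{len(failed)} group(s) excluded from the poolability "
                      f"test: {failed}", stacklevel=2)
    n_cells = len(group_lls) + len(failed)
    if n_cells == 1 and len(group_lls) == 1:
        # a single group: pooled and stratified models coincide, the LR
        # statistic is identically 0 and pooling cannot be rejected
        (key, ll), = group_lls.items()
        sub = matrix.loc[usable_idx[0]]
        critical = float(stats.chi2.ppf(1.0 - alpha, k))
        return PoolabilityResult(grouping=grouping, pooled_ll=ll,
                                 group_lls=group_lls, lr_stat=0.0, df=k,
                                 critical_value=critical, p_value=1.0,
                                 reject_pooling=False, alpha=alpha, k=k,
                                 n_obs=len(sub), failed_groups=failed)
    if len(group_lls) < 2:
        raise ValueError("fewer than 2 usable groups; poolability is untestable")

    usable = matrix.loc[np.concatenate([idx.to_numpy() for idx in usable_idx])]
    pooled = fit_matrix(usable, predictor_set, OUTCOME)

    lr = 2.0 * (sum(group_lls.values()) - pooled.log_likelihood)
    if lr < -1e-6:
        raise RuntimeError(f"nested LR statistic is negative ({lr:.3g}); "
                           "group models are not nesting the pooled model")
    lr = max(lr, 0.0)
    df = (len(group_lls) - 1) * k
    critical = float(stats.chi2.ppf(1.0 - alpha, df))
    p = float(stats.chi2.sf(lr, df))
    return PoolabilityResult(grouping=grouping, pooled_ll=pooled.log_likelihood,
                             group_lls=group_lls, lr_stat=float(lr), df=df,
                             critical_value=critical, p_value=p,
                             reject_pooling=bool(lr > critical), alpha=alpha,
                             k=k, n_obs=len(usable), failed_groups=failed)


@dataclass
class AggregationSuiteResult:
    per_year: dict[int, PoolabilityResult]
    overall: PoolabilityResult
    table: pd.DataFrame


def run_aggregation_suite(matrix: pd.DataFrame, alpha: float = 0.05,
                          predictor_set: list[str] | None = None
                          ) -> AggregationSuiteResult:
    """Region-poolability test within each survey year plus one overall
    region-year test; returns a decision table with one row per year
    and an overall row."""
    if matrix["region_id"].nunique() < 2:
        raise ValueError("the aggregation suite requires at least 2 regions")
    per_year: dict[int, PoolabilityResult] = {}
    rows = []
    for year, sub in matrix.groupby("year", sort=True):
        res = lr_poolability_test(sub, "region", predictor_set, alpha)
        per_year[int(year)] = res
        rows.append(_table_row(str(year), res))
    overall = lr_poolability_test(matrix, "region_year", predictor_set, alpha)
    rows.append(_table_row("overall", overall))
    return AggregationSuiteResult(per_year=per_year, overall=overall,
                                  table=pd.DataFrame(rows))


def _table_row(label: str, res: PoolabilityResult) -> dict:
    return {"scope": label, "G": res.n_groups, "k": res.k,
            "pooled_ll": res.pooled_ll,
            "sum_group_ll": sum(res.group_lls.values()),
            "lr_stat": res.lr_stat, "df": res.df,
            "critical_value": res.critical_value, "p_value": res.p_value,
            "reject_pooling": res.reject_pooling,
            "n_failed_groups": len(res.failed_groups)}
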