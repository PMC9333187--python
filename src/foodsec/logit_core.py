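"""Binary logistic regression by IRLS, with the diagnostics the
regional models report.

The model is logit(P(y=1|x)) = b0 + b·x; coefficients are the maximum-
likelihood estimates obtained by iteratively reweighted least squares
(Newton-Raphson on the Bernoulli log-likelihood, with step halving so
the likelihood never decreases).  Standard errors come from the inverse
observed information, per-coefficient p-values from two-sided Wald
z-tests, effect sizes are odds ratios exp(b), goodness of fit is
McFadden's pseudo-R² = 1 − LL/LL0, and collinearity is screened with
variance inflation factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAX_ITER = 100
SCORE_TOL = 1e-8       # max |score| at convergence
LL_TOL = 1e-10         # relative log-likelihood change at convergence
SEPARATION_BOUND = 30.0  # |b| beyond this flags (quasi-)complete separation

ALPHA_DEFAULT = 0.05
VIF_FLAG_THRESHOLD = 5.0


class DegenerateOutcomeError(ValueError):
    """Raised when y contains a single class."""


@dataclass
class LogitFit:
    """A fitted logistic model for one stratum (or the pool)."""

    names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n_obs: int
    converged: bool
    n_iter: int
    separation: bool = False
    ll_path: list[float] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def pseudo_r2(self) -> float:
        return mcfadden_pseudo_r2(self)

    def wald_ci(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) array of Wald confidence limits on the logit scale."""
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * self.standard_errors
        return np.column_stack([self.coefficients - half, self.coefficients + half])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.names,
            "coefficient": self.coefficients,
            "std_error": self.standard_errors,
            "odds_ratio": self.odds_ratios,
            "p_value": self.p_values,
            "stars": [significance_stars(p) for p in self.p_values],
        })


def significance_stars(p: float) -> str:
    """Conventional star codes: * 0.05, ** 0.01, *** 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def null_log_likelihood(y: np.ndarray) -> float:
    """LL of the intercept-only model (closed form at p̂ = mean y)."""
    n = y.size
    p = y.mean()
    if p <= 0 or p >= 1:
        raise DegenerateOutcomeError("degenerate outcome: y has a single class")
    return float(n * (p * np.log(p) + (1 - p) * np.log(1 - p)))


def fit_logit(y, X, names: list[str] | None = None,
              max_iter: int = MAX_ITER) -> LogitFit:
    """Maximum-likelihood logistic fit of y on X (X includes the
    intercept column).

    Convergence requires max |score| < 1e-8 or a relative LL change
    < 1e-10 within 100 iterations.  Coefficient paths diverging beyond
    |b| > 30 are flagged as separation and returned non-converged
    rather than failing silently.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per outcome")
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("degenerate outcome: y has a single class")
    if names is None:
        names = ["const"] + [f"x{i}" for i in range(1, k)]
    if len(names) != k:
        raise ValueError("one name per column required")

    beta = np.zeros(k)
    ll = _bernoulli_ll(y, X @ beta)
    ll_path = [ll]
    converged = False
    separation = False
    it = 0
    info = None
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step halving: never let the likelihood decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_ll(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll_prev, ll = ll, _bernoulli_ll(y, X @ beta)
        ll_path.append(ll)
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            separation = True
            warnings.warn("possible complete separation: coefficient path "
                          "diverged; fit flagged non-converged", stacklevel=2)
            break
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        if abs(ll - ll_prev) < LL_TOL * (abs(ll_prev) + 1e-300):
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    return LogitFit(names=list(names), coefficients=beta, standard_errors=se,
                    p_values=p, log_likelihood=ll,
                    null_log_likelihood=null_log_likelihood(y),
                    n_obs=n, converged=converged, n_iter=it,
                    separation=separation, ll_path=ll_path)


def odds_from_probability(p: float) -> float:
    """Odds p/(1−p).  OR = 1 means no association; >1 higher odds of the
    outcome; <1 lower."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
    return p / (1.0 - p)


def mcfadden_pseudo_r2(fit: LogitFit) -> float:
    """McFadden's 1 − LL/LL0 (0 for the intercept-only model)."""
    r2 = 1.0 - fit.log_likelihood / fit.null_log_likelihood
    # intercept-only fits can land at -1e-17 numerically
    return float(np.clip(r2, 0.0, 1.0))


@dataclass
class VifReport:
    """Variance inflation factors with the conventional >= 5 flag."""

    names: list[str]
    vif: np.ndarray
    flag_threshold: float = VIF_FLAG_THRESHOLD
    flagged: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "vif": self.vif,
                             "flagged": self.vif >= self.flag_threshold})


def vif(X, names: list[str] | None = None,
        flag_threshold: float = VIF_FLAG_THRESHOLD) -> VifReport:
    """VIF_j = 1/(1 − R²_j), R²_j from regressing predictor j on the
    others (with intercept).  X must not contain the intercept column.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("VIF requires at least 2 predictors")
    if names is None:
        names = [f"x{i}" for i in range(1, k + 1)]
    variances = X.var(axis=0)
    for j, v in enumerate(variances):
        if v == 0:
            raise ValueError(f"predictor {names[j]!r} is constant")
    out = np.empty(k)
    for j in range(k):
        target = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 else max(1.0, 1.0 / (1.0 - r2))
    flagged = [names[j] for j in range(k) if out[j] >= flag_threshold]
    return VifReport(names=list(names), vif=out,
                     flag_threshold=flag_threshold, flagged=flagged)


def prepare_design(matrix: pd.DataFrame, predictors: list[str],
                   outcome: str = "fs") -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(y, X-with-intercept, names) from a model-matrix frame."""
    y = matrix[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(matrix)),
                         matrix[predictors].to_numpy(dtype=float)])
    return y, X, ["const"] + list(predictors)


def fit_matrix(matrix: pd.DataFrame, predictors: list[str],
               outcome: str = "fs") -> LogitFit:
    """Fit the logit model on a model-matrix frame."""
    y, X, names = prepare_design(matrix, predictors, outcome)
    return fit_logit(y, X, names)
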