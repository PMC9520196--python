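"""Summary statistics and downstream analyses of scenario tables.

Covers the biodiversity–function analysis (Shannon index, logistic
nonlinear least squares of cumulative biomass on Shannon diversity),
per-functional-group proportion regressions with quantile bands,
Welch's t between environments, Kruskal–Wallis across mutation rates,
and the copiotroph/oligotroph biomass split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .errors import DiversityError, FitError
from .community import FunctionalGroup

__all__ = [
    "shannon_index",
    "LogisticFit",
    "fit_logistic",
    "GroupRegression",
    "group_proportion_regression",
    "welch_t_test",
    "kruskal_wallis",
    "QuantileBands",
    "quantile_bands",
    "strategy_split",
]


def shannon_index(biomass, base: float = None) -> float:
    """Shannon alpha-diversity ``H = -sum p_i log p_i`` over relative biomass.

    Zero-biomass species are excluded; natural log by default.
    """
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise DiversityError("biomass must be non-negative")
    total = b.sum()
    if total <= 0:
        raise DiversityError("diversity is undefined for an all-zero community")
    p = b[b > 0] / total
    p = p[p > 0]  # guard against underflow of vanishing proportions
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


# --------------------------------------------------------------------------
# Logistic biodiversity-function fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """3-parameter logistic ``y = Asym / (1 + exp((xmid - x)/scal))``."""

    asymptote: float
    midpoint: float
    scale: float
    r_squared: float
    p_value: float
    saturation: float  # x beyond which marginal gain is negligible
    n: int


def _logistic(x, asym, xmid, scal):
    return asym / (1.0 + np.exp(np.clip((xmid - x) / scal, -500, 500)))


def _self_start(x, y):
    """Scaled-logit self-start in the style of the classic SSlogis routine."""
    asym0 = 1.05 * np.max(y)
    z = np.clip(y / asym0, 1e-6, 1 - 1e-6)
    logit = np.log(z / (1 - z))
    slope, intercept = np.polyfit(x, logit, 1)
    if slope <= 0:
        slope = 1.0 / max(np.std(x), 1e-6)
    scal0 = 1.0 / slope
    xmid0 = -intercept * scal0
    return asym0, xmid0, scal0


def fit_logistic(shannon, biomass, saturation_gain: float = 0.05) -> LogisticFit:
    """Nonlinear least squares of cumulative biomass on Shannon diversity.

    Returns the fitted parameters, R^2 = 1 - SSE/SST, and the p-value of
    the regression F-test against a constant-mean model.  The saturation
    threshold is the diversity beyond which the marginal biomass gain
    drops below ``saturation_gain`` (default 5%) of the asymptote per
    Shannon unit.
    """
    x = np.asarray(shannon, dtype=float)
    y = np.asarray(biomass, dtype=float)
    if x.size != y.size:
        raise FitError("shannon and biomass vectors must have equal length")
    if x.size < 10:
        raise FitError("need at least 10 points for the logistic fit")
    if np.std(x) == 0 or np.std(y) == 0:
        raise FitError("logistic fit requires positive spread in both variables")
    asym0, xmid0, scal0 = _self_start(x, y)
    p0 = (max(asym0, 1e-9), xmid0, max(scal0, 1e-6))
    # constrain to an increasing curve with a positive ceiling
    bounds = ([1e-12, -np.inf, 1e-9], [np.inf, np.inf, np.inf])
    try:
        popt, _ = scipy.optimize.curve_fit(_logistic, x, y, p0=p0,
                                           bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError, scipy.optimize.OptimizeWarning) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    asym, xmid, scal = (float(v) for v in popt)
    if asym <= 0:
        raise FitError("logistic fit collapsed to a non-positive asymptote")
    resid = y - _logistic(x, *popt)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    n, k = x.size, 3
    df1, df2 = k - 1, n - k
    if sse <= 0:
        p_value = 0.0
    else:
        f = ((sst - sse) / df1) / (sse / df2)
        p_value = float(scipy.stats.f.sf(f, df1, df2))
    # marginal gain dy/dx = (asym/scal) * e^u / (1+e^u)^2 with u=(x-xmid)/scal;
    # solve for the u > 0 where it falls to saturation_gain * asym per x-unit
    target = saturation_gain * abs(scal)
    if target >= 0.25:  # derivative never exceeds asym/(4 scal)
        saturation = xmid
    else:
        # e^u/(1+e^u)^2 = target  =>  u = ln((1-2t+sqrt(1-4t))/(2t))
        disc = np.sqrt(1.0 - 4.0 * target)
        u = np.log((1.0 - 2.0 * target + disc) / (2.0 * target))
        saturation = xmid + u * abs(scal)
    return LogisticFit(asymptote=asym, midpoint=xmid, scale=scal,
                       r_squared=float(r2), p_value=p_value,
                       saturation=float(saturation), n=n)


# --------------------------------------------------------------------------
# Functional-group proportion regressions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupRegression:
    group: str
    beta: float       # slope of log10 cumulative biomass on initial proportion
    intercept: float
    r_squared: float
    p_value: float
    n: int


def group_proportion_regression(results, group) -> GroupRegression:
    """OLS of log10 total cumulative biomass on a group's initial proportion.

    Proportions are the generation-0 census (counts / community size),
    which under null mutation equals the composition throughout.
    """
    import statsmodels.api as sm

    table = results.table if hasattr(results, "table") else results
    group = FunctionalGroup(group)
    x = table[f"prop0_{group.value}"].to_numpy(dtype=float)
    y = table["cum_biomass_total"].to_numpy(dtype=float)
    keep = y > 0
    x, y = x[keep], np.log10(y[keep])
    if x.size < 3:
        raise FitError("too few replicates with positive biomass")
    if np.std(x) == 0:
        raise FitError("zero variance in group proportion")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return GroupRegression(group=group.value,
                           beta=float(model.params[1]),
                           intercept=float(model.params[0]),
                           r_squared=float(model.rsquared),
                           p_value=float(model.pvalues[1]),
                           n=int(x.size))


# --------------------------------------------------------------------------
# Classical tests (scipy-backed)
# --------------------------------------------------------------------------

def welch_t_test(x, y):
    """Welch's unequal-variance t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise FitError("Welch's t-test needs n >= 2 per sample")
    if np.std(x) == 0 and np.std(y) == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise FitError("both samples are constant; t is undefined")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def kruskal_wallis(groups):
    """Kruskal–Wallis rank test with tie correction; returns (H, df, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise FitError("Kruskal-Wallis needs at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise FitError("every group needs at least one observation")
    total = sum(g.size for g in groups)
    if total < 3:
        raise FitError("Kruskal-Wallis needs at least 3 observations in total")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, float(df), 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(df), float(p)


# --------------------------------------------------------------------------
# Quantile bands and the life-strategy split
# --------------------------------------------------------------------------

@dataclass
class QuantileBands:
    overall: tuple[float, float, float]  # (q_low, median, q_high)
    by_proportion: pd.DataFrame | None   # indexed by proportion bin


def quantile_bands(results, group=None, q_low: float = 0.05,
                   q_high: float = 0.95) -> QuantileBands:
    """Median and (q_low, q_high) quantiles of cumulative biomass.

    With ``group`` given, also per initial-proportion bin (proportions
    are multiples of 1/n so bins are exact values; empty bins are simply
    absent, never interpolated).
    """
    if not 0 <= q_low <= 0.5 <= q_high <= 1:
        raise FitError("quantiles must satisfy 0 <= q_low <= 0.5 <= q_high <= 1")
    table = results.table if hasattr(results, "table") else results
    y = table["cum_biomass_total"].to_numpy(dtype=float)
    overall = (float(np.quantile(y, q_low)), float(np.median(y)),
               float(np.quantile(y, q_high)))
    by_prop = None
    if group is not None:
        group = FunctionalGroup(group)
        col = f"prop0_{group.value}"
        by_prop = (table.groupby(col)["cum_biomass_total"]
                   .agg(q_low=lambda v: np.quantile(v, q_low),
                        median="median",
                        q_high=lambda v: np.quantile(v, q_high),
                        n="count"))
    return QuantileBands(overall=overall, by_proportion=by_prop)


def strategy_split(results) -> pd.DataFrame:
    """Per-replicate cumulative biomass of copiotrophs vs oligotrophs."""
    table = results.table if hasattr(results, "table") else results
    return table[["cum_biomass_copiotroph", "cum_biomass_oligotroph"]].copy()
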