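"""Additive century+region linear models and estimated marginal means.

Responses (back-calculated length, growth index G, isotope values) are
modelled as y ~ C(century) + C(region) with no interaction; per-century
estimated marginal means (EMMs) average the model's predictions over the
region levels with equal weights, which is the standard way to report
century effects adjusted for an unbalanced regional sampling design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices

__all__ = [
    "AdditiveFit",
    "MarginalMeans",
    "fit_additive",
    "marginal_means",
    "percentile_summary",
    "AdditiveFitError",
]


class AdditiveFitError(ValueError):
    pass


@dataclass
class AdditiveFit:
    """Wrapper around the fitted two-factor OLS model."""

    result: object = field(repr=False)
    factors: tuple = ("century", "region")
    levels: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    @property
    def r_squared(self) -> float:
        return float(self.result.rsquared)

    @property
    def df_resid(self) -> int:
        return int(self.result.df_resid)

    @property
    def p_value(self) -> float:
        return float(self.result.f_pvalue)

    def coefficients(self) -> pd.Series:
        return self.result.params


@dataclass(frozen=True)
class MarginalMeans:
    level: tuple
    estimate: tuple
    SE: tuple
    n: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"level": self.level, "estimate": self.estimate,
                             "SE": self.SE, "n": self.n})


def fit_additive(y, century, region) -> AdditiveFit:
    """Least-squares fit of y ~ C(century) + C(region), reference coding."""
    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "century": np.asarray(century),
                       "region": np.asarray(region)})
    df = df.dropna()
    for fac in ("century", "region"):
        lv = df[fac].unique()
        if lv.size < 2:
            raise AdditiveFitError(
                f"factor {fac!r} has a single level ({lv.tolist()}); "
                "an additive model needs >= 2 levels per factor")
    res = smf.ols("y ~ C(century) + C(region)", data=df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise AdditiveFitError("rank-deficient design: confounded factor levels")
    levels = {"century": sorted(df["century"].unique().tolist()),
              "region": sorted(df["region"].unique().tolist())}
    counts = df.groupby("century").size().to_dict()
    return AdditiveFit(result=res, levels=levels, counts=counts)


def marginal_means(fit: AdditiveFit, factor: str = "century") -> MarginalMeans:
    """Per-level EMMs: predictions averaged with equal weight over the
    levels of the other factor, with delta-method SEs from the coefficient
    covariance."""
    if factor not in fit.levels:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    other = [f for f in fit.levels if f != factor][0]
    design_info = fit.result.model.data.design_info
    cov = fit.result.cov_params().to_numpy()
    beta = fit.result.params.to_numpy()

    levels, est, ses, ns = [], [], [], []
    for lev in fit.levels[factor]:
        grid = pd.DataFrame({factor: [lev] * len(fit.levels[other]),
                             other: fit.levels[other]})
        (X,) = build_design_matrices([design_info], grid)
        L = np.asarray(X).mean(axis=0)
        levels.append(lev)
        est.append(float(L @ beta))
        ses.append(float(np.sqrt(L @ cov @ L)))
        ns.append(int(fit.counts.get(lev, 0)))
    return MarginalMeans(level=tuple(levels), estimate=tuple(est),
                         SE=tuple(ses), n=tuple(ns))


def percentile_summary(values, q: float) -> float:
    """Empirical quantile with linear interpolation between order statistics
    (the type-7 convention)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty input")
    if not (0 <= q <= 1):
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(values, q))
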