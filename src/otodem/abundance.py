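"""Survivorship abundance index, catch reconstruction, and the catch-Z line.

Given a constant annual recruitment of one fish at the recruitment age, the
expected number alive at age a under exponential mortality is
exp(-Z * (a - recruit_age)). Summing over the fully recruited adult ages
(6 to 21 by default) gives a relative adult-abundance index A(Z) that is
comparable across periods whenever recruitment is stable.

Catch before written records is reconstructed from the human population and
a per-capita fish-consumption schedule. Regressing per-period Z on per-period
catch yields a line whose zero-catch intercept is the natural mortality rate
M, because at zero catch all mortality is natural.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CatchRecord",
    "RegressionFit",
    "abundance_index",
    "consumption_catch",
    "per_capita_for_year",
    "PER_CAPITA_SCHEDULE",
    "catch_z_regression",
    "catch_from_z",
    "CatchRegressionError",
]


class CatchRegressionError(ValueError):
    pass


@dataclass(frozen=True)
class CatchRecord:
    """Catch components (tonnes/yr) for one period; total is their sum."""

    period: str
    population: float = 0.0
    per_capita: float = 0.0
    domestic_catch: float = 0.0
    export_catch: float = 0.0
    foreign_catch: float = 0.0

    def __post_init__(self):
        for f in ("domestic_catch", "export_catch", "foreign_catch"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")

    @property
    def total_catch(self) -> float:
        return self.domestic_catch + self.export_catch + self.foreign_catch

    def to_dict(self) -> dict:
        return asdict(self) | {"total_catch": self.total_catch}


@dataclass(frozen=True)
class RegressionFit:
    """OLS line Z = intercept + slope * catch('000 t); intercept estimates M."""

    slope: float
    intercept: float
    slope_SE: float
    intercept_SE: float
    r_squared: float
    n: int
    p_value: float = float("nan")

    def to_dict(self) -> dict:
        return asdict(self)


def abundance_index(Z, recruit_age: int = 6, max_age: int = 21,
                    allow_zero: bool = False):
    """Relative adult abundance A(Z) = sum over recruited ages of survivorship.

    Closed form of the geometric sum with unit recruitment:
    A = (1 - exp(-Z*m)) / (1 - exp(-Z)), m = max_age - recruit_age + 1.
    Strictly decreasing in Z; tends to 1 as Z -> inf. Z = 0 returns the
    number of age classes m, but only behind `allow_zero`.
    """
    Z_arr = np.asarray(Z, dtype=float)
    m = max_age - recruit_age + 1
    if m < 1:
        raise ValueError("max_age must be >= recruit_age")
    if np.any(Z_arr < 0) or (np.any(Z_arr == 0) and not allow_zero):
        raise ValueError("Z must be positive (Z=0 limit requires allow_zero=True)")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(Z_arr == 0, float(m),
                       (1.0 - np.exp(-Z_arr * m)) / (1.0 - np.exp(-Z_arr)))
    return float(out) if out.ndim == 0 else out


def consumption_catch(population, per_capita):
    """Annual catch (tonnes) implied by `population` persons eating
    `per_capita` kg of fish per year."""
    population = np.asarray(population, dtype=float)
    per_capita = np.asarray(per_capita, dtype=float)
    if np.any(population < 0) or np.any(per_capita < 0):
        raise ValueError("population and per_capita must be non-negative")
    out = population * per_capita / 1000.0
    return float(out) if out.ndim == 0 else out


#: (start_year, end_year_exclusive, kg/person/yr); boundaries belong to the
#: later period.
PER_CAPITA_SCHEDULE = (
    (877, 1200, 400.0),
    (1200, 1400, 600.0),
    (1400, 1600, 400.0),
    (1600, 1700, 600.0),
    (1700, 1801, 400.0),
)


def per_capita_for_year(year: int) -> float:
    """Per-capita cod consumption (kg/yr) for a pre-1800 calendar year."""
    if not (877 <= year <= 1800):
        raise LookupError(f"year {year} outside the consumption schedule (877-1800)")
    for start, end, rate in PER_CAPITA_SCHEDULE:
        if start <= year < end:
            return rate
    raise LookupError(f"year {year} not covered")  # pragma: no cover


def catch_z_regression(catch_kt, Z) -> RegressionFit:
    """OLS of per-period Z on per-period catch in thousands of tonnes."""
    catch_kt = np.asarray(catch_kt, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if catch_kt.size != Z.size or catch_kt.size < 3:
        raise CatchRegressionError("need >= 3 paired (catch, Z) points")
    if np.allclose(catch_kt.var(), 0):
        raise CatchRegressionError("zero catch variance: slope unidentifiable")
    res = sm.OLS(Z, sm.add_constant(catch_kt)).fit()
    return RegressionFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                         slope_SE=float(res.bse[1]), intercept_SE=float(res.bse[0]),
                         r_squared=float(res.rsquared), n=int(catch_kt.size),
                         p_value=float(res.pvalues[1]))


def catch_from_z(Z: float, fit: RegressionFit, catch_range=None):
    """Inverse prediction: catch ('000 t) consistent with a mortality Z.

    Returns (catch, extrapolated_flag). Z at or below the intercept implies
    zero catch and is returned as 0 with a warning flag.
    """
    if Z <= fit.intercept:
        return 0.0, True
    catch = (Z - fit.intercept) / fit.slope
    extrapolated = False
    if catch_range is not None:
        lo, hi = catch_range
        extrapolated = not (lo <= catch <= hi)
    return float(catch), extrapolated
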