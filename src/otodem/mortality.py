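"""Total-mortality (Z) estimation from age compositions, and longevity.

Two classical estimators of the instantaneous total mortality rate Z
(per year) from a cross-sectional age composition:

* catch curve (CC): OLS of ln(count) on age; Z is minus the slope;
* Chapman-Robson (CR): on ages recoded to x = age - start_age, the annual
  survival estimate is S = T / (n + T - 1) with T = sum(x_i), n the number
  of fish; Z = -ln(S). The CR variance used for the delta-method SE is
  Var(S) = S * (S - (T - 1) / (n + T - 2)).

Both assume constant recruitment and full selectivity from `start_age`
onward. The two estimates are combined by a mean weighted by the inverse of
the SE (inverse-variance weighting available behind a flag). Longevity is
predicted from exponential survivorship: the last age at which
N0 * exp(-Z * (age - recruit_age)) is still at least one fish.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "AgeComposition",
    "ZEstimate",
    "build_age_composition",
    "catch_curve_z",
    "chapman_robson_z",
    "combine_z",
    "pool_compositions",
    "predict_longevity",
    "MortalityEstimationError",
]


class MortalityEstimationError(ValueError):
    """Raised when an age composition carries no usable mortality signal."""


@dataclass(frozen=True)
class AgeComposition:
    """Counts at consecutive integer ages from the first fully recruited age."""

    ages: tuple
    counts: tuple
    start_age: int
    label: str = ""

    def __post_init__(self):
        ages = np.asarray(self.ages)
        counts = np.asarray(self.counts)
        if ages.size == 0 or ages.size != counts.size:
            raise ValueError("ages and counts must be non-empty and equal length")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(counts < 0) or counts.sum() < 1:
            raise ValueError("counts must be non-negative with at least one fish")

    @property
    def n(self) -> int:
        return int(sum(self.counts))


@dataclass(frozen=True)
class ZEstimate:
    method: str  # catch_curve | chapman_robson | weighted | assessment
    Z: float
    SE: float
    n: int
    start_age: int
    label: str = ""
    extra: dict = field(default_factory=dict, compare=False)


def build_age_composition(ages, min_age: int = 9, peak_rule: bool = True,
                          label: str = "") -> AgeComposition:
    """Tabulate integer ages into a composition starting at the recruited age.

    start_age is `min_age`, or the modal age if `peak_rule` is set and the
    composition clearly peaks at an older age. Gaps between start_age and the
    maximum observed age are zero-filled.
    """
    ages = np.asarray(ages)
    ages = ages[ages >= min_age]
    if ages.size == 0:
        raise MortalityEstimationError(f"no ages at or above min_age={min_age}")
    vals, cnts = np.unique(ages, return_counts=True)
    start = int(min_age)
    if peak_rule:
        modal = int(vals[np.argmax(cnts)])
        if modal > start:
            start = modal
    vals_f = vals[vals >= start]
    if vals_f.size == 0:  # defensive; modal age is always observed
        raise MortalityEstimationError("no ages at or above the start age")
    full = np.arange(start, int(vals_f.max()) + 1)
    counts = np.zeros_like(full)
    for v, c in zip(vals, cnts):
        if v >= start:
            counts[int(v) - start] = c
    return AgeComposition(ages=tuple(int(a) for a in full),
                          counts=tuple(int(c) for c in counts),
                          start_age=start, label=label)


def catch_curve_z(comp: AgeComposition) -> ZEstimate:
    """Catch-curve Z: minus the OLS slope of ln(count) on age.

    Zero-count ages are dropped (no +1 smoothing); at least three
    positive-count ages are required.
    """
    ages = np.asarray(comp.ages, dtype=float)
    counts = np.asarray(comp.counts, dtype=float)
    keep = counts > 0
    if keep.sum() < 3:
        raise MortalityEstimationError(
            f"catch curve needs >= 3 positive-count ages, got {int(keep.sum())}")
    res = sm.OLS(np.log(counts[keep]), sm.add_constant(ages[keep])).fit()
    return ZEstimate(method="catch_curve", Z=float(-res.params[1]),
                     SE=float(res.bse[1]), n=comp.n, start_age=comp.start_age,
                     label=comp.label,
                     extra={"r_squared": float(res.rsquared),
                            "ages_used": int(keep.sum())})


def chapman_robson_z(comp: AgeComposition) -> ZEstimate:
    """Chapman-Robson Z from recoded ages, with a delta-method SE.

    This is the original estimator S = T/(n+T-1); the small-sample
    bias-corrected variant of the Z point estimate is not applied here (see
    module docstring).
    """
    ages = np.asarray(comp.ages, dtype=float)
    counts = np.asarray(comp.counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise MortalityEstimationError("Chapman-Robson needs n >= 2")
    x = ages - comp.start_age
    T = float(np.sum(x * counts))
    if T <= 0:
        raise MortalityEstimationError(
            "all fish at the start age: no survival information")
    S = T / (n + T - 1.0)
    var_S = S * (S - (T - 1.0) / (n + T - 2.0))
    var_S = max(var_S, 0.0)
    se_Z = math.sqrt(var_S) / S  # delta method for Z = -ln(S)
    return ZEstimate(method="chapman_robson", Z=float(-math.log(S)),
                     SE=float(se_Z), n=int(n), start_age=comp.start_age,
                     label=comp.label, extra={"S": S, "T": T})


def combine_z(estimates, inverse_variance: bool = False) -> ZEstimate:
    """Mean of Z estimates weighted by 1/SE (or 1/SE^2 behind the flag).

    An estimate with SE == 0 carries infinite weight and is returned alone.
    The combined SE, 1/sum(weights), is approximate and flagged as such.
    """
    estimates = list(estimates)
    if not estimates:
        raise MortalityEstimationError("no estimates to combine")
    if len(estimates) == 1:
        return estimates[0]
    exact = [e for e in estimates if e.SE == 0]
    if exact:
        if len(exact) > 1:
            warnings.warn("multiple zero-SE estimates; returning the first")
        return exact[0]
    w = np.array([1.0 / e.SE**2 if inverse_variance else 1.0 / e.SE
                  for e in estimates])
    z = np.array([e.Z for e in estimates])
    Zw = float(np.sum(w * z) / np.sum(w))
    return ZEstimate(method="weighted", Z=Zw, SE=float(1.0 / np.sum(w)),
                     n=max(e.n for e in estimates),
                     start_age=min(e.start_age for e in estimates),
                     label=estimates[0].label,
                     extra={"se_approximate": True,
                            "components": [e.method for e in estimates]})


def pool_compositions(comps, min_n: int = 10):
    """Merge under-sampled compositions with an adjacent one.

    `comps` is an ordered sequence (e.g. by century). Any composition with
    fewer than `min_n` fish is merged with its nearest adjacent neighbour,
    preferring the earlier one; labels are concatenated with an en dash.
    A pooled group still below `min_n` is flagged (``flagged`` attribute on
    the returned extra list) and excluded from estimation by callers.

    Returns (pooled_comps, flagged_labels).
    """
    groups: list[list[AgeComposition]] = [[c] for c in comps]

    def _n(group):
        return sum(c.n for c in group)

    merged = True
    while merged:
        merged = False
        for i, grp in enumerate(groups):
            if _n(grp) < min_n and len(groups) > 1:
                j = i - 1 if i > 0 else i + 1
                groups[j] = groups[j] + grp if j < i else grp + groups[j]
                del groups[i]
                merged = True
                break

    pooled, flagged = [], []
    for grp in groups:
        raw = {}
        for c in grp:
            for a, k in zip(c.ages, c.counts):
                raw[a] = raw.get(a, 0) + k
        start = min(c.start_age for c in grp)
        full = range(start, max(raw) + 1)
        label = "–".join(c.label for c in grp if c.label) or grp[0].label
        comp = AgeComposition(ages=tuple(full),
                              counts=tuple(raw.get(a, 0) for a in full),
                              start_age=start, label=label)
        if comp.n < min_n:
            flagged.append(label)
            warnings.warn(f"pooled composition '{label}' still has n={comp.n} < {min_n}")
        pooled.append(comp)
    return pooled, flagged


def predict_longevity(Z: float, N0: float, recruit_age: int = 6) -> int:
    """Largest integer age with at least one expected survivor.

    Under N(a) = N0 * exp(-Z * (a - recruit_age)) this is
    floor(recruit_age + ln(N0) / Z).
    """
    if not (Z > 0):
        raise ValueError("Z must be positive")
    if N0 < 1:
        raise ValueError("N0 must be at least 1")
    return int(math.floor(recruit_age + math.log(N0) / Z))
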