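"""von Bertalanffy growth baseline and the relative growth index G.

The growth index G is the ratio of an observed length-at-age to the
length-at-age predicted by a fixed modern von Bertalanffy (VB) baseline.
Because both numerator and denominator refer to the same age, G is
age-invariant for a population whose growth differs from the baseline by a
constant multiplier, which makes it comparable across samples with very
different age compositions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "VBParams",
    "MODERN_VB",
    "vb_length",
    "fit_vb",
    "growth_index",
    "group_growth_index",
    "GrowthFitError",
]


class GrowthFitError(ValueError):
    """Raised when a VB fit is under-determined or fails to converge."""


@dataclass(frozen=True)
class VBParams:
    """von Bertalanffy parameters: L(t) = L_inf * (1 - exp(-K * (t - t0))).

    Attributes
    ----------
    L_inf : asymptotic length (cm)
    K : growth coefficient (per year)
    t0 : theoretical age at zero length (years)
    """

    L_inf: float
    K: float
    t0: float
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (self.L_inf > 0):
            raise ValueError(f"L_inf must be positive, got {self.L_inf}")
        if not (self.K > 0):
            raise ValueError(f"K must be positive, got {self.K}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("diagnostics", None)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VBParams":
        return cls(L_inf=float(d["L_inf"]), K=float(d["K"]), t0=float(d["t0"]))


#: Modern Icelandic-shelf cod baseline (fit to ~15k survey fish, 2000-2010).
MODERN_VB = VBParams(L_inf=148.0, K=0.098, t0=-0.63)


def vb_length(age, params: VBParams = MODERN_VB):
    """Predicted length (cm) at `age` (years) under the VB baseline.

    Accepts scalars or arrays. Ages below t0 are outside the model domain
    (they would imply negative length) and raise a ValueError; age == t0
    returns exactly 0.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < params.t0):
        raise ValueError(f"age below t0={params.t0} is outside the VB domain")
    out = params.L_inf * (1.0 - np.exp(-params.K * (age - params.t0)))
    return float(out) if out.ndim == 0 else out


def fit_vb(ages, lengths, p0=None, bounds=None, maxfev=10000) -> VBParams:
    """Nonlinear least-squares fit of the VB curve to length-at-age pairs.

    Requires at least 4 pairs spanning at least 3 distinct ages (3 free
    parameters). Initialisation: L_inf = 1.1*max(L), K = 0.1, t0 = 0, with
    box bounds keeping L_inf in (max L, 5*max L) and K in (1e-4, 2) so the
    optimiser behaves on sparse samples.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if ages.shape != lengths.shape:
        raise GrowthFitError("ages and lengths must have equal shape")
    if ages.size < 4:
        raise GrowthFitError(f"need >= 4 pairs, got {ages.size}")
    if np.unique(ages).size < 3:
        raise GrowthFitError("need >= 3 distinct ages to identify 3 parameters")
    if np.any(lengths <= 0):
        raise GrowthFitError("lengths must be positive")

    lmax = float(lengths.max())
    if p0 is None:
        p0 = (1.1 * lmax, 0.1, 0.0)
    if bounds is None:
        bounds = ([lmax, 1e-4, -10.0], [5.0 * lmax, 2.0, 10.0])

    def _vb(t, L_inf, K, t0):
        return L_inf * (1.0 - np.exp(-K * (t - t0)))

    try:
        popt, pcov = curve_fit(_vb, ages, lengths, p0=p0, bounds=bounds, maxfev=maxfev)
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence path
        raise GrowthFitError(f"VB fit did not converge: {exc}") from exc

    resid = lengths - _vb(ages, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((lengths - lengths.mean()) ** 2))
    diagnostics = {
        "n": int(ages.size),
        "rss": ss_res,
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
        "param_se": np.sqrt(np.diag(pcov)).tolist(),
    }
    return VBParams(L_inf=float(popt[0]), K=float(popt[1]), t0=float(popt[2]),
                    diagnostics=diagnostics)


def growth_index(length, age, params: VBParams = MODERN_VB):
    """Relative growth index G = observed length / baseline length-at-age.

    G < 1 indicates slower growth than the baseline, G > 1 faster.
    Vectorised over scalars or arrays.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length must be positive")
    expected = vb_length(age, params)
    if np.any(np.asarray(expected) <= 0):
        raise ValueError("baseline length is non-positive at the given age")
    out = length / expected
    return float(out) if out.ndim == 0 else out


def group_growth_index(records: pd.DataFrame, by=("century", "region"),
                       params: VBParams = MODERN_VB, min_n: int = 2,
                       length_col: str = "length", age_col: str = "age") -> pd.DataFrame:
    """Per-group mean G with its standard error and sample size.

    Groups with fewer than `min_n` records get ``flagged=True`` (their SE is
    undefined or unstable); empty groups simply do not appear.
    """
    df = records.dropna(subset=[length_col, age_col]).copy()
    df["G"] = growth_index(df[length_col].to_numpy(), df[age_col].to_numpy(), params)
    rows = []
    for keys, grp in df.groupby(list(by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        g = grp["G"].to_numpy()
        n = g.size
        se = float(np.std(g, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(dict(zip(by, keys)) | {
            "mean_G": float(g.mean()),
            "se_G": se,
            "n": int(n),
            "flagged": n < min_n,
        })
    return pd.DataFrame(rows)
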