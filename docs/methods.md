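# Methods

`otodem` reconstructs the demography of a fish population from otolith
measurements alone: transverse-section widths give body lengths, annual
increments give ages, age compositions give mortality, mortality gives
longevity and relative abundance, and the carbonate's oxygen isotopes give
the thermal context. This note documents the models, the constants they
ship with, the synthetic-data generator used for validation, and the design
choices made where the design was genuinely open.

## Length back-calculation and the slow-growth bias

Fish length F (cm) is predicted from otolith transverse-section width O
(μm) by the log-log allometry

    ln F = 1.366 ln O − 8.05        (R² = 0.95, n = 114 modern cod)

Otoliths of slow-growing fish are slightly larger than those of
fast-growing fish of the same length, so applying a modern (fast-growth)
calibration to slow-growing historical otoliths overestimates length. The
bias model is anchored at one calibrated point — a 7.7% proportional
overestimate at relative growth G = 0.80 (a 20% growth reduction, the
slowest observed) — and declines to zero at G = 1. Between the anchor and
G = 1 the bias is interpolated **linearly** in G and clamped outside that
interval; linearity is the minimal assumption given a single anchor point,
and both endpoints are configurable via `BiasModel`.

In the pipeline the correction is applied per century using that century's
estimated mean G, in a single pass (raw lengths → G → corrected lengths).
Because the estimated G is itself inflated by the same bias, one pass
removes most but not all of the error: at G = 0.8 a noiseless cohort
retains ≈2.3% residual overestimation (the exact correction requires the
true G, which is unknowable for real material). We deliberately do not
iterate to the fixed point; the correction is an ex-post adjustment whose
magnitude is reported alongside the uncorrected values, and the
`bias_correct` flag makes it optional.

## Growth baseline and the index G

The modern baseline is a von Bertalanffy curve

    L(t) = L∞ (1 − e^(−K (t − t₀))),  L∞ = 148.0 cm, K = 0.098 yr⁻¹, t₀ = −0.63

shipped as constants (`MODERN_VB`), not re-fit: the raw modern survey data
behind it are not part of this package. The relative growth index
G = L_obs / L_baseline(age) is age-invariant whenever growth differs from
the baseline by a constant multiplier, so G can be compared across samples
with different age compositions. `fit_vb` is provided for users with their
own length-at-age data; it uses bounded nonlinear least squares
(initialisation L∞ = 1.1·max L, K = 0.1, t₀ = 0; bounds
L∞ ∈ (max L, 5·max L), K ∈ (10⁻⁴, 2), t₀ ∈ (−10, 10)), which converges
reliably on sparse samples.

## Mortality

Two estimators of total instantaneous mortality Z act on an integer age
composition that starts at the first fully recruited age (default 9, moved
to the modal age when the composition clearly peaks later — the `peak_rule`
flag):

* **Catch curve**: unweighted OLS of ln(count) on age over positive-count
  ages (no +1 smoothing); Z = −slope, SE = the slope's SE.
* **Chapman–Robson**: on recoded ages x = age − start_age with T = Σx and
  n fish, Ŝ = T/(n + T − 1), Z = −ln Ŝ. SE by the delta method from
  Var(Ŝ) = Ŝ(Ŝ − (T−1)/(n+T−2)). This is the original minimum-variance
  unbiased survival estimator; the small-sample Z bias-corrected variant is
  not applied (the point estimate matches the geometric maximum-likelihood
  estimator to O(1/n), which the tests verify against a brute-force
  likelihood grid).

The two are combined by a mean weighted by **1/SE** (literally inverse-SE;
conventional inverse-variance weighting is available via
`inverse_variance=True`). The combined SE 1/Σ(1/SE) is reported but flagged
approximate. Centuries with fewer than 10 aged fish are pooled with the
nearest adjacent century (earlier preferred) before estimation.

Longevity is the last age with at least one expected survivor under
exponential survivorship: floor(recruit_age + ln N₀ / Z), with N₀ = 3195
age-6 recruits as the modern reference. With Z = 0.19 this gives 48 years.
Note the same rule at the modern Z = 0.55 gives 20 years, one year above
the 19 sometimes quoted; the rule is kept as stated rather than tuned.

## Abundance and catch

With unit annual recruitment at age 6, the expected adult abundance index
is the survivorship sum A(Z) = Σ_{a=6..21} e^(−Z(a−6)), evaluated in closed
form. It is explicitly **relative** (numbers, not biomass) and assumes
stable recruitment.

Pre-record catches are reconstructed from the human population and a
piecewise-constant per-capita cod-consumption schedule (kg/person/yr):
400 (877–1200), 600 (1200–1400), 400 (1400–1600), 600 (1600–1700),
400 (1700–1800); period boundaries belong to the later period. Catch
components (domestic, export, foreign) are kept separate and summed.

Regressing per-period Z on per-period catch (in '000 t) by plain OLS gives
a line whose zero-catch intercept estimates natural mortality M, since at
zero catch all mortality is natural. The underlying relationship is
nonlinear at high catch; OLS is retained for comparability and robust
options are off by default. `catch_from_z` inverts the line and flags
extrapolation.

## Isotopes

Sectioned otoliths assayed at two life stages are collapsed to one value
with a 30% juvenile / 70% adult weighting (the weighting that matches
whole-section assays in a region- and century-matched pair design;
re-derivable via `matched_pair_offset`). Whole-otolith (modern, powdered)
assays are shifted onto the weighted-section scale by subtracting 0.44‰
(δ¹³C) and 0.17‰ (δ¹⁸O). A Suess-effect correction for modern samples is
config-only (default magnitude 0 with a logged warning, onset 1850):
its magnitude is dataset-specific and no default would be defensible.

Temperature differences follow ΔT = −Δδ¹⁸O / 0.21 °C per ‰. The 0.21
slope is the least-squares constant over the five calibrated
(Δδ, ΔT) pairs the thermometer must reproduce (per-pair implied slopes
0.208–0.212); a different thermometry equation can be supplied through
`CalibrationConstants`. Chronology trends are OLS of δ¹⁸O on calendar year
and are always fit **within one dataset** — the two archival assay series
(two-stage sectioned vs whole-section) are never merged, as they are
consistent only internally.

## Century trends

Lengths, G, and isotope values are modelled as y ~ century + region
(additive, reference-coded, no interaction). Per-century estimated
marginal means average the model's predictions over the region levels with
equal weights — the standard EMM convention for reporting a factor adjusted
for an unbalanced companion factor. Percentile summaries use linear
interpolation between order statistics (quantile type 7). Classical t/F
inference, no multiple-testing correction.

## Synthetic cohort generator

The generator emulates exactly the structure the estimators assume:

* ages ~ truncated geometric, P(a) ∝ e^(−Z(a−recruit_age)) on
  [recruit_age, max_age]; max_age defaults to 30 (beyond any plausibly
  observed age) and truncation is explicit;
* lengths = G·VB(age)·e^ε with ε ~ N(0, cv) in log space (multiplicative
  lognormal noise keeps lengths positive; the error family of the modern
  baseline fit is not known, so lognormal is this package's choice);
* otolith widths invert the allometry and are inflated by
  (1 + γ(1 − G)), with γ = 0.279 chosen so that a 20% growth reduction
  produces exactly the calibrated 7.7% back-calculation bias through the
  1.366 exponent: (1 + 0.2·0.279)^1.366 = 1.077;
* optional reader ageing error: age ~ N(age, age·0.038) rounded, floored
  at 1 (the 3.8% reader CV);
* δ¹⁸O from a temperature via the 0.21‰/°C thermometer plus assay noise;
* regions are assigned W/NW with a configurable probability (default 0.5)
  and W fish receive a configurable length offset, so the region-adjusted
  GLM/EMM stage has something to adjust for;
* multi-period scenarios set Z = M + b·catch per period (defaults M = 0.19,
  b = 0.0015 Z per '000 t) and simulate an independent cohort per period.

One integer seed drives everything through deterministically spawned
per-stage substreams; repeated runs are bitwise identical.

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real material: taphonomic loss and site-dependent
preservation, gear selectivity and truncation of large sizes, inter-annual
recruitment variability, individual growth heterogeneity beyond a shared
multiplier, movement between regions, and water-mass δ¹⁸O variation.
Parameter recovery here validates the estimators under their own
assumptions, not the assumptions themselves.

## Problem sizes and tolerances

Validation runs use cohorts of 400–5000 fish and scenarios of 800–1200
fish per period: large enough that estimator noise sits well inside the
stated tolerances (±0.05 for a single Z estimator at n = 5000, ±0.03 for
the weighted combination, 2 SE for regression intercepts), small enough
that the whole suite runs in seconds. The chi-square goodness-of-fit check
of the age law uses 10⁵ draws at a fixed seed and α = 0.01. Closed-form
identities (abundance index vs brute-force summation, EMM vs cell-mean
averaging) are asserted to 10–12 decimals.

## Known limitations

* The bias correction with estimated G under-corrects by design (single
  pass); see above.
* The Chapman–Robson SE formula assumes an untruncated geometric
  composition; under heavy right-truncation the CR point estimate is
  biased upward and only the catch curve is robust — the reason both are
  computed and combined.
* Absolute temperatures are out of scope; only differences and trends are
  converted, and only within one assay dataset.
* Real archival per-otolith data are not distributed with the package, so
  real-data marginal means cannot be reproduced here; all recovery claims
  are against synthetic truth.
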