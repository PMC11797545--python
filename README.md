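# otodem

Reconstruction of a fish population's demographic history — length, growth,
mortality, longevity, relative abundance, catch, and thermal context — from
otolith measurements alone.

Otoliths (fish earstones) are metabolically inert carbonate structures whose
annual growth bands record age, whose size records body length, and whose
oxygen-isotope composition records water temperature. At archaeological
fish-processing sites they survive for centuries, which makes them the only
quantitative record of a fish population before fisheries data existed.
`otodem` packages the full analysis chain needed to turn a table of
excavated (or simulated) otoliths into century-level population dynamics,
together with a synthetic-cohort generator with known truth so that every
stage can be validated end to end. It is aimed at fisheries scientists and
archaeo-ichthyologists working with aged otolith collections.

## The models at the core

* **Back-calculation**: ln F = 1.366 ln O − 8.05 (F length in cm, O
  transverse-section width in μm), with a slow-growth bias correction
  (7.7% overestimation at relative growth G = 0.8, linear to zero at G = 1).
* **Growth**: von Bertalanffy baseline L(t) = L∞(1 − e^(−K(t−t₀))) with the
  modern reference L∞ = 148.0 cm, K = 0.098 yr⁻¹, t₀ = −0.63; the
  age-invariant relative growth index G = L_obs / L(age).
* **Mortality**: catch-curve (−slope of ln numbers on age) and
  Chapman–Robson (Ŝ = T/(n+T−1), Z = −ln Ŝ) estimators of the total
  instantaneous mortality Z, combined by an inverse-SE-weighted mean.
* **Longevity & abundance**: exponential survivorship N(a) = N₀e^(−Z(a−a₀));
  longevity is the last age with ≥ 1 expected survivor, and the relative
  adult abundance index is A(Z) = Σ_{a=6..21} e^(−Z(a−6)).
* **Catch & natural mortality**: catch reconstructed from human population ×
  per-capita consumption; OLS of Z on catch ('000 t) whose zero-catch
  intercept estimates the natural mortality rate M.
* **Thermometry**: otolith δ¹⁸O decreases with temperature at 0.21 ‰/°C;
  assay strategies are intercalibrated (30/70 juvenile/adult weighting,
  whole-otolith offsets 0.44‰ δ¹³C / 0.17‰ δ¹⁸O) before trends are fit.
* **Trends**: additive century+region linear models with per-century
  estimated marginal means.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Simulate a cohort of 5000 fish dying at Z = 0.2/yr, then recover its
demography from the otolith table alone:

```python
import otodem as od

cfg = od.SimulationConfig(n_fish=5000, Z_true=0.2, seed=42,
                          recruit_age=9, max_age=40)
records, truth = od.simulate_cohort(cfg)

comp = od.build_age_composition(records["age"].to_numpy(), min_age=9)
cc, cr = od.catch_curve_z(comp), od.chapman_robson_z(comp)
z = od.combine_z([cc, cr])
print(f"catch curve     Z = {cc.Z:.3f} +/- {cc.SE:.3f}")
print(f"Chapman-Robson  Z = {cr.Z:.3f} +/- {cr.SE:.3f}")
print(f"weighted        Z = {z.Z:.3f}   (truth {truth.Z_true})")
print(f"longevity  = {od.predict_longevity(z.Z, 3195, 6)} years")
print(f"abundance  = {od.abundance_index(z.Z):.3f} "
      f"(pristine Z=0.19: {od.abundance_index(0.19):.3f})")
```

prints

```
catch curve     Z = 0.206 +/- 0.006
Chapman-Robson  Z = 0.203 +/- 0.003
weighted        Z = 0.204   (truth 0.2)
longevity  = 45 years
abundance  = 5.210 (pristine Z=0.19: 5.503)
```

Both estimators land within ±0.01 of the generating mortality; the
longevity is the age at which 3195 age-6 recruits decay to a single
expected survivor, and the abundance index is the survivorship sum over
ages 6–21 (a pristine Z of 0.19 supports ~5.5 relative adults per recruit
versus ~1.8 at a heavily fished Z of 0.79).

The same chain is available from the shell:

```sh
otodem simulate --out cohort/ --seed 42 --n-fish 5000 --z 0.2
otodem run --in cohort/cohort.csv --out report/
```

which writes the enriched record table, per-century growth and mortality
tables, and `report.json` with longevity, abundance indices, isotope
trends, and GLM marginal means.

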