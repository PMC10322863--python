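# fluxlegacy

Drought **legacy effects** — reduced ecosystem function in the year(s)
*after* a drought, not explained by concurrent weather — are hard to pin
down at the ecosystem scale. `fluxlegacy` implements the full analysis chain
used to detect them in multi-year eddy-covariance records from forest sites:

1. **Eddy-covariance post-processing** — friction-velocity (u\*) threshold
   detection by the moving-point method with bootstrap uncertainty,
   gap-filling by marginal distribution sampling (MDS), and nighttime-method
   flux partitioning of NEE into GPP and R<sub>eco</sub> via the
   Lloyd–Taylor temperature response
   R(T) = R_ref · exp[E₀ (1/(T_ref−T₀) − 1/(T−T₀))].
2. **Multi-scale drought indexing** — the standardized
   precipitation–evapotranspiration index (SPEI) at daily resolution for
   aggregation windows of 5–365 days: Hargreaves PET, k-day climatic water
   balance D_k = Σ(P − PET), log-logistic standardization per calendar day
   (unbiased probability-weighted moments), SPEI = Φ⁻¹(F(D_k)).
3. **Greenness phenology** — green chromatic coordinate
   G_cc = G/(R+G+B) from canopy images, outlier filtering, a double-logistic
   fit g(t) = b + a[σ(c₁(t−t₁)) + σ(−c₂(t−t₂)) − 1], and season start/end
   from the extrema of the curvature change rate, with refit-based
   uncertainty.
4. **Fingerprint correlations** — day-of-year × aggregation-scale Pearson
   correlations between per-calendar-day standardized fluxes and SPEI,
   showing when in the season and at which drought time scale water
   anomalies couple to the fluxes.
5. **Legacy regression** — restricted cubic spline (RCS) models of daily GPP,
   g(y) = β₀ + β₁x + Σᵢ βᵢCᵢ(x), comparing a concurrent-driver model
   (PPFD, SWC) against one that adds drought history (SPEI_90, SPEI_365) via
   AIC = 2k − 2 ln L̂, per-year mean percentage error, and Wald-χ² feature
   importance (χ² = β̂_S′ Σ̂_S⁻¹ β̂_S, importance = χ² − df).

A **synthetic-site generator** with full ground truth (true u\* threshold,
Lloyd–Taylor and light-response parameters, phenology dates, and an
injectable post-drought GPP suppression driven by the lagged 365-day water
deficit) makes every stage testable without tower data.

## Worked example

```python
from fluxlegacy.pipeline import legacy_experiment

ex = legacy_experiment(seed=1, legacy_gain=0.7)   # 6 years, drought in year 4
c = ex.comparison
print(f"delta AIC {c.delta_aic:+.0f}")
print(c.per_year.round(1).to_string(index=False))
```

prints (simulation, u\* filtering, SPEI and both spline fits run underneath):

```
delta AIC -117
 year  mpe_simple  mpe_full  delta_mpe
 2016         2.1      -2.1       -4.3
 2017        -0.4       2.1        2.5
 2018        -1.5      -0.4        1.1
 2019       -13.8      -6.2        7.6
 2020         3.1      -2.4       -5.6
```

The concurrent-driver model overestimates 2019 growing-season GPP by 13.8%
(negative MPE = overestimation) — the injected legacy year — while every
other year sits within a few percent. Adding drought history cuts that
error to 6.2% and lowers the AIC by 117: the signature of a legacy effect.
The `examples/` directory walks through each capability (simulation,
u\*/gap-filling, partitioning and budgets, SPEI, phenology, fingerprint,
legacy detection) as short narrative scripts.

## Benchmarking against the deposited site data

The processed daily data of the study site are archived on zenodo
(doi:10.5281/zenodo.7638744). They are not bundled here; given a daily CSV
exported from the deposit, `fluxlegacy.benchmark.run_legacy_benchmark`
repeats the two-model comparison on the real record.
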