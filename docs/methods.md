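# Methods

This note documents the models, parameter choices and numerical decisions
behind `fluxlegacy`, and what the synthetic-site tests do and do not show
about real tower data.

## Synthetic site

The generator emulates a temperate deciduous forest observed for six years
with one severe drought-and-heat year, at half-hourly resolution
(timestamps mark interval ends, local standard time, no DST).

**Weather.** Daily precipitation follows a two-state occurrence chain
(P(wet|dry) = 0.3, P(wet|wet) = 0.6) with Gamma(0.8) amounts scaled so the
long-run annual total equals `annual_precip_mean` (default 550 mm; the
Monte-Carlo mean over 400 simulated years is verified to within 2%). Daily
mean temperature is an annual sinusoid (mean 9.5 °C, amplitude 9 °C,
peak mid-July) plus AR(1) noise (ρ = 0.8); the diurnal range shrinks on wet
days. A drought year applies a precipitation multiplier (default 0.5) and a
temperature offset (+1.5 °C). Weather and process noise come from separate
sub-streams of the seed, so toggling the biology never changes the weather.

**Radiation.** Clear-sky shortwave from solar geometry times a cloud factor
tied to precipitation occurrence; PPFD = 2.1 µmol J⁻¹ × SW_IN (standard
approximation). Night is defined as SW_IN < 10 W m⁻² throughout the
package; note that twilight rows (0 < SW_IN < 10) carry a little
photosynthesis, which keeps nighttime-method parameter recovery close to,
but not exactly at, the truth on simulated data (exactness is tested on
purpose-built pure-respiration tables instead).

**Biology.** R<sub>eco</sub> = Lloyd–Taylor(TA; R_ref = 3.8 µmol m⁻² s⁻¹,
E₀ = 180 K, T_ref = 15 °C, T₀ = −46.02 °C). Potential GPP is a rectangular
hyperbola of PPFD (α = 0.05, GPP_max = 30 µmol m⁻² s⁻¹) modulated by a
soil-moisture stress ramp (linear between 12 and 25 vol%), a normalized
double-logistic phenology window (t₁ = 120, c₁ = 0.15, t₂ = 290,
c₂ = 0.10), and the legacy multiplier (below). These defaults give annual
budgets of roughly GPP 1400, R<sub>eco</sub> 1100 and NEP 150–400 gC m⁻²,
the right order for a productive temperate forest. Soil moisture is a
single 500-mm bucket: infiltration from precipitation, GPP-proportional
transpiration, drainage above field capacity; saturation excess leaves as
drainage so the mass balance closes exactly (tested to 1e−6 per step).

**Legacy mechanism.** The multiplier ramps linearly from 1 to `legacy_gain`
as the 365-day water deficit (PET − P), **lagged by 270 days**, rises from
200 to 400 mm. The lag places a drought's autumn deficit peak on the *next*
growing season: with the default drought year, the multiplier averages
≈ 0.78 over the post-drought growing season (for gain 0.7) and ≈ 1
everywhere else. Without the lag the deficit decays over winter and no
post-drought suppression exists. The ramp bounds come from the generator's
own climatology (normal-year deficits stay below 200 mm; the drought year
reaches ≈ 390 mm). This linear-ramp mechanism is a deliberately simple
stand-in for the physiological pathways (hydraulic damage, carbohydrate
depletion) that produce real legacy effects; nothing about it is a claim
about any real site.

**Measurement model.** Gaussian noise on NEE (default sd 1 µmol m⁻² s⁻¹);
nighttime NEE multiplied by `night_suppression_factor` (default 0.5) where
u\* < 0.35 m s⁻¹; gaps (default 10%) as random singles plus two-day blocks.
Night u\* is lognormal with median 0.42 m s⁻¹, placing the true threshold
near the 35th percentile of the night distribution as at real sites — the
moving-point method needs unsuppressed classes among the "following 10" to
see the plateau.

What passing these tests does **not** show: real data have storage-flux
corrections, advection, sensor drift, non-Gaussian error tails, and
phenology–moisture interactions the generator omits; recovery bounds here
are necessary, not sufficient, conditions for field performance.

## u* threshold

Moving-point method per season (DJF/MAM/JJA/SON, December attached to the
following year): night data split into 6 equal-count temperature classes,
each into 20 equal-count u\* classes; the threshold class is the first
whose mean NEE reaches 95% of the mean of the following (up to) 10 classes.
Two guards make the null case behave: a temperature class whose *lowest*
u\* class already meets the criterion reports "no threshold" (there is no
suppression to detect), and a season reports one only when at least half of
its evaluated temperature classes found one. The reported threshold is the
midpoint between the last deficient and the first plateau class mean
(the step lies between them). Classes with |r(TA, u\*)| > 0.4 are excluded;
seasons need ≥ 120 night records; the annual value is the maximum over
seasons; bootstrap (default 100 draws) resamples whole nights.

## Gap-filling

MDS look-up schedule: 3-covariate window (SW_IN 50 W m⁻², TA 2.5 °C, VPD
5 hPa) at ±7 then ±14 days (grade A); SW_IN-only at ±7 days (grade B);
mean diurnal course (same half-hour ±1 h) at ±0–2 days (grade B) then ±3–7
(grade C); then all routes with windows widening in 7-day steps (grade C).
Filled value = unweighted donor mean; donor sd kept as uncertainty. For
meteorological targets (TA, VPD) the diurnal-course route runs first: at
night the remaining covariates cannot discriminate half-hours and the
look-up route would average the whole diurnal cycle. VPD is derived from TA
and RH via the Magnus formula (6.1078 hPa, 17.08085, 234.175 °C) when
absent.

## Partitioning

E₀ from 15-day windows stepped 5 days (≥ 6 records, temperature range
≥ 5 °C, E₀ ∈ [30, 450] K, relative SE < 50%); the final estimate is the
**median** of retained windows — ranking by relative SE and averaging the
best few prefers inflated E₀, because the relative error shrinks as E₀
grows (≈ +50 K bias at noise sd 1 in simulation). R_ref from 7-day windows
stepped 4 days by through-origin regression on the exponential temperature
term, interpolated linearly to every half-hour. R<sub>eco</sub> is then
evaluated at all half-hours and GPP = R<sub>eco</sub> − NEE (positive =
uptake; negatives flagged, not clipped). Monthly Michaelis–Menten
light-response fits report GPP at PPFD = 2000 µmol m⁻² s⁻¹.

## SPEI

Hargreaves PET (λ = 2.45 MJ kg⁻¹) with FAO-style extraterrestrial
radiation. For each scale and calendar day, a three-parameter log-logistic
is fitted by unbiased probability-weighted moments to the D_k values pooled
over a ±15-day window across the reference years. Two refinements keep the
per-day standardization unbiased: the pooled values are **anomalies** (the
day's climatological mean removed and a circularly smoothed climatological
sd divided out), because the raw seasonal trend across a 31-day window
otherwise widens and shifts the fitted distribution (per-day sd down to
0.67 observed without it); and pools whose L-moments fall outside the
log-logistic's feasible region are fitted on the mirrored sample with the
probability flipped. Parameters are keyed by day-of-year folded to a
non-leap frame (Feb 29 shares Feb 28). Probabilities are clamped to
[0.0005, 0.9995], bounding |SPEI| at 3.29. Categories: ≤ −1 moderate,
≤ −1.5 severe, ≤ −2 extreme (normal tail probability 2.3%). At exactly 30
reference years the per-day sd estimate's own sampling noise occasionally
leaves the 0.9–1.1 band at short scales; the standardization check
therefore uses an 80-year synthetic reference.

## Phenology

Daily G_cc is the 90th percentile of within-day values (suppresses
illumination variance). Filters: G_cc < 0.2 dropped; points > 3 scaled MADs
from a 15-day running median dropped, with the MAD scale estimated globally
(a rolling scale collapses at transition edges) and floored at 0.002 (the
sensor's digitization noise) so a noise-free curve is never flagged; days
whose brightness deviates > 50% from its 15-day running median dropped.
The double-logistic fit uses multi-start nonlinear least squares
(tolerance 1e−8) from quantile-derived initial values. Transition dates are
the first local maximum (season start) and last local minimum (season end)
of dκ/dt on a 0.1-day grid, restricted to the rising/falling limbs; κ is
computed analytically. Uncertainty: 100 refits on the fitted curve plus
resampled residuals. Other extremum conventions exist (the curvature method
yields four transition points); the chosen pair brackets the inflections on
the outside and is used consistently.

## Fingerprint

Fluxes are standardized per calendar day across years (z-scores; zero-
variance days missing). Cell (d, k) of the fingerprint is the Pearson
correlation of all (z, SPEI_k) pairs with DOY in [d−2, d+2] pooled across
years (≈ 5 × n_years pairs; cells with < 10 pairs missing); rows span DOY
110–300 by default, scales 5–365 days. Window summaries pool a DOY × scale
rectangle and fit OLS z ~ SPEI; with both axes standardized the slope
approximates the window's mean correlation. The default rectangles are
May (DOY 121–151) and August (DOY 213–243) at short (30–90 d) and long
(270–365 d) scales.

## Legacy regression

Restricted (natural) cubic splines per Harrell's truncated-cubic
construction with (k_max − k_min)² normalization; knots at the canonical
default quantiles (k = 3: 0.10/0.50/0.90; k = 4: 0.05/0.35/0.65/0.95;
k = 5: 0.05/0.275/0.50/0.725/0.95), a shared knot count selected by AIC
over {3, 4, 5} (ties to the smaller k). Identity link, Gaussian OLS;
AIC = 2k − 2 ln L̂ counts every coefficient plus the error variance, with
the Gaussian constants retained (affects absolute AIC, never ΔAIC).
Importance: Wald χ² over a predictor's basis columns (equals df × the
nested F statistic, verified to 1e−6); nonlinearity = spline share of the
predictor's partial sum of squares from sequential refits. Partial
dependence averages predictions over the empirical distribution of the
remaining predictors; the linear tails make extrapolation defined but
flagged. Per-year metrics: RMSE, MPE = 100·mean((obs−pred)/obs) over days
with obs ≥ 0.5 gC m⁻² d⁻¹ (avoids near-zero denominators), and the global
fit's within-year adjusted R².

**Regression sample.** `legacy_experiment` fits both models on
growing-season days (DOY 120–280). On all-year data the MPE is dominated by
shoulder-season days, where the phenology window — invisible to all
candidate predictors — produces large relative errors in every year and
drowns the legacy signal; on the growing season the expected pattern
emerges (the concurrent-driver model overestimates only the post-drought
year, by 8–21% across seeds, and adding SPEI removes most of it). The
within-year adjusted R² uses the global fit evaluated per year, not
within-year refits.

## Problem sizes and runtime

Defaults are desk-scale: six simulated years (105k half-hours) per site
run, 20 seeds for power experiments, 400 years for the precipitation
Monte-Carlo, 80 years for the SPEI standardization check, 100 refits for
phenology uncertainty, and 25–100 bootstrap draws for u\*. The full test
suite runs in about half a minute; the acceptance script in about 20
seconds.

## Known limitations

- The moving-point guards (majority rule, first-class rule) are needed for
  clean null behaviour on synthetic data; on real records with gradual
  suppression they may be conservative.
- MDS grade boundaries follow one published convention; implementations
  differ in detail.
- Hargreaves PET is temperature-based; sites with strong wind/humidity
  control on evaporative demand need a different PET choice.
- AIC knot selection retains a ~16% per-extra-column overfit probability by
  construction; on linear truths the smallest knot set is chosen in roughly
  three quarters of replicates, not always.
- The legacy mechanism is one multiplicative pathway with a fixed lag;
  detection power on real data depends on pathways and lags the generator
  does not model.
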