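"""Synthetic forest flux site with known ground truth.

Generates the three data streams the analysis chain consumes — half-hourly
fluxes/meteorology, daily climate, and daily canopy greenness — from a small
set of process rules whose parameters are part of the configuration, so every
downstream stage (u* detection, gap-filling, partitioning, SPEI, phenology,
legacy regression) can be tested against exact truth:

* daily weather: two-state precipitation occurrence chain with Gamma amounts,
  seasonal-sinusoid temperature with AR(1) noise; drought years apply a
  precipitation multiplier and a temperature offset;
* half-hourly radiation from clear-sky solar geometry times a cloud factor
  tied to precipitation; PPFD = 2.1 umol J-1 x SW_IN;
* ecosystem respiration from the Lloyd-Taylor temperature response, gross
  primary productivity from a rectangular-hyperbola light response modulated
  by soil-moisture stress, a double-logistic phenology window, and an
  optional post-drought "legacy" suppression driven by the 365-day
  climatic water deficit;
* a single-layer soil-moisture bucket (infiltration from precipitation,
  GPP-coupled transpiration, drainage);
* measurement artifacts: Gaussian noise on NEE, suppression of nighttime NEE
  below a true friction-velocity threshold, and missing-data gaps (random
  singles plus contiguous blocks).

Weather and process noise come from separate sub-streams of the seed, so the
weather can be held fixed while toggling the legacy mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fluxlegacy import spei as _spei

#: PPFD per unit shortwave irradiance, umol J-1
PPFD_PER_SW = 2.1
SECONDS_PER_HALFHOUR = 1800.0

# RNG sub-stream tags
_STREAM_WEATHER_DAILY = 0
_STREAM_WEATHER_HH = 1
_STREAM_PROCESS = 2
_STREAM_GAPS = 3
_STREAM_GCC = 4


@dataclass
class LloydTaylorTruth:
    rref: float = 3.8       # umol m-2 s-1 at 15 degC
    e0: float = 180.0       # K


@dataclass
class LightResponseTruth:
    alpha: float = 0.05     # umol CO2 / umol photon
    gpp_max: float = 30.0   # umol m-2 s-1 asymptote


@dataclass
class PhenoTruth:
    baseline: float = 0.32
    amplitude: float = 0.10
    t1: float = 120.0       # spring inflection, DOY
    c1: float = 0.15        # spring slope, d-1
    t2: float = 290.0       # autumn inflection, DOY
    c2: float = 0.10        # autumn slope, d-1


@dataclass
class SimConfig:
    """Configuration and ground truth of the synthetic site.

    Defaults emulate a temperate deciduous forest observed for six years
    (2015-2020) with one severe drought-and-heat year (2018): ~550 mm mean
    annual precipitation with the drought year at roughly half of that and
    1.5 degC warmer, a true u* threshold of 0.35 m s-1 with nighttime fluxes
    at 50% below it, 10% missing data, and 1 umol m-2 s-1 flux noise.
    """

    seed: int = 0
    years: tuple = (2015, 2016, 2017, 2018, 2019, 2020)
    latitude: float = 52.1
    annual_precip_mean: float = 550.0       # mm
    # year -> (precip multiplier, temperature offset degC)
    drought_years: dict = field(default_factory=lambda: {2018: (0.5, 1.5)})
    legacy_gain: float = 1.0                # GPP multiplier floor, (0, 1]
    # 365-day water deficit (PET - P, mm) where legacy suppression starts/saturates
    legacy_deficit_ramp: tuple = (200.0, 400.0)
    # lag (days) between the deficit window and its effect on GPP: the
    # drought's peak deficit (typically autumn) hits the *next* growing season
    legacy_lag_days: int = 270
    true_ustar_threshold: float = 0.35      # m s-1
    night_suppression_factor: float = 0.5   # (0, 1]
    gap_fraction: float = 0.10              # [0, 0.5)
    noise_sd_nee: float = 1.0               # umol m-2 s-1
    lt_params: LloydTaylorTruth = field(default_factory=LloydTaylorTruth)
    lr_params: LightResponseTruth = field(default_factory=LightResponseTruth)
    pheno_params: PhenoTruth = field(default_factory=PhenoTruth)
    # daily mean temperature sinusoid
    tmean_annual: float = 9.5               # degC
    tmean_amplitude: float = 9.0            # degC
    # greenness observation model
    gcc_noise_sd: float = 0.005
    gcc_outlier_fraction: float = 0.02      # low-illumination values < 0.2
    gcc_spike_fraction: float = 0.0         # +0.1 spikes
    # soil bucket
    swc_init: float = 32.0                  # vol %
    swc_wilt: float = 12.0
    swc_opt: float = 25.0

    def __post_init__(self):
        if len(self.years) == 0:
            raise ValueError("years must be nonempty")
        if sorted(self.years) != list(self.years):
            raise ValueError("years must be sorted ascending")
        if not (0.0 < self.legacy_gain <= 1.0):
            raise ValueError("legacy_gain must be in (0, 1]")
        if not (0.0 <= self.gap_fraction < 0.5):
            raise ValueError("gap_fraction must be in [0, 0.5)")
        if not (0.0 < self.night_suppression_factor <= 1.0):
            raise ValueError("night_suppression_factor must be in (0, 1]")
        if self.noise_sd_nee < 0 or self.annual_precip_mean < 0:
            raise ValueError("negative noise/precipitation parameters")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def double_logistic(t, baseline, amplitude, t1, c1, t2, c2):
    """g(t) = b + a * [1/(1+exp(-c1 (t-t1))) + 1/(1+exp(c2 (t-t2))) - 1]."""
    t = np.asarray(t, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-c1 * (t - t1)))
    fall = 1.0 / (1.0 + np.exp(c2 * (t - t2)))
    return baseline + amplitude * (rise + fall - 1.0)


def _phenology_window(doy, p: PhenoTruth) -> np.ndarray:
    """Season factor in [0, 1]: the normalized double-logistic shape."""
    shape = double_logistic(doy, 0.0, 1.0, p.t1, p.c1, p.t2, p.c2)
    return np.clip(shape, 0.0, 1.0)


def simulate_daily_climate(config: SimConfig) -> pd.DataFrame:
    """Daily precipitation and temperature for the configured years.

    Precipitation: first-order two-state occurrence chain (P(wet|dry)=0.3,
    P(wet|wet)=0.6) with Gamma(0.8) amounts scaled so the long-run annual
    total equals ``annual_precip_mean``. Temperature: annual sinusoid peaking
    in mid-July plus AR(1) noise (rho 0.8); the diurnal range shrinks on wet
    days. Drought years multiply amounts and shift temperature.
    """
    rng = config.rng(_STREAM_WEATHER_DAILY)
    dates = pd.date_range(f"{config.years[0]}-01-01", f"{config.years[-1]}-12-31", freq="D")
    n = len(dates)
    p_wd, p_ww = 0.3, 0.6
    pi_wet = p_wd / (1.0 + p_wd - p_ww)
    gamma_shape = 0.8
    gamma_scale = config.annual_precip_mean / (365.25 * pi_wet * gamma_shape)

    u_occ = rng.random(n)
    amounts = rng.gamma(gamma_shape, gamma_scale, size=n)
    wet = np.zeros(n, dtype=bool)
    prev = rng.random() < pi_wet
    for i in range(n):
        p = p_ww if prev else p_wd
        wet[i] = u_occ[i] < p
        prev = wet[i]
    precip = np.where(wet, amounts, 0.0)

    doy = dates.dayofyear.to_numpy().astype(float)
    seasonal = config.tmean_annual + config.tmean_amplitude * np.cos(
        2.0 * np.pi * (doy - 196.0) / 365.25)
    eps = rng.normal(0.0, 1.2, size=n)
    ar = np.empty(n)
    ar[0] = eps[0]
    for i in range(1, n):
        ar[i] = 0.8 * ar[i - 1] + eps[i]
    tmean = seasonal + ar
    trange = np.clip(rng.normal(8.0, 1.5, size=n), 1.0, None)
    trange = np.where(wet, trange * 0.6, trange)

    years = dates.year.to_numpy()
    for year, (pmult, toff) in config.drought_years.items():
        m = years == year
        precip[m] *= pmult
        tmean[m] += toff

    out = pd.DataFrame({
        "date": dates,
        "precip": precip,
        "tmin": tmean - trange / 2.0,
        "tmax": tmean + trange / 2.0,
        "tmean": tmean,
        "latitude": config.latitude,
    })
    return out


def legacy_multiplier_daily(config: SimConfig, climate: pd.DataFrame) -> pd.Series:
    """Daily GPP multiplier from the lagged 365-day climatic water deficit.

    The deficit is the 365-day sum of (PET - P) ending ``legacy_lag_days``
    before each day, so a drought's autumn deficit peak suppresses the next
    growing season (a delayed, not concurrent, response). The multiplier
    ramps linearly from 1 at the ramp start to ``legacy_gain`` at
    saturation; days without a full lagged history get 1.
    """
    pet = _spei.pet_hargreaves(climate)
    d365 = _spei.water_balance(climate["precip"], pet, 365)
    deficit = (-d365).shift(config.legacy_lag_days)
    lo, hi = config.legacy_deficit_ramp
    frac = ((deficit - lo) / (hi - lo)).clip(0.0, 1.0).fillna(0.0)
    mult = 1.0 - (1.0 - config.legacy_gain) * frac
    mult.index = pd.DatetimeIndex(climate["date"])
    mult.name = "legacy_multiplier"
    return mult


def _clear_sky_sw(latitude: float, doy: np.ndarray, hour: np.ndarray) -> np.ndarray:
    """Potential (clear-sky) shortwave at the surface, W m-2."""
    phi = np.deg2rad(latitude)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    h = np.deg2rad(15.0 * (hour - 12.0))
    cosz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(h)
    return 1361.0 * 0.75 * np.clip(cosz, 0.0, None)


def _magnus_es(ta):
    """Saturation vapour pressure (hPa), Magnus formula."""
    return 6.1078 * np.exp(17.08085 * ta / (234.175 + ta))


def simulate_halfhourly(config: SimConfig, climate: pd.DataFrame
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Half-hourly flux/met table plus the ground-truth table.

    Timestamps mark the end of each 30-min interval, local standard time.
    Returns ``(flux, truth)``; ``truth`` carries true GPP/Reco/NEE, the soil
    bucket terms, the legacy multiplier, and the gap/suppression masks.
    """
    clim_years = set(pd.DatetimeIndex(climate["date"]).year)
    if not set(config.years) <= clim_years:
        raise ValueError("climate table does not cover all configured years")
    climate = climate.sort_values("date").reset_index(drop=True)
    cdates = pd.DatetimeIndex(climate["date"])
    in_years = cdates.year.isin(config.years)
    climate_sim = climate.loc[in_years].reset_index(drop=True)
    cdates = pd.DatetimeIndex(climate_sim["date"])

    n_days = len(climate_sim)
    n = n_days * 48
    start = cdates[0] + pd.Timedelta(minutes=30)
    timestamps = pd.date_range(start, periods=n, freq="30min")
    # interval midpoints define the "current" solar position / calendar day
    mid = timestamps - pd.Timedelta(minutes=15)
    doy = mid.dayofyear.to_numpy().astype(float)
    hour = mid.hour.to_numpy() + mid.minute.to_numpy() / 60.0
    day_index = np.repeat(np.arange(n_days), 48)

    rng_w = config.rng(_STREAM_WEATHER_HH)
    rng_p = config.rng(_STREAM_PROCESS)

    # --- radiation ---
    sw_pot = _clear_sky_sw(config.latitude, doy, hour)
    wet_day = (climate_sim["precip"].to_numpy() > 0.0)
    cloud_daily = np.where(wet_day,
                           0.30 + 0.15 * rng_w.random(n_days),
                           0.70 + 0.25 * rng_w.random(n_days))
    sw_in = sw_pot * cloud_daily[day_index]
    ppfd = PPFD_PER_SW * sw_in

    # --- temperature / humidity ---
    tmean_d = climate_sim["tmean"].to_numpy()[day_index]
    trange_d = (climate_sim["tmax"] - climate_sim["tmin"]).to_numpy()[day_index]
    ta = tmean_d + (trange_d / 2.0) * np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)
    tdew = climate_sim["tmin"].to_numpy()[day_index] - 0.5
    rh = np.clip(100.0 * _magnus_es(tdew) / _magnus_es(ta), 20.0, 100.0)
    vpd = _magnus_es(ta) * (1.0 - rh / 100.0)

    # --- friction velocity ---
    night = sw_in < 10.0
    ustar = np.where(night,
                     rng_w.lognormal(np.log(0.42), 0.50, size=n),
                     rng_w.lognormal(np.log(0.50), 0.40, size=n))

    # --- precipitation per half-hour (uniform over the day) ---
    prec = climate_sim["precip"].to_numpy()[day_index] / 48.0

    # --- biology: respiration, potential GPP ---
    lt = config.lt_params
    reco = lloyd_taylor_curve(ta, lt.rref, lt.e0)
    lr = config.lr_params
    hyper = lr.alpha * ppfd * lr.gpp_max / (lr.alpha * ppfd + lr.gpp_max)
    hyper = np.where(ppfd > 0, hyper, 0.0)
    pheno = _phenology_window(doy, config.pheno_params)
    legacy = legacy_multiplier_daily(config, climate).to_numpy()[in_years][day_index]
    gpp_pot = hyper * pheno * legacy

    # --- soil moisture bucket (sequential) ---
    depth_mm = 500.0
    swc = np.empty(n)
    infil = prec.copy()
    drain = np.empty(n)
    transp = np.empty(n)
    s = config.swc_init / 100.0 * depth_mm     # storage, mm
    s_fc = 36.0 / 100.0 * depth_mm
    s_min = 5.0 / 100.0 * depth_mm
    k_drain = 0.004
    c_transp = 0.0035                          # mm per (umol m-2 s-1) per half-hour
    wilt, opt = config.swc_wilt, config.swc_opt
    gpp = np.empty(n)
    for i in range(n):
        theta = s / depth_mm * 100.0
        stress = min(max((theta - wilt) / (opt - wilt), 0.0), 1.0)
        g = gpp_pot[i] * stress
        gpp[i] = g
        d = k_drain * max(s - s_fc, 0.0)
        tr = min(c_transp * g, max(s - s_min, 0.0))
        s_new = s + infil[i] - d - tr
        cap = 60.0 / 100.0 * depth_mm
        if s_new > cap:             # saturation excess leaves as drainage
            d += s_new - cap
            s_new = cap
        drain[i] = d
        transp[i] = tr
        s = s_new
        swc[i] = s / depth_mm * 100.0

    nee_true = reco - gpp

    # --- measurement model ---
    noise = rng_p.normal(0.0, config.noise_sd_nee, size=n) if config.noise_sd_nee > 0 else 0.0
    nee_meas = nee_true + noise
    suppressed = night & (ustar < config.true_ustar_threshold)
    nee_meas = np.where(suppressed, nee_meas * config.night_suppression_factor, nee_meas)

    # --- gaps ---
    rng_g = config.rng(_STREAM_GAPS)
    gap = np.zeros(n, dtype=bool)
    n_target = int(round(config.gap_fraction * n))
    if n_target > 0:
        block_len = 96   # two-day blocks
        n_blocks = int(round(n_target / 2 / block_len))
        for _ in range(n_blocks):
            s0 = int(rng_g.integers(0, n - block_len))
            gap[s0:s0 + block_len] = True
        remaining = n_target - int(gap.sum())
        if remaining > 0:
            candidates = np.flatnonzero(~gap)
            singles = rng_g.choice(candidates, size=min(remaining, len(candidates)),
                                   replace=False)
            gap[singles] = True
    nee_obs = np.where(gap, np.nan, nee_meas)

    # --- energy fluxes (plausible closure, not used by the carbon chain) ---
    rn = 0.85 * sw_in - np.where(night, 40.0, 20.0)
    le = transp * 2.45e6 / SECONDS_PER_HALFHOUR  # latent heat of transpired water, W m-2
    g_soil = 0.05 * rn
    h = rn - le - g_soil

    flux = pd.DataFrame({
        "timestamp": timestamps,
        "NEE": nee_obs,
        "H": h, "LE": le, "Rn": rn, "G": g_soil,
        "ustar": ustar,
        "SW_IN": sw_in, "PPFD": ppfd,
        "TA": ta, "RH": rh, "VPD": vpd,
        "Prec": prec, "SWC_50": swc,
    })
    truth = pd.DataFrame({
        "timestamp": timestamps,
        "gpp_true": gpp, "reco_true": reco, "nee_true": nee_true,
        "legacy_multiplier": legacy, "pheno": pheno,
        "swc": swc, "infil_mm": infil, "drain_mm": drain, "transp_mm": transp,
        "suppressed": suppressed, "gap": gap,
    })
    return flux, truth


def lloyd_taylor_curve(ta, rref, e0, tref=15.0, t0=-46.02):
    """Lloyd-Taylor respiration, umol m-2 s-1 (duplicated here to keep the
    generator importable without the partitioning stage)."""
    ta = np.asarray(ta, dtype=float)
    return rref * np.exp(e0 * (1.0 / (tref - t0) - 1.0 / (ta - t0)))


def simulate_gcc(config: SimConfig) -> pd.DataFrame:
    """Daily canopy greenness (Gcc) with labelled contamination.

    Clean signal is the double-logistic phenology curve; contamination is a
    configurable fraction of low-illumination values (< 0.2) and positive
    spikes (+0.1). Column ``kind`` labels each day clean / low / spike so
    filter performance can be scored.
    """
    p = config.pheno_params
    if not (0 < p.t1 < 367 and 0 < p.t2 < 367):
        raise ValueError("phenology inflection dates outside year range")
    dates = pd.date_range(f"{config.years[0]}-01-01", f"{config.years[-1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    rng = config.rng(_STREAM_GCC)
    gcc = double_logistic(doy, p.baseline, p.amplitude, p.t1, p.c1, p.t2, p.c2)
    if config.gcc_noise_sd > 0:
        gcc = gcc + rng.normal(0.0, config.gcc_noise_sd, size=len(dates))
    kind = np.full(len(dates), "clean", dtype=object)
    n = len(dates)
    n_low = int(round(config.gcc_outlier_fraction * n))
    n_spike = int(round(config.gcc_spike_fraction * n))
    idx = rng.permutation(n)
    low_idx, spike_idx = idx[:n_low], idx[n_low:n_low + n_spike]
    gcc[low_idx] = rng.uniform(0.02, 0.19, size=n_low)
    gcc[spike_idx] = gcc[spike_idx] + 0.1
    kind[low_idx] = "low"
    kind[spike_idx] = "spike"
    return pd.DataFrame({"date": dates, "gcc": gcc, "kind": kind})
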