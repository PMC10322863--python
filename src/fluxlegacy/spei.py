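"""Standardized precipitation-evapotranspiration index (SPEI) at daily resolution.

The SPEI measures how unusual the climatic water balance (precipitation minus
potential evapotranspiration, P - PET) is relative to a reference climatology.
The balance is summed over an aggregation window of ``k`` days, a
three-parameter log-logistic distribution is fitted per calendar day (pooling
a +/-15 day window across the reference years), and the fitted cumulative
probability is mapped through the standard-normal quantile function. Values
are therefore in standard deviations: SPEI <= -1 is moderate drought,
<= -1.5 severe, <= -2 extreme (an occurrence probability of about 2.3%).

PET uses the Hargreaves equation, which needs only daily minimum/maximum/mean
temperature and latitude (via top-of-atmosphere radiation) and is the usual
choice when only temperature and precipitation records are available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import norm

log = logging.getLogger(__name__)

#: latent heat of vaporization, MJ kg-1 (converts radiation to mm water)
LAMBDA_MJ_KG = 2.45
#: solar constant, MJ m-2 min-1
SOLAR_CONSTANT = 0.0820

#: probability clamp before the normal quantile; bounds |SPEI| at 3.29
F_CLAMP = (0.0005, 0.9995)

CATEGORY_THRESHOLDS = {"extreme": -2.0, "severe": -1.5, "moderate": -1.0}

#: default aggregation scales (days) for fingerprint analyses, 5..365 d
DEFAULT_SCALES = (5, 10, 15, 20, 30, 45, 60, 90, 120, 150, 180, 240, 300, 365)


def extraterrestrial_radiation(latitude: float, doy) -> np.ndarray | float:
    """Daily top-of-atmosphere (extraterrestrial) solar radiation, MJ m-2 d-1.

    Standard solar geometry: inverse relative Earth-Sun distance, solar
    declination, and sunset hour angle for the given latitude and day of year.

    Parameters
    ----------
    latitude : degrees, must satisfy ``|latitude| < 66.5`` (no polar day/night)
    doy : int or array of int in 1..366
    """
    if not abs(latitude) < 66.5:
        raise ValueError(f"latitude {latitude} outside (-66.5, 66.5); polar latitudes not supported")
    doy = np.asarray(doy, dtype=float)
    if np.any((doy < 1) | (doy > 366)):
        raise ValueError("day of year must be in 1..366")
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    if ra.ndim == 0:
        return float(ra)
    return ra


def pet_hargreaves(climate: pd.DataFrame) -> pd.Series:
    """Hargreaves potential evapotranspiration, mm d-1.

    ``PET = 0.0023 * (Ra / lambda) * (tmean + 17.8) * sqrt(tmax - tmin)``
    with Ra the extraterrestrial radiation. Negative results (tmean below
    -17.8 degC) are clipped to zero; missing temperatures propagate.

    ``climate`` needs columns date, tmin, tmax, tmean, latitude.
    """
    if np.any(climate["tmin"].dropna() > climate["tmax"].dropna() + 1e-9):
        raise ValueError("tmin > tmax in climate table")
    lat = float(climate["latitude"].iloc[0])
    doy = pd.DatetimeIndex(climate["date"]).dayofyear.to_numpy()
    ra = extraterrestrial_radiation(lat, doy)
    trange = (climate["tmax"] - climate["tmin"]).clip(lower=0.0)
    pet = 0.0023 * (ra / LAMBDA_MJ_KG) * (climate["tmean"] + 17.8) * np.sqrt(trange)
    pet = pet.clip(lower=0.0)
    pet.name = "pet"
    return pet


def water_balance(precip: pd.Series, pet: pd.Series, scale: int) -> pd.Series:
    """k-day aggregated climatic water balance D_k(t) = sum_{t-k+1..t} (P - PET).

    Missing for the first k-1 days and whenever any member of the window is
    missing.
    """
    if scale < 1:
        raise ValueError("aggregation scale must be >= 1 day")
    d = (precip - pet).rolling(window=scale, min_periods=scale).sum()
    d.name = f"D_{scale}"
    return d


def fit_loglogistic(samples) -> tuple[float, float, float]:
    """Fit a three-parameter log-logistic distribution by unbiased PWMs.

    Returns (shape, scale, location) for the CDF
    ``F(x) = [1 + (scale / (x - location))^shape]^-1``.

    Uses the unbiased probability-weighted moments b0, b1, b2 of the sorted
    sample; requires >= 20 samples and nonzero variance.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 20:
        raise ValueError(f"need >= 20 samples to fit log-logistic, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample (zero variance)")
    # unbiased PWMs w_s with (1 - F)^s weights: the s-th moment downweights
    # the upper tail; w0 is the mean
    j = np.arange(1, n + 1)
    w0 = x.mean()
    w1 = np.sum((n - j) / (n - 1) * x) / n
    w2 = np.sum((n - j) * (n - j - 1) / ((n - 1) * (n - 2)) * x) / n
    shape = (2.0 * w1 - w0) / (6.0 * w1 - w0 - 6.0 * w2)
    if not np.isfinite(shape) or shape <= 1.0:
        raise ValueError(f"log-logistic PWM fit degenerate (shape {shape:.3g})")
    g1 = gamma_fn(1.0 + 1.0 / shape)
    g2 = gamma_fn(1.0 - 1.0 / shape)
    scale = (w0 - 2.0 * w1) * shape / (g1 * g2)
    loc = w0 - scale * g1 * g2
    return float(shape), float(scale), float(loc)


def loglogistic_cdf(x, shape: float, scale: float, loc: float) -> np.ndarray:
    """CDF of the three-parameter log-logistic; 0 below the location bound."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    above = x > loc
    with np.errstate(divide="ignore", over="ignore"):
        out[above] = 1.0 / (1.0 + (scale / (x[above] - loc)) ** shape)
    out[~np.isfinite(x)] = np.nan
    return out


def categorize(values: pd.Series) -> pd.Series:
    """Drought category per SPEI value: none / moderate / severe / extreme."""
    cat = pd.Series("none", index=values.index, dtype=object)
    cat[values <= CATEGORY_THRESHOLDS["moderate"]] = "moderate"
    cat[values <= CATEGORY_THRESHOLDS["severe"]] = "severe"
    cat[values <= CATEGORY_THRESHOLDS["extreme"]] = "extreme"
    cat[values.isna()] = "none"
    return cat


def _fit_calendar_pool(pool: np.ndarray) -> tuple:
    """Log-logistic fit with a mirrored fallback for left-skewed pools.

    Returns (shape, scale, location, mirrored). When the PWM fit is
    infeasible on x it is done on -x and the probabilities are flipped at
    transform time — the standardization stays monotone either way.
    """
    try:
        return (*fit_loglogistic(pool), False)
    except ValueError:
        return (*fit_loglogistic(-pool), True)


@dataclass
class SpeiModel:
    """Per-calendar-day log-logistic parameters for one aggregation scale.

    The distribution is fitted to pooled *anomalies* of the aggregated water
    balance (each pooled day's climatological mean removed), which keeps the
    seasonal location trend inside the +/-15 day pooling window from biasing
    the standardization. Calendar days are keyed by DOY folded to a non-leap
    frame; Feb 29 shares Feb 28's parameters.
    """

    scale: int
    reference_years: tuple[int, int]
    params: dict = field(default_factory=dict)     # folded DOY -> (shape, scale, loc, mirrored)
    day_mean: dict = field(default_factory=dict)   # folded DOY -> climatological mean of D_k
    day_sd: dict = field(default_factory=dict)     # folded DOY -> smoothed climatological sd
    pools: dict = field(default_factory=dict, repr=False)  # folded DOY -> fitted anomaly pool

    def transform(self, dates: pd.DatetimeIndex, d_k: pd.Series) -> pd.Series:
        """Map aggregated water-balance values to SPEI via the fitted CDFs."""
        out = np.full(len(d_k), np.nan)
        doys = _fold_doy(dates)
        vals = d_k.to_numpy(dtype=float)
        for i, doy in enumerate(doys):
            p = self.params.get(int(doy))
            if p is None or not np.isfinite(vals[i]):
                continue
            shape, scl, loc, mirrored = p
            x = (vals[i] - self.day_mean[int(doy)]) / self.day_sd[int(doy)]
            if mirrored:
                f = 1.0 - float(loglogistic_cdf(-x, shape, scl, loc))
            else:
                f = float(loglogistic_cdf(x, shape, scl, loc))
            f = min(max(f, F_CLAMP[0]), F_CLAMP[1])
            out[i] = norm.ppf(f)
        return pd.Series(out, index=d_k.index, name=f"spei_{self.scale}")


def _fold_doy(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day of year folded to a non-leap frame (Feb 29 -> Feb 28's slot)."""
    doy = dates.dayofyear.to_numpy().astype(int)
    leap = dates.is_leap_year & (doy > 59)
    return np.where(leap, doy - 1, doy)


def _pool_calendar_day(folded_doy: np.ndarray, anomalies: np.ndarray, target: int,
                       ref_mask: np.ndarray, halfwidth: int = 15) -> np.ndarray:
    """Anomaly values within +/-halfwidth days of the target calendar day
    over the reference years (circular in DOY)."""
    dist = np.abs(folded_doy - target)
    dist = np.minimum(dist, 365 - dist)
    mask = (dist <= halfwidth) & ref_mask & np.isfinite(anomalies)
    return anomalies[mask]


def spei(climate: pd.DataFrame, scales=(90, 365), reference_period: tuple[int, int] | None = None,
         pool_halfwidth: int = 15) -> pd.DataFrame:
    """Daily SPEI for each aggregation scale.

    Parameters
    ----------
    climate : daily table with date, precip, tmin, tmax, tmean, latitude
    scales : aggregation windows in days
    reference_period : (first_year, last_year) used to fit the climatology;
        defaults to the full record
    pool_halfwidth : half-width (days) of the calendar-day pooling window

    Returns
    -------
    Long-format DataFrame with columns date, scale, spei, category. A scale
    is skipped with a warning if any calendar-day pool has < 20 samples.
    """
    climate = climate.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(climate["date"])
    years = dates.year.to_numpy()
    if reference_period is None:
        reference_period = (int(years.min()), int(years.max()))
    y0, y1 = reference_period
    if y0 < years.min() or y1 > years.max():
        raise ValueError("reference period not contained in the record")
    ref_mask = (years >= y0) & (years <= y1)

    pet = pet_hargreaves(climate)
    precip = climate["precip"]
    frames = []
    folded = _fold_doy(dates)
    for k in scales:
        d_k = water_balance(precip, pet, k)
        try:
            model = _fit_scale(d_k.to_numpy(dtype=float), folded, k,
                               reference_period, ref_mask, pool_halfwidth)
        except ValueError as err:
            warnings.warn(f"scale {k} skipped: {err}")
            continue
        values = model.transform(dates, d_k)
        frames.append(pd.DataFrame({
            "date": dates, "scale": k, "spei": values.to_numpy(),
            "category": categorize(values).to_numpy(),
        }))
    if not frames:
        raise ValueError("no scale could be standardized (insufficient reference data)")
    return pd.concat(frames, ignore_index=True)


def _fit_scale(d_vals: np.ndarray, folded: np.ndarray, k: int,
               reference_period, ref_mask: np.ndarray, pool_halfwidth: int) -> SpeiModel:
    """Fit one scale's standardization: climatological day mean and
    (circularly smoothed) sd are removed before pooling so the +/-15 day
    window does not leak the seasonal trend into the fit."""
    model = SpeiModel(scale=k, reference_years=tuple(reference_period))
    raw_sd = np.full(366, np.nan)
    for doy in range(1, 366):
        m = (folded == doy) & ref_mask & np.isfinite(d_vals)
        model.day_mean[doy] = float(d_vals[m].mean()) if m.any() else np.nan
        raw_sd[doy] = float(d_vals[m].std(ddof=1)) if m.sum() > 1 else np.nan
    for doy in range(1, 366):
        idx = (np.arange(doy - pool_halfwidth, doy + pool_halfwidth + 1) - 1) % 365 + 1
        model.day_sd[doy] = float(np.nanmean(raw_sd[idx]))
    anom = ((d_vals - np.array([model.day_mean.get(int(d), np.nan) for d in folded]))
            / np.array([model.day_sd.get(int(d), np.nan) for d in folded]))
    model.pools = {}
    for doy in range(1, 366):
        pool = _pool_calendar_day(folded, anom, doy, ref_mask, pool_halfwidth)
        if len(pool) < 20:
            raise ValueError(f"calendar day {doy} pool has {len(pool)} samples (<20)")
        model.params[doy] = _fit_calendar_pool(pool)
        model.pools[doy] = pool
    return model


def fit_spei_model(climate: pd.DataFrame, scale: int,
                   reference_period: tuple[int, int] | None = None,
                   pool_halfwidth: int = 15) -> SpeiModel:
    """Fit the per-calendar-day standardization model for one scale."""
    climate = climate.sort_values("date").reset_index(drop=True)
    dates = pd.DatetimeIndex(climate["date"])
    years = dates.year.to_numpy()
    if reference_period is None:
        reference_period = (int(years.min()), int(years.max()))
    ref_mask = (years >= reference_period[0]) & (years <= reference_period[1])
    pet = pet_hargreaves(climate)
    d_k = water_balance(climate["precip"], pet, scale)
    return _fit_scale(d_k.to_numpy(dtype=float), _fold_doy(dates), scale,
                      reference_period, ref_mask, pool_halfwidth)
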