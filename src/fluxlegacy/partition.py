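"""Nighttime flux partitioning and light-response fits.

Nighttime NEE is (almost) pure ecosystem respiration, so a temperature
response fitted at night can be extrapolated to the day:

``Reco(T) = Rref * exp(E0 * (1/(Tref - T0) - 1/(T - T0)))``  (Lloyd-Taylor)

with Tref = 15 degC and T0 = -46.02 degC fixed. The temperature sensitivity
E0 is estimated once from short windows (15 d, stepped 5 d) and held
constant; the base respiration Rref is re-estimated in 7-day windows stepped
4 days and interpolated to every half-hour, so slow seasonal changes in
respiring biomass pass into Reco. GPP then follows by difference:
GPP = Reco - NEE (positive = uptake).

Monthly light-response (Michaelis-Menten / rectangular hyperbola) fits of
GPP against PPFD summarize canopy photosynthetic capacity:
``GPP = alpha * PPFD * gpp_max / (alpha * PPFD + gpp_max)``, reported at a
reference light level of PPFD = 2000 umol m-2 s-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from fluxlegacy.ustar import NIGHT_SW_MAX

log = logging.getLogger(__name__)

TREF = 15.0      # degC
T0 = -46.02      # degC

E0_WINDOW_DAYS = 15
E0_STEP_DAYS = 5
E0_MIN_RECORDS = 6
E0_MIN_TRANGE = 5.0
E0_BOUNDS = (30.0, 450.0)
E0_MAX_RSE = 0.5
E0_N_BEST = 3

RREF_WINDOW_DAYS = 7
RREF_STEP_DAYS = 4

PPFD_REF = 2000.0


@dataclass
class LloydTaylorParams:
    rref: float
    e0: float
    tref: float = TREF
    t0: float = T0


@dataclass
class LightResponseFit:
    alpha: float        # apparent quantum yield, umol CO2 / umol photon
    gpp_max: float      # asymptote, umol m-2 s-1
    gpp_ref: float      # GPP at PPFD = 2000
    group: str = ""
    n: int = 0


def lloyd_taylor(ta, rref, e0, tref: float = TREF, t0: float = T0):
    """Lloyd-Taylor respiration (umol m-2 s-1); monotone increasing for T > T0."""
    ta = np.asarray(ta, dtype=float)
    return rref * np.exp(e0 * (1.0 / (tref - t0) - 1.0 / (ta - t0)))


def _exp_term(ta, e0):
    return np.exp(e0 * (1.0 / (TREF - T0) - 1.0 / (np.asarray(ta, float) - T0)))


def _night_mask(table: pd.DataFrame) -> pd.Series:
    return (table["SW_IN"] < NIGHT_SW_MAX) & table["NEE"].notna() & table["TA"].notna()


def fit_e0(table: pd.DataFrame) -> float:
    """Temperature sensitivity E0 (K) from u*-filtered nighttime data.

    Lloyd-Taylor is fitted by nonlinear least squares in 15-day windows
    shifted by 5 days. A window estimate is retained when it has >= 6
    records, a temperature range >= 5 degC, E0 within [30, 450] K and a
    relative standard error below 50%. The final E0 is the median of the
    retained window estimates (ranking windows by relative standard error
    and averaging only the best few systematically prefers inflated E0
    values, because the relative error shrinks as E0 grows).
    """
    night = table.loc[_night_mask(table), ["timestamp", "NEE", "TA"]]
    if night.empty:
        raise ValueError("no nighttime records for E0 estimation")
    t0 = night["timestamp"].iloc[0].normalize()
    day = ((pd.DatetimeIndex(night["timestamp"]) - t0).days).to_numpy()
    nee = night["NEE"].to_numpy(dtype=float)
    ta = night["TA"].to_numpy(dtype=float)

    estimates = []   # (rse, e0)
    for start in range(0, int(day.max()) + 1, E0_STEP_DAYS):
        m = (day >= start) & (day < start + E0_WINDOW_DAYS)
        if m.sum() < E0_MIN_RECORDS or np.ptp(ta[m]) < E0_MIN_TRANGE:
            continue
        try:
            popt, pcov = curve_fit(lloyd_taylor, ta[m], nee[m],
                                   p0=(float(np.mean(nee[m])), 100.0),
                                   maxfev=5000)
        except RuntimeError:
            continue
        e0 = popt[1]
        se = np.sqrt(np.diag(pcov))[1]
        if not (E0_BOUNDS[0] <= e0 <= E0_BOUNDS[1]):
            continue
        rse = se / abs(e0)
        if not np.isfinite(rse) or rse >= E0_MAX_RSE:
            continue
        estimates.append((rse, e0))
    if not estimates:
        raise ValueError(
            "E0 estimation failed: no window met the acceptance rules "
            "(>= 6 records, T range >= 5 degC, E0 in [30, 450], RSE < 50%)")
    return float(np.median([e for _, e in estimates]))


def estimate_rref_series(table: pd.DataFrame, e0: float) -> pd.Series:
    """Time-varying base respiration Rref(t), umol m-2 s-1 at 15 degC.

    Within 7-day windows stepped 4 days, Rref is the through-origin
    regression of nighttime NEE on the Lloyd-Taylor exponential temperature
    term; window estimates are assigned to the window centre and linearly
    interpolated to every half-hour (flat extrapolation at the ends).
    """
    night = table.loc[_night_mask(table), ["timestamp", "NEE", "TA"]]
    if night.empty:
        raise ValueError("no nighttime records for Rref estimation")
    ts_all = pd.DatetimeIndex(table["timestamp"])
    t0 = ts_all[0].normalize()
    day_n = ((pd.DatetimeIndex(night["timestamp"]) - t0).total_seconds() / 86400.0).to_numpy()
    nee = night["NEE"].to_numpy(dtype=float)
    term = _exp_term(night["TA"].to_numpy(dtype=float), e0)

    centers, values = [], []
    last_day = float(day_n.max())
    for start in np.arange(0.0, last_day + RREF_STEP_DAYS, RREF_STEP_DAYS):
        m = (day_n >= start) & (day_n < start + RREF_WINDOW_DAYS)
        if m.sum() < 2:
            continue
        denom = float(np.sum(term[m] ** 2))
        if denom <= 0:
            continue
        rref = float(np.sum(nee[m] * term[m]) / denom)
        centers.append(start + RREF_WINDOW_DAYS / 2.0)
        values.append(rref)
    if not values:
        raise ValueError("no Rref window had >= 2 night records")
    day_all = ((ts_all - t0).total_seconds() / 86400.0).to_numpy()
    interp = np.interp(day_all, centers, values)
    return pd.Series(interp, index=table.index, name="rref")


def partition_nighttime(table: pd.DataFrame, e0: float,
                        rref: pd.Series | None = None,
                        nee_col: str = "NEE_f") -> pd.DataFrame:
    """Partition filled NEE into Reco and GPP (nighttime method).

    ``Reco = Lloyd-Taylor(TA; Rref(t), E0)`` at every half-hour and
    ``GPP = Reco - NEE``. GPP is not clipped at zero; negative values (and
    their nighttime occurrences) are flagged in ``gpp_negative``.
    """
    if table["TA"].isna().any():
        raise ValueError("TA contains missing values; gap-fill before partitioning")
    if rref is None:
        rref = estimate_rref_series(table, e0)
    reco = rref.to_numpy() * _exp_term(table["TA"].to_numpy(dtype=float), e0)
    nee = table[nee_col].to_numpy(dtype=float)
    gpp = reco - nee
    out = table.copy()
    out["Reco_NT"] = reco
    out["GPP_NT"] = gpp
    out["gpp_negative"] = gpp < 0
    return out


def _hyperbola(ppfd, alpha, gpp_max):
    return alpha * ppfd * gpp_max / (alpha * ppfd + gpp_max)


def fit_light_response(table: pd.DataFrame, group: str = "",
                       gpp_col: str = "GPP_NT", min_records: int = 30
                       ) -> LightResponseFit | None:
    """Rectangular-hyperbola (Michaelis-Menten) fit of daytime GPP vs PPFD.

    Returns None (with a log message) when the group has fewer than
    ``min_records`` daytime rows; raises on non-convergence.
    """
    day = table.loc[(table["SW_IN"] >= NIGHT_SW_MAX)
                    & table[gpp_col].notna() & table["PPFD"].notna()]
    if len(day) < min_records:
        log.info("light response %s: only %d daytime records, skipped", group, len(day))
        return None
    ppfd = day["PPFD"].to_numpy(dtype=float)
    gpp = day[gpp_col].to_numpy(dtype=float)
    p0 = (0.05, max(float(np.percentile(gpp, 95)), 1.0))
    try:
        popt, _ = curve_fit(_hyperbola, ppfd, gpp, p0=p0, maxfev=10000)
    except RuntimeError as err:
        raise RuntimeError(f"light-response fit did not converge for {group} "
                           f"(start values {p0})") from err
    alpha, gpp_max = float(popt[0]), float(popt[1])
    return LightResponseFit(alpha=alpha, gpp_max=gpp_max,
                            gpp_ref=float(_hyperbola(PPFD_REF, alpha, gpp_max)),
                            group=group, n=len(day))


def monthly_light_response(table: pd.DataFrame, year_sets: dict,
                           months=(5, 6, 7, 8, 9)) -> pd.DataFrame:
    """Tidy table of monthly light-response fits per year-set.

    ``year_sets`` maps a label (e.g. "2018", "others") to an iterable of
    years pooled for that fit.
    """
    ts = pd.DatetimeIndex(table["timestamp"]) - pd.Timedelta(minutes=15)
    rows = []
    for label, years in year_sets.items():
        in_set = ts.year.isin(list(years))
        for month in months:
            sub = table.loc[in_set & (ts.month == month)]
            fit = fit_light_response(sub, group=f"{label}-{month:02d}")
            if fit is None:
                continue
            rows.append({"month": month, "year_set": label, "alpha": fit.alpha,
                         "gpp_max": fit.gpp_max, "gpp_ref": fit.gpp_ref, "n": fit.n})
    return pd.DataFrame(rows)
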