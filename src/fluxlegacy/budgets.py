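"""Aggregation of half-hourly fluxes to daily, monthly, annual and
growing-season carbon/energy budgets.

Carbon sums convert µmol CO2 m-2 s-1 to grams of carbon:
one half-hour contributes ``flux * 1800 s * 12.011e-6 gC µmol-1``. NEP is
reported with positive = net uptake (NEP = -NEE), matching the sign of a
carbon sink. Budget uncertainty comes from reprocessing the chain at the
bootstrapped 5% / 50% / 95% u* thresholds, which is why ``period_budget``
accepts one daily table per threshold scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SECONDS_PER_HALFHOUR = 1800.0
GC_PER_UMOL = 12.011e-6      # grams of carbon per umol CO2
HH_TO_GC = SECONDS_PER_HALFHOUR * GC_PER_UMOL

CARBON_COLS = {"NEE_f": "NEP", "GPP_NT": "GPP", "Reco_NT": "Reco"}
MET_MEAN_COLS = ("H", "LE", "Rn", "PPFD", "TA", "VPD", "SW_IN")


def daily_aggregate(halfhourly: pd.DataFrame) -> pd.DataFrame:
    """Daily sums (carbon, precipitation) and means (met) from half-hours.

    The calendar day of a half-hour is the date of the interval midpoint
    (timestamps mark interval ends). Carbon columns become gC m-2 d-1; NEP
    is sign-flipped so positive means uptake. Days with any unfilled NEE are
    flagged in ``incomplete``.
    """
    ts = pd.DatetimeIndex(halfhourly["timestamp"]) - pd.Timedelta(minutes=15)
    day = ts.normalize()
    df = halfhourly.copy()
    df["_day"] = day
    agg = {}
    for col, name in CARBON_COLS.items():
        if col not in df.columns:
            continue
        s = df.groupby("_day")[col].sum(min_count=1) * HH_TO_GC
        agg[name] = -s if name == "NEP" else s
    for col in MET_MEAN_COLS:
        if col in df.columns:
            agg[col] = df.groupby("_day")[col].mean()
    if "Prec" in df.columns:
        agg["Prec"] = df.groupby("_day")["Prec"].sum()
    if "NEE_f" in df.columns:
        agg["incomplete"] = df.groupby("_day")["NEE_f"].apply(lambda v: v.isna().any())
    out = pd.DataFrame(agg).reset_index().rename(columns={"_day": "date"})
    return out


@dataclass
class Budget:
    """One period's sums/means, optionally with u*-scenario ranges."""

    period: str
    sums: dict = field(default_factory=dict)        # NEP/GPP/Reco gC m-2, Prec mm
    means: dict = field(default_factory=dict)       # met means +/- SE
    ranges: dict = field(default_factory=dict)      # var -> (low, high) across scenarios


def _period_mask(daily: pd.DataFrame, period) -> np.ndarray:
    dates = pd.DatetimeIndex(daily["date"])
    years = np.asarray(dates.year)
    kind = period[0]
    if kind == "year":
        return years == period[1]
    if kind == "month":
        return (years == period[1]) & (np.asarray(dates.month) == period[2])
    if kind == "growing_season":
        year, sos, eos = period[1], period[2], period[3]
        doy = np.asarray(dates.dayofyear)
        return (years == year) & (doy >= int(np.floor(sos))) & (doy <= int(np.ceil(eos)))
    raise ValueError(f"unknown period kind {kind!r}")


def period_budget(daily: pd.DataFrame, period,
                  scenarios: dict | None = None) -> Budget:
    """Budget for a period: ('year', y), ('month', y, m) or
    ('growing_season', y, sos_doy, eos_doy).

    ``scenarios`` maps a u*-quantile label (e.g. 'q05', 'q95') to the daily
    table obtained by reprocessing at that threshold; the spread of the
    scenario sums gives the (possibly asymmetric) uncertainty range around
    the central value.
    """
    m = _period_mask(daily, period)
    if not m.any():
        raise ValueError(f"period {period} not covered by the data")
    sub = daily.loc[m]
    budget = Budget(period=str(period))
    for var in ("NEP", "GPP", "Reco", "Prec"):
        if var in sub.columns:
            budget.sums[var] = float(sub[var].sum())
    for var in MET_MEAN_COLS:
        if var in sub.columns:
            vals = sub[var].dropna()
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            budget.means[var] = (float(vals.mean()), se)
    if scenarios:
        for var in ("NEP", "GPP", "Reco"):
            if var not in sub.columns:
                continue
            vals = [budget.sums[var]]
            for table in scenarios.values():
                ms = _period_mask(table, period)
                vals.append(float(table.loc[ms, var].sum()))
            budget.ranges[var] = (min(vals), max(vals))
    return budget


def composites(halfhourly: pd.DataFrame, groups: dict,
               value_cols=("GPP_NT", "Reco_NT", "NEE_f", "H", "LE"),
               season_doy=(110, 300)) -> dict:
    """Monthly means, within-year cumulative daily sums, and mean diurnal
    cycles per condition group.

    ``groups`` maps a label (e.g. 'drought', 'other') to the years pooled in
    that composite; the diurnal cycle uses the 48 half-hour bins over the
    vegetation period only.
    """
    ts = pd.DatetimeIndex(halfhourly["timestamp"]) - pd.Timedelta(minutes=15)
    value_cols = [c for c in value_cols if c in halfhourly.columns]
    out = {}
    for label, years in groups.items():
        m = ts.year.isin(list(years))
        if not m.any():
            raise ValueError(f"group {label!r} matches no data")
        sub = halfhourly.loc[m].copy()
        sts = ts[m]
        sub["_month"] = sts.month
        monthly = sub.groupby("_month")[value_cols].mean()
        daily = daily_aggregate(halfhourly.loc[m])
        ddates = pd.DatetimeIndex(daily["date"])
        cum = daily.copy()
        for c in ("NEP", "GPP", "Reco"):
            if c in cum.columns:
                cum[c] = cum.groupby(ddates.year)[c].cumsum()
        veg = sts.dayofyear.isin(range(season_doy[0], season_doy[1] + 1))
        sub_veg = sub.loc[np.asarray(veg)]
        bins = (sts[np.asarray(veg)].hour * 2
                + sts[np.asarray(veg)].minute // 30)
        diurnal = sub_veg.groupby(np.asarray(bins))[value_cols].mean()
        diurnal.index.name = "halfhour_bin"
        out[label] = {"monthly": monthly, "cumulative_daily": cum, "diurnal": diurnal}
    return out
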