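"""Friction-velocity (u*) threshold detection and filtering.

At night, low turbulence (low u*) causes the eddy-covariance system to miss
part of the respiratory CO2 flux. The moving point method detects the u*
value above which nighttime NEE no longer increases with u*: night data are
split into temperature classes (to decouple the u*-temperature correlation),
each class into 20 equal-count u* classes, and the threshold is the first u*
class whose mean NEE reaches 95% of the mean of the following classes.
Bootstrap resampling of whole nights yields the threshold distribution; the
median threshold drives the main processing and the 5%/95% quantiles give
the uncertainty range of derived carbon budgets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

NIGHT_SW_MAX = 10.0         # W m-2; night is SW_IN < 10
N_TA_CLASSES = 6
N_USTAR_CLASSES = 20
PLATEAU_RATIO = 0.95
FOLLOWING_CLASSES = 10
TA_CORR_LIMIT = 0.4
MIN_SEASON_RECORDS = 120


@dataclass
class UstarResult:
    """Seasonal/annual u* thresholds (m s-1), optionally with bootstrap quantiles."""

    seasonal: dict = field(default_factory=dict)   # (year, season) -> threshold
    annual: float = float("nan")                   # max over seasons
    bootstrap: np.ndarray | None = None
    q05: float = float("nan")
    q50: float = float("nan")
    q95: float = float("nan")


def _season_labels(timestamps: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """(year, season) labels; December counts toward the following year's DJF."""
    month = timestamps.month.to_numpy()
    year = timestamps.year.to_numpy().copy()
    season = np.empty(len(month), dtype=object)
    season[np.isin(month, (12, 1, 2))] = "DJF"
    season[np.isin(month, (3, 4, 5))] = "MAM"
    season[np.isin(month, (6, 7, 8))] = "JJA"
    season[np.isin(month, (9, 10, 11))] = "SON"
    year[month == 12] += 1
    return year, season


def _class_threshold(nee: np.ndarray, ustar: np.ndarray) -> float:
    """Moving-point threshold within one temperature class, NaN if not found."""
    order = np.argsort(ustar, kind="stable")
    nee, ustar = nee[order], ustar[order]
    edges = np.linspace(0, len(nee), N_USTAR_CLASSES + 1).astype(int)
    means_nee = np.array([nee[edges[i]:edges[i + 1]].mean() for i in range(N_USTAR_CLASSES)])
    means_ust = np.array([ustar[edges[i]:edges[i + 1]].mean() for i in range(N_USTAR_CLASSES)])
    for i in range(N_USTAR_CLASSES - 1):
        following = means_nee[i + 1:i + 1 + FOLLOWING_CLASSES]
        if means_nee[i] >= PLATEAU_RATIO * following.mean():
            if i == 0:
                # even the lowest u* class carries the full flux: there is
                # no detectable suppression, hence no threshold
                return float("nan")
            # the suppression step lies between the last deficient class
            # and this one
            return float(0.5 * (means_ust[i - 1] + means_ust[i]))
    return float("nan")


def _season_threshold(nee: np.ndarray, ta: np.ndarray, ustar: np.ndarray) -> float:
    """Median over retained temperature-class thresholds.

    NaN when no class yields a threshold, or when fewer than half of the
    evaluated classes do (isolated detections on u*-independent data are
    sampling noise, not suppression).
    """
    order = np.argsort(ta, kind="stable")
    nee, ta, ustar = nee[order], ta[order], ustar[order]
    edges = np.linspace(0, len(nee), N_TA_CLASSES + 1).astype(int)
    found, evaluated = [], 0
    for i in range(N_TA_CLASSES):
        sl = slice(edges[i], edges[i + 1])
        t, u, z = ta[sl], ustar[sl], nee[sl]
        if len(t) < N_USTAR_CLASSES:
            continue
        if np.std(t) > 0 and np.std(u) > 0:
            r = np.corrcoef(t, u)[0, 1]
            if abs(r) > TA_CORR_LIMIT:
                continue
        evaluated += 1
        th = _class_threshold(z, u)
        if np.isfinite(th):
            found.append(th)
    if not found or len(found) < 0.5 * evaluated:
        return float("nan")
    return float(np.median(found))


def _night_subset(table: pd.DataFrame) -> pd.DataFrame:
    m = (table["SW_IN"] < NIGHT_SW_MAX) & table["NEE"].notna() & table["ustar"].notna()
    return table.loc[m, ["timestamp", "NEE", "TA", "ustar", "SW_IN"]]


def detect_ustar_threshold(table: pd.DataFrame) -> UstarResult:
    """Moving-point u* threshold from nighttime data.

    Seasons are DJF/MAM/JJA/SON (December attached to the following year).
    Seasons with fewer than 120 usable night records, or where no class
    satisfies the plateau criterion, are skipped with a warning; if every
    season is skipped a ValueError is raised.
    """
    night = _night_subset(table)
    if night.empty:
        raise ValueError("no usable nighttime records (SW_IN < 10 with NEE and u*)")
    year, season = _season_labels(pd.DatetimeIndex(night["timestamp"]))
    result = UstarResult()
    for key in sorted(set(zip(year, season)), key=str):
        m = (year == key[0]) & (season == key[1])
        if m.sum() < MIN_SEASON_RECORDS:
            log.warning("season %s: only %d night records (<%d), skipped",
                        key, m.sum(), MIN_SEASON_RECORDS)
            continue
        th = _season_threshold(night["NEE"].to_numpy()[m],
                               night["TA"].to_numpy()[m],
                               night["ustar"].to_numpy()[m])
        if np.isfinite(th):
            result.seasonal[key] = th
        else:
            log.warning("season %s: no u* class satisfied the plateau criterion", key)
    if not result.seasonal:
        raise ValueError("u* threshold not found in any season "
                         "(night NEE may be independent of u*)")
    result.annual = float(max(result.seasonal.values()))
    return result


def bootstrap_ustar(table: pd.DataFrame, n_boot: int = 100, seed: int = 0) -> UstarResult:
    """Bootstrap the annual u* threshold by resampling whole nights.

    The resampling unit is the calendar night (date of the preceding noon),
    preserving within-night correlation. Returns the point estimate plus the
    bootstrap sample and its 5/50/95% quantiles.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    point = detect_ustar_threshold(table)
    night = _night_subset(table)
    ts = pd.DatetimeIndex(night["timestamp"])
    night_id = (ts - pd.Timedelta(hours=12)).normalize()
    groups = {nid: g for nid, g in night.groupby(night_id)}
    ids = list(groups)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        pick = rng.choice(len(ids), size=len(ids), replace=True)
        sample = pd.concat([groups[ids[i]] for i in pick], ignore_index=True)
        try:
            draws.append(detect_ustar_threshold(sample).annual)
        except ValueError:
            continue
    if len(draws) < 2:
        raise ValueError("bootstrap failed: threshold not found in resamples")
    arr = np.asarray(draws)
    point.bootstrap = arr
    point.q05, point.q50, point.q95 = (float(q) for q in
                                       np.quantile(arr, [0.05, 0.50, 0.95]))
    return point


def apply_ustar(table: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, int]:
    """Set nighttime NEE to missing where u* < threshold.

    Daytime rows are untouched. Returns the filtered copy and the count of
    newly missing values.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = table.copy()
    mask = (out["SW_IN"] < NIGHT_SW_MAX) & (out["ustar"] < threshold) & out["NEE"].notna()
    out.loc[mask, "NEE"] = np.nan
    return out, int(mask.sum())
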