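"""SPEI-flux fingerprint: correlation of daily fluxes with multi-scale drought.

Daily ecosystem fluxes are standardized per calendar day across years
(removing the mean seasonal cycle), then correlated with SPEI at many
aggregation scales in a 5-day rolling window pooled across years. The
resulting day-of-year x scale matrix shows when in the season, and at which
drought time scale, water anomalies couple to the fluxes — e.g. short-scale
dryness in spring can *increase* uptake (warm, sunny) while long-scale
deficits suppress it throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_PAIRS = 10
DEFAULT_DOY_RANGE = (110, 300)

#: default DOY x scale rectangles summarizing spring/late-summer coupling at
#: short and long drought scales
DEFAULT_WINDOWS = {
    "may_short": ((121, 151), (30, 90)),
    "may_long": ((121, 151), (270, 365)),
    "aug_short": ((213, 243), (30, 90)),
    "aug_long": ((213, 243), (270, 365)),
}


def _doy(dates: pd.DatetimeIndex) -> np.ndarray:
    """Day of year folded to a non-leap frame (Feb 29 -> 59)."""
    doy = dates.dayofyear.to_numpy().astype(int)
    leap = dates.is_leap_year & (doy > 59)
    return np.where(leap, doy - 1, doy)


def standardize_by_doy(series: pd.Series) -> pd.Series:
    """z-transform a daily series per calendar day across years.

    For each calendar day d: z = (x - mean_d) / sd_d with the statistics
    taken over the years at that day. Days with zero variance give missing
    values; a single-year input is rejected.
    """
    dates = pd.DatetimeIndex(series.index)
    if dates.year.nunique() < 2:
        raise ValueError("standardization needs >= 2 years per calendar day")
    doy = _doy(dates)
    df = pd.DataFrame({"x": series.to_numpy(dtype=float), "doy": doy})
    grp = df.groupby("doy")["x"]
    mean = grp.transform("mean")
    sd = grp.transform("std")
    z = (df["x"] - mean) / sd.where(sd > 0)
    return pd.Series(z.to_numpy(), index=series.index, name=f"z_{series.name}")


@dataclass
class FingerprintMatrix:
    """DOY x scale grid of Pearson correlations with per-cell sample sizes."""

    r: pd.DataFrame          # index doy, columns scale
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        long = self.r.stack().rename("r").reset_index()
        long.columns = ["doy", "scale", "r"]
        long["n"] = self.n.stack().to_numpy()
        return long


def rolling_correlation(z: pd.Series, spei_long: pd.DataFrame, window: int = 5,
                        doy_range: tuple = DEFAULT_DOY_RANGE) -> FingerprintMatrix:
    """Rolling SPEI-flux correlation per day of year and aggregation scale.

    Cell (d, k) is the Pearson correlation of all (z, SPEI_k) pairs whose
    DOY falls within the centred window [d-2, d+2], pooled across years
    (about window x n_years pairs). Cells with fewer than 10 complete pairs
    are missing.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    half = window // 2
    scales = sorted(spei_long["scale"].unique())
    zdates = pd.DatetimeIndex(z.index)
    zdoy = _doy(zdates)
    zval = z.to_numpy(dtype=float)
    doys = np.arange(doy_range[0], doy_range[1] + 1)
    rmat = np.full((len(doys), len(scales)), np.nan)
    nmat = np.zeros((len(doys), len(scales)), dtype=int)
    for j, k in enumerate(scales):
        sub = spei_long.loc[spei_long["scale"] == k]
        s = pd.Series(sub["spei"].to_numpy(), index=pd.DatetimeIndex(sub["date"]))
        sval = s.reindex(zdates).to_numpy(dtype=float)
        ok = np.isfinite(zval) & np.isfinite(sval)
        for i, d in enumerate(doys):
            m = ok & (np.abs(zdoy - d) <= half)
            nmat[i, j] = int(m.sum())
            if nmat[i, j] < MIN_PAIRS:
                continue
            zz, ss = zval[m], sval[m]
            if np.std(zz) == 0 or np.std(ss) == 0:
                continue
            rmat[i, j] = np.corrcoef(zz, ss)[0, 1]
    return FingerprintMatrix(
        r=pd.DataFrame(rmat, index=pd.Index(doys, name="doy"),
                       columns=pd.Index(scales, name="scale")),
        n=pd.DataFrame(nmat, index=pd.Index(doys, name="doy"),
                       columns=pd.Index(scales, name="scale")),
    )


@dataclass
class WindowSummary:
    slope: float
    intercept: float
    r: float
    n: int
    pairs: pd.DataFrame      # pooled (spei, z) scatter sample


def window_summary(z: pd.Series, spei_long: pd.DataFrame,
                   doy_range: tuple, scale_range: tuple) -> WindowSummary:
    """Pooled scatter regression over a DOY x scale rectangle.

    All (SPEI, z) pairs with DOY in ``doy_range`` and scale in
    ``scale_range`` are pooled across years and scales; an ordinary
    least-squares line z ~ SPEI is fitted. With both axes standardized the
    slope approximates the average correlation in the window.
    """
    zdates = pd.DatetimeIndex(z.index)
    zdoy = _doy(zdates)
    zval = z.to_numpy(dtype=float)
    rows = []
    for k in sorted(spei_long["scale"].unique()):
        if not (scale_range[0] <= k <= scale_range[1]):
            continue
        sub = spei_long.loc[spei_long["scale"] == k]
        s = pd.Series(sub["spei"].to_numpy(), index=pd.DatetimeIndex(sub["date"]))
        sval = s.reindex(zdates).to_numpy(dtype=float)
        m = (np.isfinite(zval) & np.isfinite(sval)
             & (zdoy >= doy_range[0]) & (zdoy <= doy_range[1]))
        rows.append(pd.DataFrame({"spei": sval[m], "z": zval[m], "scale": k}))
    pairs = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["spei", "z", "scale"]))
    if len(pairs) < 20:
        raise ValueError(f"only {len(pairs)} pooled pairs (<20) in window")
    x, y = pairs["spei"].to_numpy(), pairs["z"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1])
    return WindowSummary(slope=float(slope), intercept=float(intercept),
                         r=r, n=len(pairs), pairs=pairs)
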