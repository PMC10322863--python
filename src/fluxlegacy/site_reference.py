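"""Published annual budgets of the DE-HoH ('Hohes Holz') study site.

The tables below are the printed annual/growing-season results for the
six observation years 2015-2020 of the mixed deciduous forest DE-HoH in
Central Germany, which saw an extreme drought-and-heat year in 2018. They
serve as inputs to small "arithmetic twin" summaries — the same aggregation
arithmetic the budget and light-response modules apply to processed tower
data, evaluated on the published numbers — used for cross-checks and worked
examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DROUGHT_YEAR = 2018
LEGACY_YEAR = 2019
PRE_DROUGHT_YEARS = (2015, 2016, 2017)

#: annual NEP (gC m-2, positive = sink), annual precipitation (mm),
#: growing-season precipitation (mm) and Phenocam growing-season length (d)
ANNUAL = pd.DataFrame({
    "year": [2015, 2016, 2017, 2018, 2019, 2020],
    "nep": [309.0, 354.0, 439.0, 424.0, 274.0, 372.0],
    "precip": [550.0, 389.0, 610.0, 302.0, 471.0, 478.0],
    "gs_precip": [353.0, 261.0, 438.0, 130.0, 322.0, 315.0],
    "gs_length": [205.0, 207.0, 215.0, 227.0, 230.0, 211.0],
}).set_index("year")

#: monthly light-response reference GPP (umol m-2 s-1 at PPFD = 2000) for
#: the drought year, the legacy year, and the pooled remaining years
GPP_REF = pd.DataFrame({
    "month": [5, 6, 7, 8, 9],
    "y2018": [21.19, 26.78, 19.07, 17.07, 15.17],
    "y2019": [15.45, 19.19, 18.51, 16.19, 15.08],
    "others": [18.80, 26.32, 25.76, 22.49, 18.80],
}).set_index("month")


def mean_annual_nep() -> float:
    """Six-year mean NEP, gC m-2 yr-1."""
    return float(ANNUAL["nep"].mean())


def pre_drought_mean_nep() -> float:
    """Mean NEP of the pre-drought years 2015-2017, gC m-2 yr-1."""
    return float(ANNUAL.loc[list(PRE_DROUGHT_YEARS), "nep"].mean())


def legacy_year_nep_reduction() -> float:
    """Relative NEP reduction of the post-drought year vs pre-drought mean, %."""
    return float(100.0 * (1.0 - ANNUAL.loc[LEGACY_YEAR, "nep"] / pre_drought_mean_nep()))


def growing_season_elongation() -> float:
    """Mean growing-season length of 2018-2019 minus the other years, days."""
    long_years = [DROUGHT_YEAR, LEGACY_YEAR]
    others = [y for y in ANNUAL.index if y not in long_years]
    return float(ANNUAL.loc[long_years, "gs_length"].mean()
                 - ANNUAL.loc[others, "gs_length"].mean())


def drought_year_gs_precip_share() -> float:
    """Share of the drought year's precipitation that fell in the growing season, %."""
    return float(100.0 * ANNUAL.loc[DROUGHT_YEAR, "gs_precip"]
                 / ANNUAL.loc[DROUGHT_YEAR, "precip"])


def midsummer_gpp_ref_ratio() -> float:
    """July+August drought-year reference GPP as a share of non-drought years, %."""
    drought = GPP_REF.loc[[7, 8], "y2018"].sum()
    others = GPP_REF.loc[[7, 8], "others"].sum()
    return float(100.0 * drought / others)
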