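"""Benchmark harness for the deposited DE-HoH dataset.

The study's processed daily data are archived at zenodo
(doi:10.5281/zenodo.7638744) and are not bundled here. Given a daily table
with columns date, GPP, PPFD, SWC_50, SPEI_90, SPEI_365 exported from that
deposit, ``run_legacy_benchmark`` repeats the two-model spline regression
comparison (knot count selected by AIC) so the published model scores
(adj. R2, AIC, per-year MPE) can be reproduced. Exact agreement also
depends on the deposit's own gap-filling/partitioning settings and on the
PET formulation of the drought-index dataset it uses.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from fluxlegacy import rcs

REQUIRED = ("date", "GPP", "PPFD", "SWC_50", "SPEI_90", "SPEI_365")
DEPOSIT_DOI = "10.5281/zenodo.7638744"


def load_deposit_daily(path) -> pd.DataFrame:
    """Load a daily benchmark table exported from the zenodo deposit."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"benchmark table {path} not found; download the study deposit "
            f"(doi:{DEPOSIT_DOI}) and export a daily CSV with columns "
            f"{', '.join(REQUIRED)}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"benchmark table missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"])
    return df


def run_legacy_benchmark(daily: pd.DataFrame, legacy_year: int = 2019) -> dict:
    """Two-model comparison on a deposited (or stand-in) daily table.

    Returns the AIC-selected knot count, both fitted models, the model
    comparison, and per-year metrics of each model.
    """
    k_simple, simple = rcs.select_knots(daily, ["PPFD", "SWC_50"])
    k_full, full = rcs.select_knots(daily, ["PPFD", "SWC_50", "SPEI_90", "SPEI_365"])
    comp = rcs.compare_models(
        rcs.fit_model(daily, ["PPFD", "SWC_50"], k_full),
        full, legacy_years=[legacy_year])
    return {
        "knots_simple": k_simple, "knots_full": k_full,
        "simple": simple, "full": full, "comparison": comp,
        "years_simple": rcs.yearly_metrics(simple),
        "years_full": rcs.yearly_metrics(full),
    }
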