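"""Greenness phenology: Gcc, filtering, double-logistic fit, dates."""

import numpy as np
import pandas as pd
import pytest

from fluxlegacy import phenology, synthetic
from fluxlegacy.phenology import PhenoFit
from fluxlegacy.synthetic import SimConfig, simulate_gcc


def test_compute_gcc_chromatic_cases():
    ts = pd.to_datetime(["2020-06-01 12:00"] * 3)
    pure_green = pd.DataFrame({"timestamp": ts[:1], "R": [0.0], "G": [120.0], "B": [0.0]})
    assert phenology.compute_gcc(pure_green)["gcc"].iloc[0] == pytest.approx(1.0)
    grey = pd.DataFrame({"timestamp": ts[:1], "R": [80.0], "G": [80.0], "B": [80.0]})
    assert phenology.compute_gcc(grey)["gcc"].iloc[0] == pytest.approx(1 / 3)
    zero = pd.DataFrame({"timestamp": ts[:1], "R": [0.0], "G": [0.0], "B": [0.0]})
    assert np.isnan(phenology.compute_gcc(zero)["gcc"].iloc[0])


def test_compute_gcc_daily_percentile_prefers_greener_subset():
    # grey morning images plus a 10% greener midday subset
    ts = pd.to_datetime(["2020-06-01 08:00"] * 17 + ["2020-06-01 12:00"] * 3)
    r = np.full(20, 100.0)
    b = np.full(20, 100.0)
    g = np.full(20, 100.0)
    g[17:] = 150.0     # greener midday images (15% of the day)
    daily = phenology.compute_gcc(pd.DataFrame({"timestamp": ts, "R": r, "G": g, "B": b}))
    greener = 150.0 / 350.0
    assert daily["gcc"].iloc[0] == pytest.approx(greener, abs=0.01)


def test_filter_thresholds_and_clean_series():
    cfg = SimConfig(seed=1, years=(2019,), gcc_noise_sd=0.0, gcc_outlier_fraction=0.0)
    g = simulate_gcc(cfg)
    injected = g.copy()
    injected.loc[injected.index[100], "gcc"] = 0.15
    out = phenology.filter_gcc(injected)
    assert len(out) == len(g) - 1          # only the low-illumination point dropped
    clean = phenology.filter_gcc(g)
    assert len(clean) == len(g)


def test_filter_confusion_counts():
    cfg = SimConfig(seed=2, years=(2019,), gcc_noise_sd=0.005,
                    gcc_outlier_fraction=0.03, gcc_spike_fraction=0.05)
    g = simulate_gcc(cfg)
    out = phenology.filter_gcc(g)
    spikes = g[g["kind"] == "spike"]
    clean = g[g["kind"] == "clean"]
    spikes_kept = len(out.merge(spikes[["date"]], on="date"))
    clean_kept = len(out.merge(clean[["date"]], on="date"))
    assert 1 - spikes_kept / len(spikes) >= 0.90
    assert 1 - clean_kept / len(clean) <= 0.01
    lows = g[g["kind"] == "low"]
    assert len(out.merge(lows[["date"]], on="date")) == 0


def test_double_logistic_exact_recovery():
    cfg = SimConfig(seed=1, years=(2019,), gcc_noise_sd=0.0, gcc_outlier_fraction=0.0)
    fit = phenology.fit_double_logistic(simulate_gcc(cfg))
    p = cfg.pheno_params
    assert fit.baseline == pytest.approx(p.baseline, abs=1e-3)
    assert fit.amplitude == pytest.approx(p.amplitude, abs=1e-3)
    assert fit.t1 == pytest.approx(p.t1, abs=1e-3)
    assert fit.t2 == pytest.approx(p.t2, abs=1e-3)
    assert fit.c1 == pytest.approx(p.c1, abs=1e-3)
    assert fit.c2 == pytest.approx(p.c2, abs=1e-3)


def test_flat_series_is_degenerate():
    cfg = SimConfig(seed=1, years=(2019,), gcc_noise_sd=0.0, gcc_outlier_fraction=0.0,
                    pheno_params=synthetic.PhenoTruth(amplitude=0.0))
    with pytest.raises(ValueError, match="flat|amplitude"):
        phenology.fit_double_logistic(simulate_gcc(cfg))


def test_spring_inflection_recovery_with_noise():
    errs = []
    for seed in range(20):
        cfg = SimConfig(seed=seed, years=(2019,), gcc_noise_sd=0.005,
                        gcc_outlier_fraction=0.0)
        fit = phenology.fit_double_logistic(simulate_gcc(cfg))
        errs.append(abs(fit.t1 - cfg.pheno_params.t1))
    assert max(errs) <= 3.0


def _reference_fit(**kw):
    base = dict(baseline=0.32, amplitude=0.10, t1=120.0, c1=0.15, t2=290.0, c2=0.10)
    base.update(kw)
    return PhenoFit(**base)


def test_transition_dates_geometry():
    fit = _reference_fit()
    dates = phenology.transition_dates(fit)
    assert dates.sos < fit.t1
    assert dates.eos > fit.t2
    assert dates.length == pytest.approx(dates.eos - dates.sos)

    sym = _reference_fit(c1=0.12, c2=0.12, t1=130.0, t2=280.0)
    d = phenology.transition_dates(sym)
    mid = (sym.t1 + sym.t2) / 2.0
    assert (mid - d.sos) == pytest.approx(d.eos - mid, abs=0.3)


def test_curvature_matches_finite_differences():
    fit = _reference_fit()
    t = np.linspace(60.0, 350.0, 2000)
    h = 1e-4
    g = fit(t)
    g1 = (fit(t + h) - fit(t - h)) / (2 * h)
    g2 = (fit(t + h) - 2 * g + fit(t - h)) / h ** 2
    kappa_num = g2 / (1 + g1 ** 2) ** 1.5
    np.testing.assert_allclose(phenology.curvature(fit, t), kappa_num, atol=1e-6)


def test_date_uncertainty_behaviour():
    cfg = SimConfig(seed=1, years=(2019,), gcc_noise_sd=0.0, gcc_outlier_fraction=0.0)
    clean = simulate_gcc(cfg)
    fit = phenology.fit_double_logistic(clean)
    res = phenology.date_uncertainty(fit, clean, n=10, seed=0)
    assert res.sos_sd == 0.0 and res.eos_sd == 0.0

    sds = []
    for noise in (0.004, 0.012):
        cfg_n = SimConfig(seed=3, years=(2019,), gcc_noise_sd=noise,
                          gcc_outlier_fraction=0.0)
        series = simulate_gcc(cfg_n)
        fit_n = phenology.fit_double_logistic(series)
        unc = phenology.date_uncertainty(fit_n, series, n=30, seed=1)
        sds.append(unc.sos_sd)
    assert sds[1] >= sds[0]
    # fixed seed reproducibility
    cfg_n = SimConfig(seed=3, years=(2019,), gcc_noise_sd=0.012, gcc_outlier_fraction=0.0)
    series = simulate_gcc(cfg_n)
    fit_n = phenology.fit_double_logistic(series)
    a = phenology.date_uncertainty(fit_n, series, n=15, seed=5)
    b = phenology.date_uncertainty(fit_n, series, n=15, seed=5)
    assert (a.sos_sd, a.eos_sd) == (b.sos_sd, b.eos_sd)


def test_growing_season_length_recovery():
    truth_dates = phenology.transition_dates(_reference_fit())
    cfg = SimConfig(seed=9, years=(2019,), gcc_noise_sd=0.005, gcc_outlier_fraction=0.02)
    series = phenology.filter_gcc(simulate_gcc(cfg))
    fit = phenology.fit_double_logistic(series)
    est = phenology.transition_dates(fit)
    assert abs(est.length - truth_dates.length) <= 4.0


def test_residuals_uncorrelated_on_clean_data():
    cfg = SimConfig(seed=11, years=(2019,), gcc_noise_sd=0.005, gcc_outlier_fraction=0.0)
    series = simulate_gcc(cfg)
    fit = phenology.fit_double_logistic(series)
    doy = pd.DatetimeIndex(series["date"]).dayofyear.to_numpy(dtype=float)
    fitted = fit(doy)
    resid = series["gcc"].to_numpy() - fitted
    r = np.corrcoef(fitted, resid)[0, 1]
    assert abs(r) < 0.1


def test_phenofit_validation():
    with pytest.raises(ValueError):
        PhenoFit(baseline=0.3, amplitude=-0.1, t1=120, c1=0.1, t2=290, c2=0.1)
    with pytest.raises(ValueError):
        PhenoFit(baseline=0.3, amplitude=0.1, t1=290, c1=0.1, t2=120, c2=0.1)
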