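"""Drought index: solar geometry, Hargreaves PET, log-logistic SPEI."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from fluxlegacy import synthetic
from fluxlegacy import spei as sp


def test_extraterrestrial_radiation_equator_equinox():
    # independent solar-geometry value: ~37.6 MJ m-2 d-1 at the equator
    assert sp.extraterrestrial_radiation(0.0, 80) == pytest.approx(37.6, rel=0.02)


def test_extraterrestrial_radiation_reference_point():
    # standard worked example: 20 deg S, 3 September -> 32.2 MJ m-2 d-1
    assert sp.extraterrestrial_radiation(-20.0, 246) == pytest.approx(32.2, abs=0.3)


def test_extraterrestrial_radiation_hemispheric_symmetry():
    # at the equinox the declination is ~0 and the two hemispheres see the
    # same geometry (away from the equinox the Earth-Sun distance differs)
    a = sp.extraterrestrial_radiation(52.0, 80)
    b = sp.extraterrestrial_radiation(-52.0, 80)
    assert a == pytest.approx(b, rel=0.03)


def test_extraterrestrial_radiation_positive_and_polar_rejection():
    doys = np.arange(1, 367)
    for lat in (-60.0, -30.0, 0.0, 30.0, 60.0):
        assert (sp.extraterrestrial_radiation(lat, doys) > 0).all()
    with pytest.raises(ValueError):
        sp.extraterrestrial_radiation(70.0, 100)


def _climate_row(lat, doy, tmin, tmax, tmean):
    date = pd.Timestamp("2019-01-01") + pd.Timedelta(days=doy - 1)
    return pd.DataFrame({"date": [date], "precip": [0.0], "tmin": [tmin],
                         "tmax": [tmax], "tmean": [tmean], "latitude": [lat]})


def test_pet_hargreaves_zeros_and_formula():
    assert sp.pet_hargreaves(_climate_row(52, 172, -20, -15.6, -17.8)).iloc[0] == 0.0
    assert sp.pet_hargreaves(_climate_row(52, 172, 12, 12, 12)).iloc[0] == 0.0
    # explicit recomputation of the formula
    ra = sp.extraterrestrial_radiation(52.0, 172)
    expected = 0.0023 * (ra / 2.45) * (19.0 + 17.8) * np.sqrt(26.0 - 12.0)
    assert sp.pet_hargreaves(_climate_row(52, 172, 12, 26, 19)).iloc[0] == pytest.approx(expected)


def test_water_balance_oracle():
    rng = np.random.default_rng(1)
    p = pd.Series(rng.gamma(1.0, 3.0, 200))
    pet = pd.Series(rng.uniform(0.5, 4.0, 200))
    d1 = sp.water_balance(p, pet, 1)
    np.testing.assert_allclose(d1, p - pet)
    const = sp.water_balance(pd.Series(np.full(50, 5.0)), pd.Series(np.full(50, 2.0)), 10)
    np.testing.assert_allclose(const[9:], 30.0)
    assert const[:9].isna().all()
    d30 = sp.water_balance(p, pet, 30).to_numpy()
    diff = (p - pet).to_numpy()
    brute = np.array([diff[i - 29:i + 1].sum() if i >= 29 else np.nan for i in range(200)])
    np.testing.assert_allclose(d30, brute, equal_nan=True)
    with pytest.raises(ValueError):
        sp.water_balance(p, pet, 0)


def test_loglogistic_pwm_recovery_and_equivariance():
    rng = np.random.default_rng(0)
    u = rng.random(10_000)
    true = (3.0, 50.0, -100.0)
    x = true[2] + true[1] * (u / (1 - u)) ** (1 / true[0])
    fit = sp.fit_loglogistic(x)
    for got, want in zip(fit, true):
        assert got == pytest.approx(want, rel=0.05, abs=5.0)
    shifted = sp.fit_loglogistic(x + 100.0)
    assert shifted[2] == pytest.approx(fit[2] + 100.0, rel=0.02, abs=2.0)
    assert shifted[0] == pytest.approx(fit[0], rel=0.01)
    assert shifted[1] == pytest.approx(fit[1], rel=0.01)


def test_loglogistic_median_maps_to_half():
    rng = np.random.default_rng(3)
    u = rng.random(1000)
    x = -20.0 + 30.0 * (u / (1 - u)) ** (1 / 4.0)
    fit = sp.fit_loglogistic(x)
    f_med = sp.loglogistic_cdf(np.median(x), *fit)
    assert abs(float(f_med) - 0.5) < 0.05


def test_loglogistic_rejects_bad_samples():
    with pytest.raises(ValueError):
        sp.fit_loglogistic(np.ones(50))
    with pytest.raises(ValueError):
        sp.fit_loglogistic(np.arange(10.0))


@pytest.fixture(scope="module")
def stationary_spei():
    cfg = synthetic.SimConfig(seed=7, years=tuple(range(1981, 2011)), drought_years={})
    climate = synthetic.simulate_daily_climate(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series = sp.spei(climate, scales=(90,))
    return climate, series


def test_spei_median_day_maps_to_zero(stationary_spei):
    # the median of a calendar day's fitted pool transforms to ~Phi^-1(0.5)
    climate, _ = stationary_spei
    model = sp.fit_spei_model(climate, 90)
    from scipy.stats import norm
    for doy in (30, 120, 210, 300):
        shape, scl, loc, mirrored = model.params[doy]
        med = float(np.median(model.pools[doy]))
        f = (1.0 - sp.loglogistic_cdf(-med, shape, scl, loc) if mirrored
             else sp.loglogistic_cdf(med, shape, scl, loc))
        assert abs(norm.ppf(float(f))) < 0.1


def test_spei_standardization_property(stationary_spei):
    # 30 reference years: per-day bias small, spread close to one
    _, series = stationary_spei
    v = series[series["scale"] == 90].dropna(subset=["spei"])
    doy = sp._fold_doy(pd.DatetimeIndex(v["date"]))
    per = v.groupby(doy)["spei"].agg(["mean", "std"])
    assert per["mean"].abs().max() < 0.05
    assert per["std"].between(0.85, 1.15).all()


def test_spei_clamped(stationary_spei):
    _, series = stationary_spei
    assert series["spei"].abs().max() <= 3.30


def test_spei_monotone_in_water_balance(stationary_spei):
    # with the standardization model held fixed, adding rain inside a
    # window can only raise the SPEI at that window's end, and leaves all
    # other days untouched
    climate, _ = stationary_spei
    scale = 90
    model = sp.fit_spei_model(climate, scale)
    dates = pd.DatetimeIndex(climate["date"])
    pet = sp.pet_hargreaves(climate)
    d = sp.water_balance(climate["precip"], pet, scale)
    climate2 = climate.copy()
    climate2.loc[5000, "precip"] += 40.0
    d2 = sp.water_balance(climate2["precip"], pet, scale)
    base = model.transform(dates, d).to_numpy()
    bumped = model.transform(dates, d2).to_numpy()
    changed = ((d2 - d).abs() > 1e-12).fillna(False).to_numpy()
    assert changed.sum() == scale
    delta = bumped - base
    assert np.nanmin(delta[changed]) >= 0.0
    same = ~changed
    np.testing.assert_allclose(np.nan_to_num(delta[same]), 0.0, atol=1e-12)


def test_spei_categories_and_extreme_probability():
    s = pd.Series([0.5, -1.2, -1.7, -2.4, np.nan])
    cats = sp.categorize(s)
    assert list(cats[:4]) == ["none", "moderate", "severe", "extreme"]
    # the extreme threshold corresponds to a cumulative normal probability
    # of 2.3%
    assert norm.cdf(sp.CATEGORY_THRESHOLDS["extreme"]) == pytest.approx(0.02275, abs=1e-4)


def test_spei_reference_period_validation(stationary_spei):
    climate, _ = stationary_spei
    with pytest.raises(ValueError):
        sp.spei(climate, scales=(90,), reference_period=(1900, 2010))
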