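import pytest

from fluxlegacy import synthetic


@pytest.fixture(scope="session")
def clean_site():
    """Two noise-free years: suppression 0.5 below u* = 0.35, no gaps."""
    cfg = synthetic.SimConfig(seed=3, years=(2018, 2019), noise_sd_nee=0.0,
                              gap_fraction=0.0, drought_years={},
                              night_suppression_factor=0.5)
    climate = synthetic.simulate_daily_climate(cfg)
    flux, truth = synthetic.simulate_halfhourly(cfg, climate)
    return cfg, climate, flux, truth


@pytest.fixture(scope="session")
def noisy_site():
    """One year with measurement noise (sd 0.5) and no other artifacts."""
    cfg = synthetic.SimConfig(seed=4, years=(2019,), noise_sd_nee=0.5,
                              gap_fraction=0.0, drought_years={},
                              night_suppression_factor=1.0)
    climate = synthetic.simulate_daily_climate(cfg)
    flux, truth = synthetic.simulate_halfhourly(cfg, climate)
    return cfg, climate, flux, truth


@pytest.fixture(scope="session")
def ideal_site():
    """One fully ideal year: no noise, no gaps, no u* suppression."""
    cfg = synthetic.SimConfig(seed=6, years=(2019,), noise_sd_nee=0.0,
                              gap_fraction=0.0, drought_years={},
                              night_suppression_factor=1.0)
    climate = synthetic.simulate_daily_climate(cfg)
    flux, truth = synthetic.simulate_halfhourly(cfg, climate)
    return cfg, climate, flux, truth
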