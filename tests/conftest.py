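import numpy as np
import pandas as pd
import pytest

from yielduq import pipeline
from yielduq.synthetic_data import make_fixture, preset_config


@pytest.fixture(scope="session")
def tiny_fixture():
    """5 counties x 15 years x 3 members."""
    return make_fixture("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_noiseless():
    cfg = preset_config("tiny")
    cfg.yields.residual_sd_bu = 0.0
    cfg.yields.spatial_residual_frac = 0.0
    cfg.yields.county_effect_sd_bu = 0.0
    return make_fixture(config=cfg, seed=5)


@pytest.fixture(scope="session")
def tiny_calibration(tiny_fixture):
    return pipeline.calibrate(tiny_fixture.covariates, tiny_fixture.yields,
                              structure=tiny_fixture.truth.structure)


@pytest.fixture(scope="session")
def default_fixture():
    """30 counties x 40 years x 18 members (the full-size study)."""
    return make_fixture("default", seed=1)


@pytest.fixture(scope="session")
def default_calibration(default_fixture):
    return pipeline.calibrate(default_fixture.covariates, default_fixture.yields,
                              structure=default_fixture.truth.structure)


def constant_weather(days=240, county="C0", year=2000, tmax=25.0, tmin=15.0,
                     precip=2.0, rhmax=60.0, rhmin=40.0):
    dates = pd.date_range(f"{year}-01-01", periods=days, freq="D")
    return pd.DataFrame({
        "county_id": county, "date": dates,
        "tmax_c": tmax, "tmin_c": tmin, "precip_mm": precip,
        "rhmax_pct": rhmax, "rhmin_pct": rhmin,
    })
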