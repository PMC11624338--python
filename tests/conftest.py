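import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import rumengas as rg

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return rg.DEFAULT_CONFIG


@pytest.fixture(scope="session")
def small_params():
    """Default 4-cow study with a fixed seed."""
    return rg.GeneratorParams(seed=1234)


@pytest.fixture(scope="session")
def study(small_params, config):
    return rg.generate_study(small_params, config)


@pytest.fixture(scope="session")
def noise_free_params():
    """Deterministic limit: every variance component and contamination zero."""
    p = rg.GeneratorParams(seed=0)
    silent = {
        gas: rg.GasParams(hourly_mean=gp.hourly_mean, peak_frac=gp.peak_frac,
                          decay=gp.decay)
        for gas, gp in p.chamber_gases.items()
    }
    hs4 = p.headspace_ch4
    hsn = p.headspace_n2o
    return p.replace(
        chamber_gases=silent,
        headspace_ch4=rg.GasParams(hs4.hourly_mean, hs4.peak_frac, hs4.decay),
        headspace_n2o=rg.GasParams(hsn.hourly_mean, hsn.peak_frac, hsn.decay),
        traits={k: rg.TraitParams(t.mean) for k, t in p.traits.items()},
        contamination_range=(0.0, 0.0),
    )
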