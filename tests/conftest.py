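import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def water_preset():
    from fibrilscatter.synthetic_data import get_preset
    return get_preset("A8K-water")


@pytest.fixture(scope="session")
def meoh_preset():
    from fibrilscatter.synthetic_data import get_preset
    return get_preset("A10K-MeOH")


@pytest.fixture(scope="session")
def water_curve_noisy(water_preset):
    """1 wt% aqueous (dilute-regime) SAXS curve with counting noise."""
    from fibrilscatter.synthetic_data import simulate_saxs
    return simulate_saxs(water_preset, seed=7)


@pytest.fixture(scope="session")
def water_curve_subtracted(water_preset, water_curve_noisy):
    """The same curve with the known flat background removed."""
    from fibrilscatter.scatter_io import ScatteringCurve
    c = water_curve_noisy
    return ScatteringCurve(c.q, c.intensity - water_preset.model.background,
                           c.sigma)


@pytest.fixture(scope="session")
def noisy_water_fit(water_preset, water_curve_noisy):
    """Form-factor fit of the noisy aqueous curve (expensive; shared)."""
    from dataclasses import replace
    from fibrilscatter.saxs_models import fit_form_factor
    init = replace(water_preset.model, a=water_preset.model.a * 1.25,
                   b=water_preset.model.b * 0.8)
    return fit_form_factor(water_curve_noisy, init)
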