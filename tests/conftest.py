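import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """Two-country synthetic study with a strong injected heat effect,
    small enough for fast pipeline tests."""
    from heatperi.synthetic_data import COUNTRY_PRESETS, simulate_study

    presets = {k: COUNTRY_PRESETS[k] for k in ("benin", "uganda")}
    births, series = simulate_study(
        presets=presets, seed=42, births_per_day_mean=4.0, true_cumulative_or=1.8
    )
    return births, series


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
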