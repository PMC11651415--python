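import pytest

from napus import (CampaignGenSpec, WeatherGenSpec, generate_campaign,
                   generate_truth, generate_weather)


@pytest.fixture(scope="session")
def weather():
    """One synthetic Hengyang-like season."""
    return generate_weather(WeatherGenSpec(seed=11))


@pytest.fixture(scope="session")
def truth():
    """Published single-point means (SPA = 0.00065, TSUM1 = 701, ...)."""
    return generate_truth()


@pytest.fixture(scope="session")
def campaign(weather, truth):
    """Noise-free five-stage campaign generated by the engine itself."""
    return generate_campaign(CampaignGenSpec(truth=truth, noise_cv=0.0, seed=0),
                             weather)
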