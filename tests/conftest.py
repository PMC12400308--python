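import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def paper_cfg():
    """Published-parameter synthetic config with noise switched off."""
    from cdphotostab import datasets

    cfg = datasets.paper2025()
    cfg.noise_cv = 0.0
    return cfg


@pytest.fixture
def noisy_cfg():
    """Published-parameter synthetic config at the default 2% CV noise."""
    from cdphotostab import datasets

    return datasets.paper2025()
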