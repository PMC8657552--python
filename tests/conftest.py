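import numpy as np
import pytest

from ecosens import GeneratorConfig, ResponseSpec, generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """Default-response panel at reduced scale: 5 regions x 8 years."""
    cfg = GeneratorConfig(n_regions=5, years=(2002, 2009), seed=11)
    panel, truth = generate_panel(cfg)
    return panel, truth


@pytest.fixture(scope="session")
def proportional_panel():
    """Noiseless panel whose outcome is proportional to temperature."""
    spec = ResponseSpec(family="linear", coefficients={"temperature": 10.0})
    cfg = GeneratorConfig(n_regions=10, years=(2002, 2016),
                          response_spec=spec, noise_sd=0.0, seed=3)
    return generate_panel(cfg)
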