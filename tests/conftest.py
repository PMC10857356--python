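import numpy as np
import pytest

from crescentseg.phantom import HUParams, desk_spec, generate_cohort, generate_series
from crescentseg.unet_core import ModelConfig, UNet


@pytest.fixture(scope="session")
def noiseless_spec():
    """Desk-scale spec with zero texture/noise: crisp tissue plateaus."""
    return desk_spec(
        64, 8,
        hu_params=HUParams(brain_sd=0, skull_sd=0, collection_sd=0),
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_series(noiseless_spec):
    return generate_series(noiseless_spec, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four small annotated series for pipeline plumbing tests."""
    spec = desk_spec(32, 6)
    return generate_cohort(4, None, base_spec=spec, seed=5)


@pytest.fixture(scope="session")
def tiny_unet():
    """A seeded, untrained U-Net used as an 'arbitrary model' in contracts."""
    return UNet(ModelConfig(in_channels=3, depth=2, base_filters=4), seed=9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
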