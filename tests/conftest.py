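import numpy as np
import pytest

from ncfish.scene import ScenarioParams, generate_scene


def small_params(**overrides) -> ScenarioParams:
    """A fast scene: 512 px field, two neurites, 60 mRNA spots."""
    kw = dict(
        image_shape=(512, 512),
        soma_radius_um=3.0,
        neurite_specs=((7.0, 1.4, 30.0), (6.0, 1.2, 200.0)),
        n_spots_per_channel={"rna": 60, "ribosome": 60},
        mito_specs=(20, 1.5, 0.4),
        coloc_fraction=0.5,
        noise_sd=0.0,
    )
    kw.update(overrides)
    return ScenarioParams(**kw)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free small scene shared across read-only tests."""
    return generate_scene(small_params(), seed=11)


@pytest.fixture(scope="session")
def noisy_scene():
    return generate_scene(small_params(noise_sd=0.05), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
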