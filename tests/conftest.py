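import dataclasses

import numpy as np
import pytest

from vascmap import phantom


SMALL_GRID = (24, 48, 48)


@pytest.fixture(scope="session")
def small_config() -> phantom.PhantomConfig:
    """A fast phantom: small grid, small nidus, default prevalences."""
    return phantom.PhantomConfig(
        grid_shape=SMALL_GRID,
        nidus=phantom.NidusConfig(radius=4.0),
        noise_sigma=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_labels(small_config) -> phantom.LabelVolume:
    return phantom.build_label_volume(small_config)


@pytest.fixture(scope="session")
def small_images(small_config, small_labels) -> phantom.MultiparametricVolume:
    model = phantom.default_intensity_model()
    return phantom.render_modalities(small_labels, model, small_config)


@pytest.fixture(scope="session")
def clean_config(small_config) -> phantom.PhantomConfig:
    """Noise- and bias-free variant for exact-intensity checks."""
    return dataclasses.replace(small_config, noise_sigma=0.0, bias_field_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_images(clean_config, small_labels) -> phantom.MultiparametricVolume:
    model = phantom.default_intensity_model()
    return phantom.render_modalities(small_labels, model, clean_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
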