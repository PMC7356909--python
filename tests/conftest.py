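import numpy as np
import pytest

from niaflush import FlushModel, SkinThresholds


@pytest.fixture
def rng():
    return np.random.default_rng(20200613)


@pytest.fixture
def permissive():
    return SkinThresholds.permissive()


@pytest.fixture
def small_model():
    """A compact noise-free measurement model for fast end-to-end tests."""
    return FlushModel(
        noise_sd=0.0,
        image_shape=(150, 200),
        ellipse_center_mm=(5.0, 7.5),
        ellipse_axes_mm=(3.0, 2.0),
        control_gap_mm=2.0,
    )


@pytest.fixture
def noisy_model(small_model):
    from dataclasses import replace

    return replace(small_model, noise_sd=2.0)
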