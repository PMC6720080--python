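from dataclasses import replace

import numpy as np
import pytest

from conequant.mosaic import sample_cone_mosaic
from conequant.presets import make_preset
from conequant.render import render_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_field():
    """A reduced-density noiseless, evenly lit two-channel field.

    Session-scoped because rendering is the expensive step shared by
    several segmentation and typing tests.
    """
    preset = replace(
        make_preset("P14", "inferior"),
        noise_sd=0.0,
        illumination_amplitude=0.0,
        soma_survival=0.3,
    )
    gen = np.random.default_rng(7)
    gt = sample_cone_mosaic(preset, gen)
    field = render_field(gt, preset, gen)
    return preset, gt, field


@pytest.fixture(scope="session")
def noisy_field():
    """A reduced-density field with the default noise and illumination."""
    preset = replace(make_preset("P14", "inferior"), soma_survival=0.3)
    gen = np.random.default_rng(3)
    gt = sample_cone_mosaic(preset, gen)
    field = render_field(gt, preset, gen)
    return preset, gt, field
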