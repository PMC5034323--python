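import numpy as np
import pytest

from isletquant import RunConfig, SynthParams, generate_section


@pytest.fixture(scope="session")
def clean_section():
    """Small noise-free synthetic section with ground truth."""
    params = SynthParams(frame_um=(800.0, 800.0), n_islets=12, seed=7,
                         noise_sd=0.0, gradient_amplitude=0.0)
    return generate_section(params)


@pytest.fixture(scope="session")
def noisy_section():
    """Section at the reference noise level (5% of signal) with a gradient."""
    params = SynthParams(frame_um=(1000.0, 1000.0), n_islets=16, seed=11)
    return generate_section(params)


@pytest.fixture()
def no_bg_config():
    return RunConfig(pixel_size=1.0, background_subtraction=False)


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    return ((xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2) <= radius**2
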