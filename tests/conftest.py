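import math

import numpy as np
import pytest

from fibrespot import SyntheticSpotSpec


def small_spec(
    true_do: float = 1.0,
    seed: int = 0,
    frame: int = 512,
    sigma_minor: float = 60.0,
    speckle_contrast: float = 0.3,
    background_noise_sd: float = 0.01,
    tilt_deg: float = 25.0,
) -> SyntheticSpotSpec:
    """Compact spot spec for fast pipeline tests (not the full-scale default)."""
    return SyntheticSpotSpec(
        height=frame,
        width=frame,
        sigma_major=sigma_minor * math.sqrt(true_do),
        sigma_minor=sigma_minor,
        tilt=math.radians(tilt_deg),
        speckle_contrast=speckle_contrast,
        background_noise_sd=background_noise_sd,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def disc_mask():
    """Filled disc of radius 50 centred in a 160 x 160 frame."""
    ax = np.arange(160) - 80
    return ax[:, None] ** 2 + ax[None, :] ** 2 <= 50**2
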