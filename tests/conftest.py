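import numpy as np
import pytest

from evquant.quant import QuantConfig, TIRFField
from evquant.simulate import FieldSimConfig


@pytest.fixture
def clean_field_cfg() -> FieldSimConfig:
    """Noiseless, zero-background, non-overlapping sparse field (oracle regime).

    256 px at 0.3125 um/px keeps the 80 um x 80 um field geometry while
    staying fast; amplitudes ~10^3 put the detection contour near the
    3-sigma radius of the PSF.
    """
    return FieldSimConfig(
        image_size_px=(256, 256),
        pixel_size_um=0.3125,
        spot_count_mean=10.0,
        background_level=0.0,
        read_noise_sd=0.0,
        shot_noise=False,
        min_separation_px=18.0,
        border_margin_px=10.0,
        amplitude_log10_mean=3.0,
        amplitude_log10_sd=0.15,
    )


@pytest.fixture
def clean_quant_cfg() -> QuantConfig:
    """Quantification settings for the noiseless oracle regime.

    An absolute detection floor stands in for the noise term (the noise sd
    estimate is 0 on noiseless fields) and the area cutoff admits the full
    above-floor footprint of each spot.
    """
    return QuantConfig(min_contrast=1.0, max_area_px=500)


def gaussian_spot_image(
    shape=(128, 128), centers=((64.0, 64.0),), amplitude=1000.0, sigma=1.3, background=0.0
) -> np.ndarray:
    """Render ideal Gaussian spots analytically (independent of the package's
    own simulator internals)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(background))
    for cx, cy in centers:
        img += (
            amplitude
            / (2 * np.pi * sigma**2)
            * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        )
    return img


@pytest.fixture
def single_spot_field() -> tuple[TIRFField, float, tuple[float, float]]:
    amp, center = 1000.0, (64.0, 64.0)
    img = gaussian_spot_image(centers=(center,), amplitude=amp)
    return TIRFField(pixels=img), amp, center
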