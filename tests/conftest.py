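import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from tastekit import synthetic as syn


@pytest.fixture
def textured_image():
    """Smooth random image with enough structure for correlation."""
    rng = np.random.default_rng(42)
    return gaussian_filter(rng.standard_normal((64, 64)), sigma=2.0, mode="wrap")


@pytest.fixture
def small_roi():
    return syn.RoiSpec(center_row=32.0, center_col=32.0, radius=10.0, soft_edge=2.0)


@pytest.fixture
def clean_params(small_roi):
    """Noise- and drift-free 64x64 simulation parameters."""
    return syn.ImagingSimParams(
        frame_height=64,
        frame_width=64,
        roi_spec=small_roi,
        amplitude_schedule={"water": 0.0, "stim": 0.5},
        trial_cv=0.0,
        texture_contrast=0.2,
        seed=7,
    )


@pytest.fixture
def noisy_params(small_roi):
    """Realistic noise + drift at high trace SNR."""
    return syn.ImagingSimParams(
        frame_height=64,
        frame_width=64,
        roi_spec=small_roi,
        amplitude_schedule={"water": 0.0, "stim": 0.5},
        trial_cv=0.1,
        drift_per_frame=(0.05, -0.03),
        drift_jitter_sd=0.02,
        photon_gain=2.0,
        read_noise_sd=2.0,
        texture_contrast=0.25,
        seed=11,
    )
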