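import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nmrdecon as nd

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

EXAMPLES_DIR = Path(__file__).resolve().parent.parent / "examples"

#: (relative area %, center ppm, FWHM ppm) of the packaged five-peak
#: synthetic example spectrum.
FIVE_PEAK_TRIPLETS = [
    (19.24, 3.961253, 0.6362),
    (21.0776, -5.064015, 0.4249),
    (18.31387, -5.503231, 0.8113),
    (18.63312, 3.048056, 0.6403),
    (22.73541, 1.778537, 0.7756),
]


def five_peak_list() -> tuple[nd.LorentzianPeak, ...]:
    return tuple(
        nd.LorentzianPeak(height=a / 100.0 / (0.5 * math.pi * w),
                          center_ppm=c, fwhm_ppm=w)
        for a, c, w in FIVE_PEAK_TRIPLETS
    )


def closed_form_spectrum(peaks, left=3.0, right=-3.0, n=800,
                         noise_sigma=0.0, seed=0,
                         freq_mhz=None) -> nd.Spectrum:
    """Ideal (closed-form) multi-Lorentzian trace on a fixed axis."""
    axis = np.linspace(left, right, n)
    y = np.zeros(n)
    for pk in peaks:
        y += nd.evaluate_peak(pk, axis)
    if noise_sigma > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sigma, n)
    return nd.Spectrum(left, right, y, spectrometer_freq_mhz=freq_mhz)


@pytest.fixture
def single_peak_spectrum() -> nd.Spectrum:
    return closed_form_spectrum([nd.LorentzianPeak(1.0, 0.3, 0.25)])


@pytest.fixture
def three_peak_truth():
    return (nd.LorentzianPeak(1.0, -1.5, 0.12),
            nd.LorentzianPeak(0.5, 0.3, 0.10),
            nd.LorentzianPeak(0.15, 1.6, 0.08))


@pytest.fixture
def example_file() -> Path:
    return EXAMPLES_DIR / "five_peak_synthetic.txt"
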